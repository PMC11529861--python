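import numpy as np
import pytest

from bonobonet import ExpressionMatrix


def make_expr(g: int, n: int, seed: int = 0, loc: float = 0.0) -> ExpressionMatrix:
    """Random Gaussian expression fixture with labelled genes/samples."""
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        values=loc + rng.standard_normal((g, n)),
        gene_ids=tuple(f"g{j}" for j in range(g)),
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    return make_expr(5, 8, seed=42)
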