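"""Reference single-sample coexpression estimators.

Two widely used comparators for sample-specific network inference:

* **LIONESS::Pearson** — linear interpolation between the all-sample and
  leave-one-out Pearson correlation matrices,
  ``N * C_all - (N - 1) * C_minus_i``. Fast and simple, but the
  interpolated entries are not bounded in [-1, 1] and the resulting
  matrices need not be positive-semidefinite on heterogeneous data.

* **SPCC** — the single-sample Pearson contribution: the outer product
  of a sample's per-gene z-scores, ``w_jk = z_ij * z_ik`` with z-scores
  computed against the across-sample mean and (population, divisor-N)
  standard deviation. The across-sample mean of w_jk is exactly the
  Pearson correlation r_jk. Significance is assessed with a Z-test
  using the across-sample standard deviation of w_jk as the null
  spread (the exact null is a documented implementation choice; the
  benchmark compares weights only).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy.stats import norm

from .exceptions import DegenerateGeneError, InsufficientSamplesError
from .expression import ExpressionMatrix


@dataclasses.dataclass
class BaselineNetwork:
    """A single-sample network from one of the baseline estimators."""

    sample_id: str
    method: Literal["lioness_pearson", "spcc"]
    gene_ids: tuple[str, ...]
    weights: np.ndarray
    pvalues: np.ndarray | None = None


def _pearson(values: np.ndarray) -> np.ndarray:
    # rows are genes; constant rows would give nan
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(values)
    return np.atleast_2d(c)


def lioness_pearson(expr: ExpressionMatrix, sample_index: int) -> BaselineNetwork:
    """LIONESS interpolation applied to Pearson correlation.

    weights = N * C_all - (N - 1) * C_minus_i. Entries can fall outside
    [-1, 1] and the matrix can be indefinite — that is a property of the
    estimator, not a bug.
    """
    n = expr.n_samples
    if n < 3:
        raise InsufficientSamplesError(f"need N >= 3 samples, got {n}")
    c_all = _pearson(expr.values)
    keep = np.arange(n) != sample_index
    c_minus = _pearson(expr.values[:, keep])
    weights = n * c_all - (n - 1) * c_minus
    return BaselineNetwork(
        sample_id=expr.sample_ids[sample_index],
        method="lioness_pearson",
        gene_ids=expr.gene_ids,
        weights=0.5 * (weights + weights.T),
    )


def spcc(
    expr: ExpressionMatrix, sample_index: int, pvalues: bool = True
) -> BaselineNetwork:
    """Single-sample Pearson correlation contribution with a Z-test."""
    x = expr.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1)  # divisor N
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise DegenerateGeneError(
            "zero-variance genes: " + ", ".join(bad), bad
        )
    z = (x - mu[:, None]) / sd[:, None]  # (g, N)
    z_i = z[:, sample_index]
    weights = np.outer(z_i, z_i)
    pv = None
    if pvalues:
        # null spread of w_jk across samples: sd over i of z_ij * z_ik
        mean_w = (z @ z.T) / expr.n_samples  # = Pearson r
        mean_w2 = (z**2) @ (z**2).T / expr.n_samples
        spread = np.sqrt(np.maximum(mean_w2 - mean_w**2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.abs(weights) / spread
        pv = 2.0 * norm.sf(zstat)
        pv[spread == 0.0] = np.where(weights[spread == 0.0] == 0.0, 1.0, 0.0)
        pv = 0.5 * (pv + pv.T)
    return BaselineNetwork(
        sample_id=expr.sample_ids[sample_index],
        method="spcc",
        gene_ids=expr.gene_ids,
        weights=weights,
        pvalues=pv,
    )
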