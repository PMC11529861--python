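"""Expression-matrix container and delimited-text I/O.

The core data structure is :class:`ExpressionMatrix`: a genes x samples
array of log-scale expression values with unique gene and sample
identifiers. Files are plain delimited text with samples in the header
row and gene identifiers in the first column (the common bulk-expression
convention); a ``transpose`` flag accommodates the opposite orientation.

Missing values are rejected rather than imputed — the downstream model
has no missingness mechanism — and genes with zero variance across all
samples are rejected by default because leave-one-out variances of zero
break both the prior calibration and the covariance-to-correlation
conversion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGeneError,
    InputFormatError,
    InsufficientSamplesError,
    ValidationError,
)

LogTransform = Literal["none", "log2_plus_1", "ln_plus_1"]

#: Aliases accepted by the CLI for the named log transforms.
LOG_TRANSFORM_ALIASES = {
    "none": "none",
    "log2p1": "log2_plus_1",
    "log2_plus_1": "log2_plus_1",
    "lnp1": "ln_plus_1",
    "ln_plus_1": "ln_plus_1",
}


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Attributes
    ----------
    values : ndarray, shape (g, N)
        Log-transformed expression, one row per gene, one column per sample.
    gene_ids : tuple of str
        Unique, ordered gene identifiers (length g).
    sample_ids : tuple of str
        Unique, ordered sample identifiers (length N).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        g, n = values.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} rows of values"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns of values"
            )
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "missing or non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}; "
                "missing entries are an error, not imputed"
            )
        if n < 3:
            raise InsufficientSamplesError(
                f"need at least 3 samples for leave-one-out statistics, got {n}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def grand_mean(self) -> np.ndarray:
        """Mean expression of each gene across all samples (length g)."""
        return self.values.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=tuple(str(i) for i in df.index),
            sample_ids=tuple(str(c) for c in df.columns),
        )

    def zero_variance_genes(self) -> list[str]:
        """Gene ids whose expression is constant across all samples."""
        var = self.values.var(axis=1)
        return [gid for gid, v in zip(self.gene_ids, var) if v == 0.0]

    def drop_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        drop = set(genes)
        keep = [i for i, gid in enumerate(self.gene_ids) if gid not in drop]
        return ExpressionMatrix(
            values=self.values[keep, :],
            gene_ids=tuple(self.gene_ids[i] for i in keep),
            sample_ids=self.sample_ids,
        )


def _apply_log_transform(
    values: np.ndarray, transform: LogTransform, gene_ids, sample_ids
) -> np.ndarray:
    if transform == "none":
        return values
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise InputFormatError(
            f"negative value at gene {gene_ids[bad[0]]!r}, sample "
            f"{sample_ids[bad[1]]!r}: log transform requires values >= 0"
        )
    if transform == "log2_plus_1":
        return np.log2(values + 1.0)
    if transform == "ln_plus_1":
        return np.log1p(values)
    raise ValueError(f"unknown log transform {transform!r}")


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    log_transform: LogTransform = "none",
    transpose: bool = False,
    drop_zero_variance: bool = False,
) -> ExpressionMatrix:
    """Read a delimited genes x samples expression table.

    Parameters
    ----------
    path : path
        Delimited text file; first row is the sample header, first column
        holds gene identifiers.
    delimiter : str
        Field separator (tab by default; pass ``","`` for CSV).
    log_transform : {"none", "log2_plus_1", "ln_plus_1"}
        Optional transform applied cell-wise as ``log(v + 1)`` in the
        chosen base. Requires all values to be nonnegative.
    transpose : bool
        Set when the file stores samples in rows and genes in columns.
    drop_zero_variance : bool
        Silently drop genes constant across all samples instead of
        raising :class:`DegenerateGeneError`.

    Returns
    -------
    ExpressionMatrix

    Raises
    ------
    InputFormatError
        Unparseable cell (named by row/column) or negative value under a
        log transform.
    ValidationError
        Duplicate identifiers or missing values.
    DegenerateGeneError
        Zero-variance genes present and ``drop_zero_variance`` is False.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed layout
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if transpose:
        df = df.T
    gene_ids = tuple(str(i) for i in df.index)
    sample_ids = tuple(str(c) for c in df.columns)

    # locate non-numeric cells precisely before converting
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna() & df.notna()
    if bad_mask.to_numpy().any():
        r, c = np.argwhere(bad_mask.to_numpy())[0]
        raise InputFormatError(
            f"unparseable value {df.iat[r, c]!r} at gene {gene_ids[r]!r}, "
            f"sample {sample_ids[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at gene {gene_ids[r]!r}, sample {sample_ids[c]!r} "
            f"in {path}; missing entries are an error, not imputed"
        )

    values = _apply_log_transform(
        numeric.to_numpy(dtype=float), log_transform, gene_ids, sample_ids
    )
    expr = ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)
    degenerate = expr.zero_variance_genes()
    if degenerate:
        if drop_zero_variance:
            expr = expr.drop_genes(degenerate)
            if expr.n_genes == 0:
                raise DegenerateGeneError(
                    "all genes have zero variance across samples", degenerate
                )
        else:
            raise DegenerateGeneError(
                "genes with zero variance across all samples: "
                + ", ".join(degenerate),
                degenerate,
            )
    return expr


def write_dense_network(net, path: str | Path, precision: int = 6) -> None:
    """Write a sample network as dense gene x gene TSV matrices.

    Writes the correlation (weight) matrix to ``path`` with gene ids as
    both header row and first column. When the network carries p-values a
    sibling file ``<stem>.pvalues.tsv`` with the same layout is written
    next to it; otherwise no sibling appears.
    """
    path = Path(path)
    _write_matrix(net.correlation, net.gene_ids, path, precision)
    if net.pvalues is not None:
        stem = str(path)[: -len(".tsv")] if str(path).endswith(".tsv") else str(path)
        _write_matrix(net.pvalues, net.gene_ids, Path(stem + ".pvalues.tsv"), precision)


def _write_matrix(matrix: np.ndarray, gene_ids, path: Path, precision: int) -> None:
    df = pd.DataFrame(matrix, index=list(gene_ids), columns=list(gene_ids))
    df.to_csv(path, sep="\t", float_format=f"%.{precision}f")


def read_dense_network(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a dense gene x gene matrix written by :func:`write_dense_network`."""
    return pd.read_csv(path, sep=delimiter, index_col=0, header=0)


def write_edge_list(net, path: str | Path) -> None:
    """Write a sparse network as a 4-column edge list.

    Columns are ``gene_a  gene_b  weight  pvalue`` with ``gene_a``
    lexicographically before ``gene_b``; rows sorted by ascending p-value
    then by the gene pair. Self-edges are never emitted.
    """
    path = Path(path)
    rows = []
    for a, b, w, p in net.edges:
        if a == b:
            continue
        if b < a:
            a, b = b, a
        rows.append((a, b, w, p))
    rows.sort(key=lambda r: (r[3], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\tpvalue\n")
        for a, b, w, p in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\t{p:.10g}\n")
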