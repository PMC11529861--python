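"""Leave-one-out sufficient statistics and empirical-Bayes prior calibration.

For each sample *i* the shrinkage prior on its covariance matrix is an
inverse-Wishart centered on S_i, the sample covariance of the remaining
N-1 samples. The prior degrees of freedom nu_i — equivalently the mixing
weight delta_i = 1/(nu_i - g) — are calibrated from the data by matching
the inverse-Wishart prior variance of the diagonal entries,

    Var(v_i^(kk)) = 2 (s_i^(kk))^2 / (nu_i - g - 3),

summed over genes, to an empirical estimate eta^(k): the population
variance (divisor N) of the N leave-one-out variances of gene k.
Solving for nu_i gives

    nu_i = g + 3 + 2 * sum_k (s_i^(kk))^2 / sum_k eta^(k),

so delta_i = 1 / (3 + 2 sum_k (s_i^(kk))^2 / sum_k eta^(k)) always lies
in (0, 1/3]. Homogeneous populations have small eta^(k) and hence small
delta_i (heavy shrinkage toward the population covariance); outlying or
heterogeneous samples earn larger delta_i.

Everything is computed by downdating two global accumulators — the sum
vector and the sum of outer products — in a single pass, so the whole
run keeps only one gene-by-gene matrix in memory regardless of N.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .exceptions import (
    DegenerateGeneError,
    InsufficientSamplesError,
    ParameterError,
)
from .expression import ExpressionMatrix

CovDivisor = Literal["unbiased", "ml"]


def _loo_denominator(n: int, divisor: CovDivisor) -> int:
    # covariance of N-1 samples: unbiased -> N-2, maximum likelihood -> N-1
    return n - 2 if divisor == "unbiased" else n - 1


@dataclasses.dataclass(frozen=True)
class LeaveOneOutStats:
    """Sufficient statistics for all leave-one-out quantities.

    Attributes
    ----------
    total_sum : ndarray (g,)
        Sum of expression vectors over all N samples.
    total_outer : ndarray (g, g)
        Sum of outer products x_i x_i^T over all N samples.
    grand_mean : ndarray (g,)
        total_sum / N — the x-bar used to center the data term.
    loo_gene_variances : ndarray (N, g)
        Entry (j, k) is the variance of gene k over all samples except j.
    eta_dispersion : ndarray (g,)
        Entry k is the variance (divisor N) of the N leave-one-out
        variances of gene k.
    n_samples, n_genes : int
    cov_divisor : {"unbiased", "ml"}
    """

    total_sum: np.ndarray
    total_outer: np.ndarray
    grand_mean: np.ndarray
    loo_gene_variances: np.ndarray
    eta_dispersion: np.ndarray
    n_samples: int
    n_genes: int
    cov_divisor: CovDivisor = "unbiased"


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Prior degrees of freedom and mixing weight for one sample.

    ``delta == 1/(nu - g)`` always; ``degenerate`` marks the delta -> 0
    limit reached when the leave-one-out variances carry no dispersion
    (perfectly homogeneous data), in which case the posterior mean
    collapses onto S_i exactly.
    """

    sample_id: str
    nu: float
    delta: float
    prior_mean_diag_sq_sum: float
    degenerate: bool = False


def loo_covariance(
    expr: ExpressionMatrix,
    sample_index: int,
    cov_divisor: CovDivisor = "unbiased",
    stats: "LeaveOneOutStats | None" = None,
) -> np.ndarray:
    """Covariance S_i of the N-1 samples excluding ``sample_index``.

    Centered at the leave-one-out mean and computed by downdating the
    global accumulators, never by re-scanning all samples per i.
    """
    n = expr.n_samples
    if n < 3:
        raise InsufficientSamplesError(f"need N >= 3 samples, got {n}")
    if not 0 <= sample_index < n:
        raise IndexError(f"sample_index {sample_index} out of range [0, {n})")
    if stats is None:
        stats = compute_loo_stats(expr, cov_divisor=cov_divisor)
    x_i = expr.values[:, sample_index]
    loo_mean = (stats.total_sum - x_i) / (n - 1)
    scatter = (
        stats.total_outer
        - np.outer(x_i, x_i)
        - (n - 1) * np.outer(loo_mean, loo_mean)
    )
    s_i = scatter / _loo_denominator(n, stats.cov_divisor)
    s_i = 0.5 * (s_i + s_i.T)
    # cancellation can leave tiny negative diagonals on constant genes
    np.fill_diagonal(s_i, np.maximum(np.diagonal(s_i), 0.0))
    return s_i


def compute_loo_stats(
    expr: ExpressionMatrix, cov_divisor: CovDivisor = "unbiased"
) -> LeaveOneOutStats:
    """One-pass accumulators plus all N x g leave-one-out gene variances."""
    n, g = expr.n_samples, expr.n_genes
    if n < 3:
        raise InsufficientSamplesError(f"need N >= 3 samples, got {n}")
    x = expr.values  # (g, N)
    total_sum = x.sum(axis=1)
    total_outer = x @ x.T
    grand_mean = total_sum / n

    # row j = diag of S_j, vectorized over j
    loo_means = (total_sum[None, :] - x.T) / (n - 1)  # (N, g)
    diag_outer = np.diagonal(total_outer)  # sum of x^2 per gene
    scatter_diag = diag_outer[None, :] - x.T**2 - (n - 1) * loo_means**2
    loo_var = scatter_diag / _loo_denominator(n, cov_divisor)
    np.maximum(loo_var, 0.0, out=loo_var)

    eta = loo_var.var(axis=0)  # divisor N, population variance
    return LeaveOneOutStats(
        total_sum=total_sum,
        total_outer=total_outer,
        grand_mean=grand_mean,
        loo_gene_variances=loo_var,
        eta_dispersion=eta,
        n_samples=n,
        n_genes=g,
        cov_divisor=cov_divisor,
    )


def calibrate_dof(
    stats: LeaveOneOutStats,
    s_i_diag: np.ndarray,
    g: int,
    sample_id: str = "",
) -> PriorSpec:
    """Data-driven degrees of freedom for one sample.

    nu_i = g + 3 + 2 sum_k (s_i^(kk))^2 / sum_k eta^(k); delta_i is its
    reciprocal through 1/(nu_i - g) and therefore lies in (0, 1/3].

    When the total eta dispersion is zero (perfectly replicated data)
    the delta -> 0 limit is returned flagged ``degenerate``; downstream
    the posterior mean is then S_i exactly.
    """
    s_i_diag = np.asarray(s_i_diag, dtype=float)
    if np.any(s_i_diag < 0):
        raise DegenerateGeneError("negative diagonal entry in prior mean")
    diag_sq_sum = float(np.sum(s_i_diag**2))
    eta_sum = float(np.sum(stats.eta_dispersion))
    if eta_sum == 0.0:
        return PriorSpec(
            sample_id=sample_id,
            nu=float("inf"),
            delta=0.0,
            prior_mean_diag_sq_sum=diag_sq_sum,
            degenerate=True,
        )
    if diag_sq_sum == 0.0:
        raise DegenerateGeneError(
            "all prior-mean variances are zero while leave-one-out "
            "variances disperse; constant genes should have been removed"
        )
    nu = g + 3.0 + 2.0 * diag_sq_sum / eta_sum
    return PriorSpec(
        sample_id=sample_id,
        nu=nu,
        delta=1.0 / (nu - g),
        prior_mean_diag_sq_sum=diag_sq_sum,
    )


def fixed_delta_prior(delta: float, g: int, sample_id: str = "") -> PriorSpec:
    """Prior with a user-fixed mixing weight delta in (0, 1] for all samples."""
    if not 0.0 < delta <= 1.0:
        raise ParameterError(f"delta must lie in (0, 1], got {delta}")
    return PriorSpec(
        sample_id=sample_id,
        nu=g + 1.0 / delta,
        delta=float(delta),
        prior_mean_diag_sq_sum=float("nan"),
    )
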