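"""Empirical-Bayes sample-specific coexpression model.

Model
-----
For N samples of g log-transformed expression values, each centered
vector x_i - x_bar is modelled as multivariate normal with its own
covariance V_i. The prior on V_i is inverse-Wishart with scale
(nu_i - g - 1) S_i and nu_i degrees of freedom, where S_i is the sample
covariance of the other N-1 samples — each individual's covariance is
shrunk toward the population's. Conjugacy gives a closed-form posterior,
inverse-Wishart with scale (nu_i - g) Sigma_i and nu_i + 1 degrees of
freedom, whose mean is the convex combination

    Sigma_i = delta_i (x_i - x_bar)(x_i - x_bar)^T + (1 - delta_i) S_i,

with delta_i = 1/(nu_i - g). Sigma_i is positive-semidefinite by
construction (a convex combination of a rank-1 outer product and a
covariance), and is converted to a coexpression (correlation) matrix by
the usual normalisation r_jk = v_jk / sqrt(v_jj v_kk).

Edge significance uses the inverse-Wishart variance of an individual
entry,

    Var(v_jk) = [(nu-g+1) s_jk^2 + (nu-g-1) s_jj s_kk]
                / [(nu-g)(nu-g-3)],

evaluated at the prior-mean entries of S (the printed form), and a
normal approximation to the credible region: the null v_jk = 0 is
rejected at level alpha when 2(1 - Phi(|sigma_jk| / psi_jk)) <= alpha.

Usage mirrors statsmodels: build a :class:`Bonobo` model from data,
``fit()`` it, and read estimates off the returned
:class:`BonoboResults`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    BonobonetError,
    DegenerateGeneError,
    DegreesOfFreedomError,
    StateError,
    ValidationError,
)
from .expression import ExpressionMatrix
from .loo import (
    CovDivisor,
    LeaveOneOutStats,
    PriorSpec,
    calibrate_dof,
    compute_loo_stats,
    fixed_delta_prior,
    loo_covariance,
)

EdgeVar = Literal["as-printed", "posterior-params"]
Correction = Literal["none", "benjamini_hochberg"]


@dataclasses.dataclass
class SampleNetwork:
    """One sample's posterior coexpression network.

    ``post_mean_cov`` is Sigma_i, the posterior-mean covariance;
    ``correlation`` its normalisation; ``pvalues`` the full symmetric
    g x g matrix of two-sided edge p-values when computed (diagonal
    entries are reported but untestable — a null of zero variance is
    not meaningful).
    """

    sample_id: str
    gene_ids: tuple[str, ...]
    post_mean_cov: np.ndarray
    correlation: np.ndarray
    nu: float
    delta: float
    pvalues: np.ndarray | None = None


@dataclasses.dataclass
class SparseNetwork:
    """Edge list surviving the significance threshold.

    Each edge is ``(gene_a, gene_b, weight, pvalue)`` with
    ``gene_a < gene_b`` lexicographically; weights are correlation
    entries. ``correction`` records whether the threshold was applied to
    raw or Benjamini-Hochberg-adjusted p-values.
    """

    sample_id: str
    edges: list[tuple[str, str, float, float]]
    alpha: float
    correction: Correction


# ---------------------------------------------------------------------------
# core closed-form operations


def posterior_mean(
    x_i: np.ndarray, grand_mean: np.ndarray, prior: PriorSpec, s_i: np.ndarray
) -> np.ndarray:
    """Posterior-mean covariance Sigma_i for one sample.

    ``Sigma_i = delta (x_i - x_bar)(x_i - x_bar)^T + (1 - delta) S_i``.
    The grand mean includes sample i, exactly as the likelihood centers
    the data. For a degenerate prior (delta = 0) this is S_i itself.
    """
    x_i = np.asarray(x_i, dtype=float)
    grand_mean = np.asarray(grand_mean, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    g = x_i.shape[0]
    if grand_mean.shape != (g,) or s_i.shape != (g, g):
        raise ValidationError(
            f"dimension mismatch: x_i {x_i.shape}, x_bar {grand_mean.shape}, "
            f"S_i {s_i.shape}"
        )
    dev = x_i - grand_mean
    sigma = prior.delta * np.outer(dev, dev) + (1.0 - prior.delta) * s_i
    return 0.5 * (sigma + sigma.T)


def posterior_edge_sd(
    prior: PriorSpec, s_entries: tuple[float, float, float]
) -> float:
    """Standard deviation psi_jk of a single edge's covariance.

    ``s_entries`` is ``(s_jj, s_kk, s_jk)`` taken from the prior mean
    S_i. Requires nu - g > 3.
    """
    s_jj, s_kk, s_jk = s_entries
    m = prior.nu - _infer_g(prior)
    if not m > 3:
        raise DegreesOfFreedomError(
            f"edge variance needs nu - g > 3, got {m}; use the calibrated "
            "degrees of freedom (which guarantee nu > g + 3)"
        )
    var = ((m + 1) * s_jk**2 + (m - 1) * s_jj * s_kk) / (m * (m - 3))
    return float(np.sqrt(var))


def _infer_g(prior: PriorSpec) -> float:
    # nu and delta jointly encode g: nu - g = 1/delta
    return prior.nu - 1.0 / prior.delta


def _edge_sd_matrix(m: float, scale: np.ndarray) -> np.ndarray:
    """Vectorized psi matrix for inverse-Wishart entry variances.

    ``m`` is df minus dimension of the parameterisation being used;
    ``scale`` the matrix whose entries enter the formula.
    """
    if not m > 3:
        raise DegreesOfFreedomError(
            f"edge variance needs df - g > 3, got {m}; use the calibrated "
            "degrees of freedom (which guarantee nu > g + 3)"
        )
    d = np.diagonal(scale)
    var = ((m + 1) * scale**2 + (m - 1) * np.outer(d, d)) / (m * (m - 3))
    return np.sqrt(np.maximum(var, 0.0))


def edge_pvalues(
    post_mean: np.ndarray,
    prior: PriorSpec,
    s_i: np.ndarray,
    edge_var: EdgeVar = "as-printed",
) -> np.ndarray:
    """Two-sided edge p-values ``2 (1 - Phi(|sigma_jk| / psi_jk))``.

    ``edge_var="as-printed"`` evaluates the entry-variance formula at the
    prior mean S_i with the prior degrees of freedom;
    ``"posterior-params"`` evaluates the same inverse-Wishart formula at
    the posterior parameters (df nu + 1, mean Sigma_i). Diagonal entries
    are filled but untestable. A zero psi with a nonzero estimate gives
    p = 0 with a warning; zero psi with zero estimate gives p = 1.
    """
    g = post_mean.shape[0]
    if prior.degenerate:
        psi = np.zeros_like(post_mean)
    elif edge_var == "as-printed":
        psi = _edge_sd_matrix(prior.nu - g, s_i)
    elif edge_var == "posterior-params":
        psi = _edge_sd_matrix(prior.nu + 1 - g, post_mean)
    else:
        raise ValueError(f"unknown edge_var {edge_var!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(post_mean) / psi
    pvals = 2.0 * norm.sf(z)
    zero_psi = psi == 0.0
    if np.any(zero_psi):
        nonzero_est = zero_psi & (post_mean != 0.0)
        if np.any(nonzero_est):
            warnings.warn(
                "degenerate edges: zero posterior spread with nonzero "
                "estimate; p-values set to 0",
                stacklevel=2,
            )
            pvals[nonzero_est] = 0.0
        pvals[zero_psi & (post_mean == 0.0)] = 1.0
    return 0.5 * (pvals + pvals.T)


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    """Normalise a PSD covariance to a correlation matrix.

    r_jk = v_jk / sqrt(v_jj v_kk); diagonal exactly 1. Entries are
    clipped to [-1, 1] only when the overshoot is within 1e-12 —
    anything larger signals an internal inconsistency, not rounding.
    """
    d = np.diagonal(cov)
    if np.any(d <= 0):
        raise DegenerateGeneError(
            "nonpositive variance on the covariance diagonal; remove "
            "zero-variance genes before converting to correlation"
        )
    inv_sd = 1.0 / np.sqrt(d)
    corr = cov * np.outer(inv_sd, inv_sd)
    overshoot = np.max(np.abs(corr)) - 1.0
    if overshoot > 1e-12:
        raise BonobonetError(
            f"correlation overshoot {overshoot:.3e} exceeds 1e-12; "
            "internal consistency error"
        )
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def sparsify(
    net: SampleNetwork,
    alpha: float = 0.05,
    correction: Correction = "none",
) -> SparseNetwork:
    """Prune edges whose credible region contains zero.

    With ``correction="none"`` an edge is retained when p_jk <= alpha
    (equivalently the 100(1-alpha)% credible region excludes zero); with
    ``"benjamini_hochberg"`` the threshold applies to BH-adjusted
    p-values over the g(g-1)/2 distinct edges of this one network.
    """
    if net.pvalues is None:
        raise StateError("sparsify requires edge p-values; fit with pvalues=True")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    g = len(net.gene_ids)
    iu = np.triu_indices(g, k=1)
    pvals = net.pvalues[iu]
    if correction == "benjamini_hochberg":
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        keep = reject
        p_report = p_adj
    elif correction == "none":
        keep = pvals <= alpha
        p_report = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")
    edges = []
    for j, k, w, p in zip(
        iu[0][keep], iu[1][keep], net.correlation[iu][keep], p_report[keep]
    ):
        a, b = net.gene_ids[j], net.gene_ids[k]
        if b < a:
            a, b = b, a
        edges.append((a, b, float(w), float(p)))
    return SparseNetwork(
        sample_id=net.sample_id, edges=edges, alpha=alpha, correction=correction
    )


# ---------------------------------------------------------------------------
# model / results


class Bonobo:
    """Sample-specific coexpression model for a bulk expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples log-expression with at least 3 samples.
    delta : "auto" or float in (0, 1]
        "auto" calibrates nu_i (hence delta_i) per sample from the
        leave-one-out variance dispersion; a float fixes delta for all
        samples.
    cov_divisor : {"unbiased", "ml"}
        Divisor convention for the leave-one-out covariance: N-2
        (unbiased for N-1 samples, the default) or N-1.
    edge_var : {"as-printed", "posterior-params"}
        Which parameterisation the edge-variance formula is evaluated
        at; see :func:`edge_pvalues`.

    Examples
    --------
    >>> model = Bonobo.from_dataframe(df)
    >>> res = model.fit()
    >>> net = res.network("sample_7")
    >>> net.correlation.shape
    (g, g)
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        delta: float | Literal["auto"] = "auto",
        cov_divisor: CovDivisor = "unbiased",
        edge_var: EdgeVar = "as-printed",
    ):
        if not isinstance(expr, ExpressionMatrix):
            raise TypeError("expr must be an ExpressionMatrix; see from_dataframe")
        self.expr = expr
        self.delta = delta
        self.cov_divisor: CovDivisor = cov_divisor
        self.edge_var: EdgeVar = edge_var

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "Bonobo":
        """Build from a genes x samples DataFrame (index = gene ids)."""
        return cls(ExpressionMatrix.from_dataframe(df), **kwargs)

    def fit(self, pvalues: bool = True) -> "BonoboResults":
        """Compute leave-one-out statistics and per-sample priors.

        Cheap relative to the networks themselves: one pass over the
        data fills the global accumulators and the N x g leave-one-out
        variance table; the per-sample networks are produced lazily by
        the results object. Estimation is fully deterministic.
        """
        stats = compute_loo_stats(self.expr, cov_divisor=self.cov_divisor)
        priors: list[PriorSpec] = []
        g = self.expr.n_genes
        for i, sid in enumerate(self.expr.sample_ids):
            if self.delta == "auto":
                # diag of S_i is exactly row i of the LOO variance table
                prior = calibrate_dof(
                    stats, stats.loo_gene_variances[i], g, sample_id=sid
                )
            else:
                prior = fixed_delta_prior(float(self.delta), g, sample_id=sid)
            priors.append(prior)
        return BonoboResults(self, stats, priors, compute_pvalues=pvalues)


class BonoboResults:
    """Fitted sample-specific coexpression networks.

    Holds the calibrated priors for every sample and materialises each
    sample's posterior network on demand, keeping resident state at a
    couple of gene-by-gene matrices regardless of N.
    """

    def __init__(
        self,
        model: Bonobo,
        stats: LeaveOneOutStats,
        priors: Sequence[PriorSpec],
        compute_pvalues: bool = True,
    ):
        self.model = model
        self.stats = stats
        self.priors = list(priors)
        self.compute_pvalues = compute_pvalues

    @property
    def expr(self) -> ExpressionMatrix:
        return self.model.expr

    @property
    def nu(self) -> np.ndarray:
        """Calibrated degrees of freedom, one per sample."""
        return np.array([p.nu for p in self.priors])

    @property
    def delta(self) -> np.ndarray:
        """Mixing weights delta_i = 1/(nu_i - g), one per sample."""
        return np.array([p.delta for p in self.priors])

    def prior_table(self) -> pd.DataFrame:
        """Per-sample prior hyperparameters as a DataFrame."""
        return pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in self.priors],
                "nu": self.nu,
                "delta": self.delta,
            }
        )

    def network(self, sample: int | str) -> SampleNetwork:
        """Posterior network for one sample (by index or sample id)."""
        if isinstance(sample, str):
            try:
                idx = self.expr.sample_ids.index(sample)
            except ValueError:
                raise KeyError(f"unknown sample id {sample!r}") from None
        else:
            idx = sample
        return self._compute_network(idx)

    def sample_networks(self) -> Iterator[SampleNetwork]:
        """Yield one posterior network per sample, in input order."""
        for i in range(self.expr.n_samples):
            yield self._compute_network(i)

    def _compute_network(self, i: int) -> SampleNetwork:
        expr = self.expr
        prior = self.priors[i]
        s_i = loo_covariance(
            expr, i, cov_divisor=self.model.cov_divisor, stats=self.stats
        )
        sigma = posterior_mean(
            expr.values[:, i], self.stats.grand_mean, prior, s_i
        )
        corr = cov_to_corr(sigma)
        pvals = None
        if self.compute_pvalues:
            pvals = edge_pvalues(sigma, prior, s_i, edge_var=self.model.edge_var)
        return SampleNetwork(
            sample_id=expr.sample_ids[i],
            gene_ids=expr.gene_ids,
            post_mean_cov=sigma,
            correlation=corr,
            nu=prior.nu,
            delta=prior.delta,
            pvalues=pvals,
        )

    def sparse_network(
        self,
        sample: int | str,
        alpha: float = 0.05,
        correction: Correction = "none",
    ) -> SparseNetwork:
        """Sparsified network for one sample; see :func:`sparsify`."""
        return sparsify(self.network(sample), alpha=alpha, correction=correction)

    def summary(self) -> str:
        """Text summary of the fit: data shape and prior calibration."""
        expr = self.expr
        delta = self.delta
        lines = [
            "Sample-specific coexpression model (empirical-Bayes inverse-Wishart)",
            "=" * 68,
            f"Genes:   {expr.n_genes:>6d}    Samples: {expr.n_samples:>6d}",
            f"Prior:   {'calibrated per sample' if self.model.delta == 'auto' else f'fixed delta = {self.model.delta}'}",
            f"LOO covariance divisor: {self.model.cov_divisor}",
            "-" * 68,
            f"{'sample_id':<24s}{'nu':>16s}{'delta':>14s}",
        ]
        for p in self.priors:
            lines.append(f"{p.sample_id:<24s}{p.nu:>16.4f}{p.delta:>14.6f}")
        lines.append("-" * 68)
        lines.append(
            f"delta range: [{delta.min():.6f}, {delta.max():.6f}]  "
            f"(calibrated deltas always lie in (0, 1/3])"
        )
        return "\n".join(lines)


def bonobo_all_samples(
    expr: ExpressionMatrix,
    delta: float | Literal["auto"] = "auto",
    cov_divisor: CovDivisor = "unbiased",
    edge_var: EdgeVar = "as-printed",
    pvalues: bool = True,
) -> Iterator[SampleNetwork]:
    """Convenience: fit and stream one network per sample, in input order."""
    res = Bonobo(
        expr, delta=delta, cov_divisor=cov_divisor, edge_var=edge_var
    ).fit(pvalues=pvalues)
    yield from res.sample_networks()
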