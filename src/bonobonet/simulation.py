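"""Synthetic expression data and the MSE benchmark harness.

The generator emulates a bulk expression study in which every individual
has its own true coexpression structure:

1. draw a population covariance (a random correlation matrix with unit
   variances);
2. draw each individual's true covariance V_i from an inverse-Wishart
   centered on the population covariance, with degrees of freedom
   ``population_spread`` controlling how far individuals scatter;
3. define each individual's ground-truth correlation empirically from
   ``truth_draws`` held-out multivariate-normal replicate draws under
   V_i, and give each estimator exactly one observed draw per
   individual.

Three scenarios: a homogeneous population; a mixture of two populations
with distinct means and covariances (configurable minor-population
share); and gene loss, in which a subset of samples loses expression of
a subset of genes (values zeroed plus tiny jitter, sd 1e-6, so that
variance-based machinery stays defined).

Estimators are scored by the squared Frobenius norm of the difference
between estimated and true correlation matrices, averaged over samples
("MSE"), plus a scaled variant that divides each sample's MSE by the
variance of its true correlation's off-diagonal entries.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .baselines import lioness_pearson, spcc
from .exceptions import ParameterError
from .expression import ExpressionMatrix
from .model import Bonobo

Scenario = Literal["homogeneous", "mixture", "gene_loss"]

#: Methods the benchmark knows how to run.
KNOWN_METHODS = ("bonobo", "bonobo_sparse", "lioness", "spcc", "truth")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic-population benchmark condition.

    Defaults mirror the benchmark's study conditions: a 20% minor
    population in mixtures, loss of 1% of genes in 20% of samples, 500
    held-out replicate draws defining each individual's ground truth,
    and inverse-Wishart scatter df of g + 10 around the population
    covariance.
    """

    g: int
    N: int
    n_replicates: int = 20
    seed: int = 0
    scenario: Scenario = "homogeneous"
    mixture_fraction: float = 0.2
    loss_gene_fraction: float = 0.01
    loss_sample_fraction: float = 0.2
    truth_draws: int = 500
    population_spread: float | None = None  # default g + 10
    mean_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.g < 2 or self.N < 3:
            raise ParameterError("need g >= 2 genes and N >= 3 samples")
        if self.scenario not in ("homogeneous", "mixture", "gene_loss"):
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.mixture_fraction <= 0.5:
            raise ParameterError("mixture_fraction must lie in (0, 0.5]")
        if not 0.0 < self.loss_gene_fraction < 1.0:
            raise ParameterError("loss_gene_fraction must lie in (0, 1)")
        if not 0.0 < self.loss_sample_fraction < 1.0:
            raise ParameterError("loss_sample_fraction must lie in (0, 1)")
        if self.truth_draws < 100:
            raise ParameterError("truth_draws must be at least 100")
        if self.population_spread is None:
            self.population_spread = self.g + 10.0
        if not self.population_spread > self.g + 3:
            raise ParameterError("population_spread must exceed g + 3")


@dataclasses.dataclass
class SyntheticPopulation:
    """One generated dataset with its per-individual ground truth."""

    expr: ExpressionMatrix
    true_correlations: list[np.ndarray]
    true_covariances: list[np.ndarray]
    lost_genes: np.ndarray  # indices; empty outside gene_loss
    lost_samples: np.ndarray  # indices; empty outside gene_loss
    minor_samples: np.ndarray  # indices; empty outside mixture


def random_correlation_matrix(g: int, rng: np.random.Generator) -> np.ndarray:
    """Random correlation matrix with unit variances.

    A Wishart-style draw with 2g degrees of freedom, normalised to unit
    diagonal: full rank, moderately strong off-diagonal structure.
    """
    b = rng.standard_normal((g, 2 * g))
    c = b @ b.T
    d = 1.0 / np.sqrt(np.diagonal(c))
    corr = c * np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _draw_individual(
    mean: np.ndarray,
    v_i: np.ndarray,
    truth_draws: int,
    rng: np.random.Generator,
    loss_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One observed vector plus the empirical ground-truth correlation."""
    g = mean.shape[0]
    chol = np.linalg.cholesky(v_i + 1e-10 * np.eye(g))
    draws = mean[:, None] + chol @ rng.standard_normal((g, truth_draws + 1))
    if loss_mask is not None:
        draws[loss_mask, :] = rng.normal(0.0, 1e-6, (int(loss_mask.sum()), truth_draws + 1))
    observed = draws[:, 0]
    truth_corr = np.corrcoef(draws[:, 1:])
    return observed, truth_corr, v_i


def generate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticPopulation:
    """Generate one dataset under the configured scenario.

    Deterministic given the same seed/generator state. The observed
    matrix holds exactly one draw per individual; ground truth is the
    empirical correlation of ``truth_draws`` held-out replicates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g, n = config.g, config.N
    spread = float(config.population_spread)

    pop_corr_a = random_correlation_matrix(g, rng)
    mean_a = np.zeros(g)
    minor = np.array([], dtype=int)
    if config.scenario == "mixture":
        pop_corr_b = random_correlation_matrix(g, rng)
        mean_b = np.full(g, config.mean_offset)
        n_minor = int(round(config.mixture_fraction * n))
        minor = rng.choice(n, size=n_minor, replace=False)
    lost_genes = np.array([], dtype=int)
    lost_samples = np.array([], dtype=int)
    if config.scenario == "gene_loss":
        n_lost_genes = max(1, int(round(config.loss_gene_fraction * g)))
        n_lost_samples = max(1, int(round(config.loss_sample_fraction * n)))
        lost_genes = np.sort(rng.choice(g, size=n_lost_genes, replace=False))
        lost_samples = np.sort(rng.choice(n, size=n_lost_samples, replace=False))

    minor_set = set(minor.tolist())
    lost_sample_set = set(lost_samples.tolist())
    loss_mask = np.zeros(g, dtype=bool)
    loss_mask[lost_genes] = True

    # per-individual true covariance scattered around its population's
    scale_a = (spread - g - 1) * pop_corr_a
    observed = np.empty((g, n))
    truths: list[np.ndarray] = []
    covs: list[np.ndarray] = []
    for i in range(n):
        if i in minor_set:
            scale, mean = (spread - g - 1) * pop_corr_b, mean_b
        else:
            scale, mean = scale_a, mean_a
        v_i = invwishart.rvs(df=spread, scale=scale, random_state=rng)
        mask = loss_mask if i in lost_sample_set else None
        x_i, t_i, v_i = _draw_individual(mean, v_i, config.truth_draws, rng, mask)
        observed[:, i] = x_i
        truths.append(t_i)
        covs.append(v_i)

    expr = ExpressionMatrix(
        values=observed,
        gene_ids=tuple(f"g{j}" for j in range(g)),
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )
    return SyntheticPopulation(
        expr=expr,
        true_correlations=truths,
        true_covariances=covs,
        lost_genes=lost_genes,
        lost_samples=lost_samples,
        minor_samples=np.sort(minor),
    )


def frobenius_mse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Squared Frobenius norm of (estimate - truth)."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {estimate.shape} vs {truth.shape}"
        )
    diff = estimate - truth
    return float(np.sum(diff * diff))


def scaled_frobenius_mse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """MSE divided by the variance of the truth's upper-triangle entries."""
    mse = frobenius_mse(estimate, truth)
    iu = np.triu_indices(truth.shape[0], k=1)
    denom = float(np.var(truth[iu]))
    return mse / denom if denom > 0 else float("inf")


def block_mse(
    estimate: np.ndarray, truth: np.ndarray, gene_indices: np.ndarray
) -> float:
    """MSE restricted to off-diagonal edges touching the given genes."""
    g = truth.shape[0]
    mask = np.zeros((g, g), dtype=bool)
    mask[gene_indices, :] = True
    mask[:, gene_indices] = True
    np.fill_diagonal(mask, False)
    diff = (estimate - truth)[mask]
    return float(np.sum(diff * diff))


def _estimate_networks(
    method: str,
    expr: ExpressionMatrix,
    pop: SyntheticPopulation,
    alpha: float,
) -> Iterable[np.ndarray]:
    n = expr.n_samples
    if method in ("bonobo", "bonobo_sparse"):
        need_p = method == "bonobo_sparse"
        res = Bonobo(expr).fit(pvalues=need_p)
        for net in res.sample_networks():
            est = net.correlation
            if need_p:
                est = np.where(net.pvalues <= alpha, est, 0.0)
                np.fill_diagonal(est, 1.0)
            yield est
    elif method == "lioness":
        for i in range(n):
            yield lioness_pearson(expr, i).weights
    elif method == "spcc":
        for i in range(n):
            yield spcc(expr, i, pvalues=False).weights
    elif method == "truth":  # oracle estimator, for harness validation
        yield from pop.true_correlations
    else:
        raise ValueError(
            f"unknown method {method!r}; choose from {KNOWN_METHODS}"
        )


@dataclasses.dataclass
class SimulationResult:
    """Benchmark output: one row per (method, replicate)."""

    table: pd.DataFrame
    replicate_seeds: list[int]

    def mean_mse(self) -> pd.Series:
        """Mean MSE per method across replicates."""
        return self.table.groupby("method")["mean_mse"].mean()


def run_benchmark(
    config: SimulationConfig,
    methods: Sequence[str] = ("bonobo", "lioness", "spcc"),
    alpha: float = 0.05,
) -> SimulationResult:
    """Score estimators on fresh synthetic datasets.

    For each replicate a new population is generated from a seed spawned
    deterministically from ``config.seed``; every method estimates all N
    sample networks; the per-sample squared-Frobenius error against the
    per-sample empirical truth is averaged over samples. For the
    gene-loss scenario an extra ``lost_block_mse`` column reports the
    error restricted to edges touching lost genes, over affected samples
    only.
    """
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_replicates)
    rep_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        pop = generate_population(config, rng=rng)
        for method in methods:
            mses, scaled, lost = [], [], []
            for i, est in enumerate(
                _estimate_networks(method, pop.expr, pop, alpha)
            ):
                truth = pop.true_correlations[i]
                mses.append(frobenius_mse(est, truth))
                scaled.append(scaled_frobenius_mse(est, truth))
                if config.scenario == "gene_loss" and i in pop.lost_samples:
                    lost.append(block_mse(est, truth, pop.lost_genes))
            row = {
                "method": method,
                "scenario": config.scenario,
                "g": config.g,
                "N": config.N,
                "replicate": rep,
                "mean_mse": float(np.mean(mses)),
                "scaled_mse": float(np.mean(scaled)),
            }
            if config.scenario == "gene_loss":
                row["lost_block_mse"] = float(np.mean(lost))
            rows.append(row)
    return SimulationResult(table=pd.DataFrame(rows), replicate_seeds=rep_seeds)
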