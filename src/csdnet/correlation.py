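"""Bootstrap estimation of all-pairs Spearman co-expression within one condition.

The Spearman correlation of two genes is the Pearson correlation of their
within-gene observational ranks.  Exploiting this, the all-to-all correlation
matrix is obtained by ranking every gene column once and then taking a single
standardized matrix product, instead of correlating pairs one at a time.

Sampling variability is estimated by bootstrapping: each replicate draws
``n_samples`` sample indices with replacement, correlates the resampled rank
matrix, and folds the resulting correlation matrix into a streaming
(Welford) mean/variance accumulator, so no per-replicate history is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import validate_expression

__all__ = ["CorrelationSummary", "rank_transform", "pearson_all_pairs", "bootstrap_correlation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationSummary:
    """Bootstrap mean and variance of every pairwise correlation in one condition.

    ``rho_mean[i, j]`` is the bootstrap-mean Spearman correlation of genes
    ``gene_ids[i]`` and ``gene_ids[j]`` (the rho of the C/S/D formulas) and
    ``rho_var[i, j]`` the corresponding bootstrap variance (sigma squared).
    Pairs involving a constant-expression gene carry NaN and are excluded
    downstream.
    """

    gene_ids: tuple[str, ...]
    rho_mean: np.ndarray
    rho_var: np.ndarray
    n_iterations: int
    seed: int
    constant_genes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        p = len(self.gene_ids)
        if self.rho_mean.shape != (p, p) or self.rho_var.shape != (p, p):
            raise ValueError("correlation matrices must be square over gene_ids")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.rho_mean), initial=0.0) > 1 + 1e-12:
                raise ValueError("|rho_mean| must not exceed 1")
            if np.nanmin(self.rho_var, initial=0.0) < -1e-15:
                raise ValueError("rho_var must be non-negative")


def rank_transform(expr: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Replace each gene column by its within-column observational ranks.

    Ties receive the average of the ranks they span (fractional ranks), so a
    column of ``n`` all-equal values maps to ``(n + 1) / 2`` and every column
    sums to ``n (n + 1) / 2``.
    """
    if validate:
        expr = validate_expression(expr)
    ranks = rankdata(expr.to_numpy(dtype=float), axis=0, method="average")
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def _constant_columns(values: np.ndarray) -> np.ndarray:
    return (values == values[0]).all(axis=0)


def pearson_all_pairs(
    values: np.ndarray | pd.DataFrame,
    warn_constant: bool = True,
) -> np.ndarray:
    """All-to-all Pearson correlation of the columns of a samples x genes array.

    When ``values`` holds ranks this is the Spearman correlation of the
    original data.  Columns with zero variance have no defined correlation:
    their rows/columns are set to NaN and (optionally) a warning lists the
    affected genes.  Off-diagonal entries are clipped to [-1, 1] to absorb
    round-off; the diagonal is exactly 1 for non-constant columns.
    """
    if isinstance(values, pd.DataFrame):
        genes = list(values.columns)
        X = values.to_numpy(dtype=float)
    else:
        genes = None
        X = np.asarray(values, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to correlate")

    constant = _constant_columns(X)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc * Xc).sum(axis=0))
    norms[constant] = 1.0  # avoid 0/0; entries overwritten with NaN below
    U = Xc / norms
    R = U.T @ U
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    if constant.any():
        R[constant, :] = np.nan
        R[:, constant] = np.nan
        if warn_constant:
            which = (
                [genes[i] for i in np.nonzero(constant)[0]]
                if genes is not None
                else np.nonzero(constant)[0].tolist()
            )
            logger.warning(
                "correlations undefined for %d constant gene(s): %s",
                constant.sum(), which,
            )
    return R


def bootstrap_correlation(
    expr: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int = 0,
    rerank: bool = False,
    use_full_sample_rho: bool = False,
) -> CorrelationSummary:
    """Bootstrap the all-pairs Spearman correlation matrix of one condition.

    Each of ``n_iterations`` replicates draws ``n_samples`` sample indices
    with replacement (every bootstrap sample is as large as the original),
    correlates the resampled rank matrix and updates a Welford accumulator.
    The returned mean is the rho entering the C/S/D scores and the variance
    is the sigma-squared denominator term.

    Parameters
    ----------
    expr
        Samples x genes expression matrix.
    n_iterations
        Number of bootstrap replicates, at least 2 (the sample variance is
        undefined for fewer).  Default 1000.
    seed
        Seed of the replicate index stream; recorded in the summary so runs
        are reproducible bit for bit.
    rerank
        When True, re-rank each resampled expression matrix from scratch
        (duplicated samples then produce tied ranks).  The default ranks the
        full sample once and resamples rows of that precomputed rank matrix,
        which is substantially faster.
    use_full_sample_rho
        When True, report the full-sample Spearman correlation as
        ``rho_mean`` instead of the bootstrap mean; the variance is still
        the bootstrap variance.

    Notes
    -----
    Identical ``(expr, n_iterations, seed)`` triples give bit-identical
    results: the replicate stream depends only on ``seed``, never on thread
    scheduling.
    """
    expr = validate_expression(expr)
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2: the bootstrap variance is undefined otherwise")

    genes = tuple(str(g) for g in expr.columns)
    values = expr.to_numpy(dtype=float)
    n, p = values.shape

    full_constant = _constant_columns(values)
    if full_constant.any():
        logger.warning(
            "correlations undefined for %d constant gene(s): %s",
            full_constant.sum(),
            [genes[i] for i in np.nonzero(full_constant)[0]],
        )
    ranks = rankdata(values, axis=0, method="average")

    rng = np.random.default_rng(seed)
    mean = np.zeros((p, p))
    m2 = np.zeros((p, p))
    ever_constant = full_constant.copy()
    for it in range(n_iterations):
        idx = rng.integers(0, n, size=n)
        if rerank:
            sub = rankdata(values[idx], axis=0, method="average")
        else:
            sub = ranks[idx]
        r = pearson_all_pairs(sub, warn_constant=False)
        ever_constant |= _constant_columns(sub)
        # Welford update on the full matrix
        delta = r - mean
        mean += delta / (it + 1)
        m2 += delta * (r - mean)
    var = m2 / (n_iterations - 1)

    if ever_constant.any() and not full_constant.all():
        extra = ever_constant & ~full_constant
        if extra.any():
            logger.warning(
                "%d gene(s) were constant in at least one bootstrap replicate: %s",
                extra.sum(),
                [genes[i] for i in np.nonzero(extra)[0]],
            )
    # a column constant in any replicate leaves NaN in the accumulator already
    with np.errstate(invalid="ignore"):
        var[var < 0] = 0.0  # guard against -0 / tiny negative round-off

    if use_full_sample_rho:
        rho = pearson_all_pairs(ranks, warn_constant=False)
        nan_mask = np.isnan(mean)
        rho[nan_mask] = np.nan
        mean = rho

    return CorrelationSummary(
        gene_ids=genes,
        rho_mean=mean,
        rho_var=var,
        n_iterations=n_iterations,
        seed=seed,
        constant_genes=tuple(genes[i] for i in np.nonzero(ever_constant)[0]),
    )
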