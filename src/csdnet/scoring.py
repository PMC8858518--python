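"""Conserved / Specific / Differentiated scoring of gene pairs across two conditions.

Given the bootstrap mean correlations rho1, rho2 and bootstrap variances
var1, var2 of a gene pair in the two conditions, the scores are

    C = |rho1 + rho2| / sqrt(var1 + var2)
    S = ||rho1| - |rho2|| / sqrt(var1 + var2)
    D = (|rho1| + |rho2| - |rho1 + rho2|) / sqrt(var1 + var2)

C is large when both conditions show strong correlation of the same sign,
S when the correlation is strong in one condition and weak in the other,
and D when both are strong but of opposite sign.  The three numerators
satisfy the triangle identity |rho1 + rho2| + (|rho1| + |rho2| - |rho1 +
rho2|) = |rho1| + |rho2|, so C + D = (|rho1| + |rho2|) / sqrt(var1 + var2)
for every pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .correlation import CorrelationSummary

__all__ = ["align_conditions", "compute_csd", "score_pairs", "write_scores", "read_scores"]

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "gene_a", "gene_b", "rho1", "rho2", "var1", "var2",
    "c_score", "s_score", "d_score",
]

# Pooled variances at or below this level are round-off, not sampling
# variability: a deterministically correlated pair (e.g. a duplicated gene)
# yields replicate correlations identical up to ~n*eps, i.e. a variance of
# ~1e-26, while any genuine bootstrap variance of a correlation is orders of
# magnitude larger.  Such pairs are unscored rather than ranked first.
VARIANCE_FLOOR = 1e-24


def align_conditions(
    summary1: CorrelationSummary, summary2: CorrelationSummary
) -> tuple[CorrelationSummary, CorrelationSummary]:
    """Restrict both condition summaries to their shared genes, in lexicographic order."""
    shared = sorted(set(summary1.gene_ids) & set(summary2.gene_ids))
    if len(shared) < 2:
        raise ValueError(
            f"conditions share only {len(shared)} gene(s); at least 2 are required"
        )

    def _restrict(s: CorrelationSummary) -> CorrelationSummary:
        pos = [s.gene_ids.index(g) for g in shared]
        idx = np.asarray(pos)
        return CorrelationSummary(
            gene_ids=tuple(shared),
            rho_mean=s.rho_mean[np.ix_(idx, idx)],
            rho_var=s.rho_var[np.ix_(idx, idx)],
            n_iterations=s.n_iterations,
            seed=s.seed,
            constant_genes=tuple(g for g in s.constant_genes if g in set(shared)),
        )

    return _restrict(summary1), _restrict(summary2)


def compute_csd(rho1, var1, rho2, var2):
    """Evaluate the C, S and D scores element-wise.

    Inputs broadcast like numpy arrays.  Pairs whose pooled variance
    ``var1 + var2`` is zero up to round-off (:data:`VARIANCE_FLOOR`), or
    whose correlation is undefined (NaN), get
    NaN in all three scores: an infinite score would let degenerate pairs
    (e.g. duplicated genes) outrank every genuine signal.

    Returns ``(C, S, D)`` arrays, all non-negative where defined.
    """
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    var1 = np.asarray(var1, dtype=float)
    var2 = np.asarray(var2, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(var1, initial=0.0) < 0 or np.nanmin(var2, initial=0.0) < 0:
            raise ValueError("negative bootstrap variance: upstream contract violated")

    denom_sq = var1 + var2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(denom_sq)
        c = np.abs(rho1 + rho2) / denom
        s = np.abs(np.abs(rho1) - np.abs(rho2)) / denom
        # the numerator is >= 0 analytically; the outer abs guards against -0 noise
        d = np.abs(np.abs(rho1) + np.abs(rho2) - np.abs(rho1 + rho2)) / denom
    undefined = (denom_sq <= VARIANCE_FLOOR) | ~np.isfinite(rho1) | ~np.isfinite(rho2)
    for arr in (c, s, d):
        if arr.ndim:
            arr[undefined] = np.nan
    if not c.ndim and undefined:
        c = s = d = np.float64(np.nan)
    return c, s, d


def score_pairs(
    summary1: CorrelationSummary, summary2: CorrelationSummary
) -> pd.DataFrame:
    """Build the full pair table of C/S/D scores for two aligned conditions.

    The summaries are aligned on their shared genes first.  The result has
    exactly ``n (n - 1) / 2`` rows (one per unordered pair, ``gene_a <
    gene_b`` lexicographically) with columns ``gene_a, gene_b, rho1, rho2,
    var1, var2, c_score, s_score, d_score``.  Unscored pairs (zero pooled
    variance or undefined correlation) keep their row with NaN scores and
    are counted in a warning.
    """
    s1, s2 = align_conditions(summary1, summary2)
    # object dtype: pandas re-sanitizes fixed-width string arrays at O(n_pairs)
    genes = np.asarray(s1.gene_ids, dtype=object)
    iu, ju = np.triu_indices(len(genes), k=1)

    rho1 = s1.rho_mean[iu, ju]
    rho2 = s2.rho_mean[iu, ju]
    var1 = s1.rho_var[iu, ju]
    var2 = s2.rho_var[iu, ju]
    c, s, d = compute_csd(rho1, var1, rho2, var2)

    n_unscored = int(np.isnan(c).sum())
    if n_unscored:
        logger.warning(
            "%d of %d gene pairs unscored (zero pooled variance or undefined correlation)",
            n_unscored, len(c),
        )

    # one pre-stacked float block avoids a per-column consolidation pass
    numeric = np.column_stack([rho1, rho2, var1, var2, c, s, d])
    out = pd.DataFrame(numeric, columns=SCORE_COLUMNS[2:], copy=False)
    out.insert(0, "gene_b", genes[ju])
    out.insert(0, "gene_a", genes[iu])
    return out


def write_scores(scores: pd.DataFrame, path, sep: str = "\t") -> None:
    """Dump the full pair table as delimited text, one row per unordered pair."""
    scores.to_csv(path, sep=sep, index=False, columns=SCORE_COLUMNS)


def read_scores(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype={"gene_a": str, "gene_b": str})
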