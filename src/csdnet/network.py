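"""Top-k edge selection and export of the typed C/S/D network.

The number of edges per link type is either given directly or derived from
an *importance level* ``p``: the fraction of all unordered gene pairs kept,
``k = floor(p * n_genes * (n_genes - 1) / 2)`` with a minimum of one edge.
Selection uses partial sorting (``numpy.argpartition``) so only the top of
the score distribution is ever ordered, with ties at the boundary broken by
gene labels for run-to-run reproducibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EdgeSet",
    "edges_from_importance",
    "select_top",
    "build_network",
    "write_network",
    "read_edge_list",
    "node_table",
]

logger = logging.getLogger(__name__)

LINK_TYPES = ("C", "S", "D")
_SCORE_COL = {"C": "c_score", "S": "s_score", "D": "d_score"}
EDGE_COLUMNS = ["gene_a", "gene_b", "score", "rho1", "rho2"]


@dataclass
class EdgeSet:
    """Selected edges per link type, each a frame sorted by descending score."""

    edges: dict[str, pd.DataFrame]
    n_requested: int
    importance_level: float | None = None

    def __post_init__(self):
        for lt, df in self.edges.items():
            if lt not in LINK_TYPES:
                raise ValueError(f"unknown link type {lt!r}")
            if (df["gene_a"] == df["gene_b"]).any():
                raise ValueError(f"self-loop in {lt}-edges")

    def to_networkx(self):
        """Combined multigraph; parallel edges carry distinct ``link_type``."""
        import networkx as nx

        g = nx.MultiGraph()
        for lt, df in self.edges.items():
            for row in df.itertuples(index=False):
                g.add_edge(row.gene_a, row.gene_b, link_type=lt,
                           score=row.score, rho1=row.rho1, rho2=row.rho2)
        return g


def edges_from_importance(n_genes: int, p: float) -> int:
    """Number of edges per link-type network at importance level ``p``.

    ``p`` is the fraction of the ``n_genes * (n_genes - 1) / 2`` unordered
    gene pairs retained; the count is floored, with a minimum of 1.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not (0 < p <= 1):
        raise ValueError(f"importance level must be in (0, 1], got {p}")
    n_pairs = n_genes * (n_genes - 1) // 2
    return max(1, math.floor(p * n_pairs))


def select_top(scores: pd.DataFrame, link_type: str, k: int) -> pd.DataFrame:
    """The ``k`` highest-scoring pairs of one link type, sorted descending.

    Equivalent to a full descending sort truncated at ``k`` — including at
    score ties, which are broken by ``(gene_a, gene_b)`` lexicographic order
    — but implemented with a partial partition so only the candidate top of
    the array is sorted.  Unscored (NaN) pairs are excluded beforehand; if
    fewer than ``k`` scored pairs exist, all are returned with a warning.
    """
    if link_type not in LINK_TYPES:
        raise ValueError(f"link type must be one of {LINK_TYPES}, got {link_type!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    col = _SCORE_COL[link_type]
    s = scores[col].to_numpy(dtype=float)
    valid = np.nonzero(np.isfinite(s))[0]
    if valid.size == 0:
        raise ValueError(f"no scored pairs available for {link_type}-selection")
    if valid.size <= k:
        if valid.size < k:
            logger.warning(
                "only %d scored pairs available for %s-selection (k=%d requested)",
                valid.size, link_type, k,
            )
        cand = valid
    else:
        sv = s[valid]
        part = np.argpartition(-sv, k - 1)
        threshold = sv[part[k - 1]]
        cand = valid[sv >= threshold]  # includes every tie at the boundary

    ga = scores["gene_a"].to_numpy()[cand].astype(str)
    gb = scores["gene_b"].to_numpy()[cand].astype(str)
    order = np.lexsort((gb, ga, -s[cand]))
    take = cand[order][:k]

    out = pd.DataFrame({
        "gene_a": scores["gene_a"].to_numpy()[take],
        "gene_b": scores["gene_b"].to_numpy()[take],
        "score": s[take],
        "rho1": scores["rho1"].to_numpy()[take],
        "rho2": scores["rho2"].to_numpy()[take],
    })
    return out.reset_index(drop=True)


def build_network(
    scores: pd.DataFrame,
    n_edges: int | None = None,
    importance_level: float | None = None,
    n_genes: int | None = None,
) -> EdgeSet:
    """Select the top pairs for each of C, S and D into an :class:`EdgeSet`.

    Exactly one of ``n_edges`` / ``importance_level`` must be given; the
    latter needs ``n_genes`` (or infers it from the pair count) to convert
    the level into an edge count.  The three selections are independent: a
    pair may appear under more than one link type.
    """
    if (n_edges is None) == (importance_level is None):
        raise ValueError("specify exactly one of n_edges and importance_level")
    if importance_level is not None:
        if n_genes is None:
            # invert n_pairs = n (n-1) / 2
            n_pairs = len(scores)
            n_genes = int(round((1 + math.sqrt(1 + 8 * n_pairs)) / 2))
        n_edges = edges_from_importance(n_genes, importance_level)
    edges = {lt: select_top(scores, lt, n_edges) for lt in LINK_TYPES}
    return EdgeSet(edges=edges, n_requested=n_edges, importance_level=importance_level)


def write_network(edge_set: EdgeSet, prefix, combined: bool = True) -> list[str]:
    """Write one TSV edge list per link type (``<prefix>_C.tsv`` etc.).

    With ``combined=True`` also writes ``<prefix>_CSD.tsv`` carrying a
    ``link_type`` column, suitable for import into graph tools; a pair
    selected under several types appears once per type there.  Returns the
    written paths.
    """
    paths = []
    for lt in LINK_TYPES:
        df = edge_set.edges.get(lt, pd.DataFrame(columns=EDGE_COLUMNS))
        path = f"{prefix}_{lt}.tsv"
        df.to_csv(path, sep="\t", index=False, columns=EDGE_COLUMNS)
        paths.append(path)
    if combined:
        frames = []
        for lt in LINK_TYPES:
            df = edge_set.edges.get(lt)
            if df is not None and len(df):
                frames.append(df.assign(link_type=lt))
        combined_df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=EDGE_COLUMNS + ["link_type"])
        )
        path = f"{prefix}_CSD.tsv"
        combined_df.to_csv(path, sep="\t", index=False,
                           columns=EDGE_COLUMNS + ["link_type"])
        paths.append(path)
    return paths


def read_edge_list(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype={"gene_a": str, "gene_b": str})


def node_table(edge_set: EdgeSet) -> pd.DataFrame:
    """Per-gene degree within each link-type network."""
    genes: dict[str, dict[str, int]] = {}
    for lt, df in edge_set.edges.items():
        for col in ("gene_a", "gene_b"):
            for g in df[col]:
                genes.setdefault(g, {t: 0 for t in LINK_TYPES})[lt] += 1
    rows = [
        {"gene": g, **{f"degree_{t}": counts[t] for t in LINK_TYPES}}
        for g, counts in sorted(genes.items())
    ]
    return pd.DataFrame(rows, columns=["gene"] + [f"degree_{t}" for t in LINK_TYPES])
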