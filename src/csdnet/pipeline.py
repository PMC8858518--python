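"""The three-step differential co-expression pipeline.

Step 1 bootstraps the all-pairs Spearman correlations of each condition,
step 2 combines the two summaries into C/S/D scores, and step 3 selects the
top-scoring pairs per link type and writes the network files.  Step 1
dominates the runtime on any realistically sized input; steps 2 and 3 are a
vectorized pass over the pair table and a partial sort.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from . import io, network, scoring
from .correlation import bootstrap_correlation
from .network import EdgeSet

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``importance_level`` (fraction of all pairs kept per
    link type) and ``n_edges`` (explicit per-type edge count) must be set.
    Condition 1 bootstraps with ``seed`` and condition 2 with ``seed + 1``
    so the two replicate streams are distinct but fully determined.
    ``threads`` > 1 lets the two conditions run concurrently; results are
    bit-identical at any thread count because each condition owns its seed.
    """

    cond1_path: str
    cond2_path: str
    output_prefix: str
    n_iterations: int = 1000
    importance_level: float | None = None
    n_edges: int | None = None
    seed: int = 0
    threads: int = 1
    transpose_input: bool = False
    dump_all_scores: bool = False
    sep: str = "\t"

    def __post_init__(self):
        if (self.importance_level is None) == (self.n_edges is None):
            raise ValueError("set exactly one of importance_level and n_edges")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


def run_pipeline(config: RunConfig) -> tuple[EdgeSet, dict]:
    """Execute the pipeline and write the network files and run report.

    Returns the selected :class:`EdgeSet` and the run-report dictionary
    (also written as ``<output_prefix>_report.txt`` in ``key<TAB>value``
    form).
    """
    report: dict = {"seed": config.seed, "n_iterations": config.n_iterations}

    t0 = time.perf_counter()
    expr1 = io.read_expression(config.cond1_path, sep=config.sep,
                               transpose=config.transpose_input, name="condition 1")
    expr2 = io.read_expression(config.cond2_path, sep=config.sep,
                               transpose=config.transpose_input, name="condition 2")
    report["n_samples_1"], report["n_genes_1"] = expr1.shape
    report["n_samples_2"], report["n_genes_2"] = expr2.shape
    logger.info("condition 1: %d samples x %d genes; condition 2: %d samples x %d genes",
                *expr1.shape, *expr2.shape)

    seed1, seed2 = config.seed, config.seed + 1

    def _boot(expr, seed):
        return bootstrap_correlation(expr, n_iterations=config.n_iterations, seed=seed)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=2) as pool:
            f1 = pool.submit(_boot, expr1, seed1)
            f2 = pool.submit(_boot, expr2, seed2)
            summary1, summary2 = f1.result(), f2.result()
    else:
        summary1, summary2 = _boot(expr1, seed1), _boot(expr2, seed2)
    report["seed_cond1"], report["seed_cond2"] = seed1, seed2
    step1 = time.perf_counter()
    report["step1_seconds"] = step1 - t0

    scores = scoring.score_pairs(summary1, summary2)
    n_shared = len(set(summary1.gene_ids) & set(summary2.gene_ids))
    report["n_shared_genes"] = n_shared
    report["n_pairs"] = len(scores)
    report["n_unscored_pairs"] = int(scores["c_score"].isna().sum())
    step2 = time.perf_counter()
    report["step2_seconds"] = step2 - step1
    logger.info("%d shared genes, %d pairs (%d unscored)",
                n_shared, report["n_pairs"], report["n_unscored_pairs"])

    edge_set = network.build_network(
        scores,
        n_edges=config.n_edges,
        importance_level=config.importance_level,
        n_genes=n_shared,
    )
    report["n_edges_requested"] = edge_set.n_requested
    paths = network.write_network(edge_set, config.output_prefix)
    if config.dump_all_scores:
        scores_path = f"{config.output_prefix}_scores.tsv"
        scoring.write_scores(scores, scores_path)
        paths.append(scores_path)
    step3 = time.perf_counter()
    report["step3_seconds"] = step3 - step2
    report["total_seconds"] = step3 - t0

    report_path = f"{config.output_prefix}_report.txt"
    with open(report_path, "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")
    logger.info("wrote %s", ", ".join(paths + [report_path]))
    return edge_set, report
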