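"""Synthetic two-condition expression data with planted co-expression structure.

Background genes are independent standard normals.  A *planted pair* is a
pair of genes drawn from a bivariate normal whose Pearson parameter is set,
through the bivariate-normal relation

    rho_S = (6 / pi) * arcsin(rho_P / 2)   <=>   rho_P = 2 * sin(pi * rho_S / 6),

so that the population Spearman correlation equals the requested target in
each condition.  Planting a pair with targets (0.9, 0.9) yields a conserved
(C) pair, (0.9, 0.0) a condition-specific (S) pair, and (0.9, -0.9) a
sign-flipped differentiated (D) pair.  Independent Gaussian measurement
noise of standard deviation ``noise_sd`` is added on top, attenuating the
planted correlations slightly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import scoring
from .correlation import bootstrap_correlation
from .network import LINK_TYPES, select_top

__all__ = [
    "SyntheticSpec",
    "spearman_to_pearson",
    "generate",
    "write_fixture_pair",
    "default_fixture_spec",
    "seed_overlap_experiment",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson parameter of a bivariate normal with population Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    ``planted_pairs`` is a list of ``(pair_index, target_rho_1,
    target_rho_2)`` entries; pair ``i`` occupies the dedicated gene columns
    ``2 i`` and ``2 i + 1`` so planted pairs are always disjoint.  Targets
    are population Spearman correlations, strictly inside (-1, 1).
    ``noise_sd`` is the standard deviation of additive Gaussian measurement
    noise (expression units; the latent signals have unit variance).
    """

    n_samples_1: int
    n_samples_2: int
    n_genes: int
    planted_pairs: list[tuple[int, float, float]] = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples_1, self.n_samples_2) < 3:
            raise ValueError("each condition needs at least 3 samples")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        seen = set()
        for idx, t1, t2 in self.planted_pairs:
            if idx in seen:
                raise ValueError(f"pair index {idx} planted twice")
            seen.add(idx)
            if 2 * idx + 1 >= self.n_genes:
                raise ValueError(
                    f"pair index {idx} needs gene columns {2 * idx} and "
                    f"{2 * idx + 1} but only {self.n_genes} genes exist"
                )
            if not (abs(t1) < 1 and abs(t2) < 1):
                raise ValueError(f"targets for pair {idx} must satisfy |target| < 1")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def pair_genes(self, pair_index: int) -> tuple[str, str]:
        ids = self.gene_ids()
        return ids[2 * pair_index], ids[2 * pair_index + 1]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["planted_pairs"] = [tuple(p) for p in raw.get("planted_pairs", [])]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "n_samples_1": self.n_samples_1,
            "n_samples_2": self.n_samples_2,
            "n_genes": self.n_genes,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _one_condition(spec: SyntheticSpec, n: int, targets: dict[int, float],
                   rng: np.random.Generator, prefix: str) -> pd.DataFrame:
    X = rng.standard_normal((n, spec.n_genes))
    for idx, t in targets.items():
        a, b = 2 * idx, 2 * idx + 1
        rho_p = spearman_to_pearson(t)
        X[:, b] = rho_p * X[:, a] + np.sqrt(1.0 - rho_p**2) * X[:, b]
    X += rng.normal(0.0, spec.noise_sd, size=X.shape)
    samples = [f"{prefix}S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(X, index=samples, columns=spec.gene_ids())


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the paired (condition 1, condition 2) expression matrices.

    Deterministic for a fixed ``spec.seed``; different seeds redraw from the
    same population structure.
    """
    rng = np.random.default_rng(spec.seed)
    t1 = {idx: t for idx, t, _ in spec.planted_pairs}
    t2 = {idx: t for idx, _, t in spec.planted_pairs}
    expr1 = _one_condition(spec, spec.n_samples_1, t1, rng, "C1")
    expr2 = _one_condition(spec, spec.n_samples_2, t2, rng, "C2")
    return expr1, expr2


def default_fixture_spec(seed: int = 0) -> SyntheticSpec:
    """A small paired dataset (50 genes, 40 + 30 samples) for walk-throughs.

    Plants one strong pair of each kind: conserved (0.8, 0.8), specific
    (0.8, 0.0) and differentiated (0.8, -0.8).
    """
    return SyntheticSpec(
        n_samples_1=40,
        n_samples_2=30,
        n_genes=50,
        planted_pairs=[(0, 0.8, 0.8), (1, 0.8, 0.0), (2, 0.8, -0.8)],
        noise_sd=0.1,
        seed=seed,
    )


def overlap_benchmark_spec(seed: int = 11) -> SyntheticSpec:
    """Desk-scale dataset for the seed-robustness experiment.

    Plants 20 pairs of each kind (conserved, specific, differentiated) with
    strengths tapered from 0.3 to 0.85 among 200 genes, 100 samples per
    condition.  The taper puts planted pairs on both sides of any top-k
    cutoff, so the overlap across bootstrap seeds is informative rather
    than saturating at 1.
    """
    strengths = np.linspace(0.3, 0.85, 20)
    pairs: list[tuple[int, float, float]] = []
    i = 0
    for t in strengths:
        pairs.append((i, float(t), float(t))); i += 1
        pairs.append((i, float(t), 0.0)); i += 1
        pairs.append((i, float(t), -float(t))); i += 1
    return SyntheticSpec(
        n_samples_1=100, n_samples_2=100, n_genes=200,
        planted_pairs=pairs, noise_sd=0.1, seed=seed,
    )


def write_fixture_pair(spec: SyntheticSpec, prefix) -> tuple[str, str]:
    """Generate and write the two condition matrices as TSV; returns the paths."""
    from .io import write_expression

    expr1, expr2 = generate(spec)
    p1, p2 = f"{prefix}_cond1.tsv", f"{prefix}_cond2.tsv"
    write_expression(expr1, p1)
    write_expression(expr2, p2)
    return p1, p2


def seed_overlap_experiment(
    spec: SyntheticSpec,
    n_parallels: int = 10,
    n_iterations: int = 1000,
    max_rank: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Robustness of the top-ranked edges across bootstrap seeds.

    One dataset is generated from ``spec``; the full scoring pipeline is run
    ``n_parallels`` times with different bootstrap seeds.  For each link
    type and each rank cutoff ``r <= max_rank`` the returned frame holds the
    fraction ``|intersection of the top-r pairs across all parallels| / r``
    — the proportion of the highest ranking gene pairs shared by every
    parallel.  A single parallel gives a fraction of 1 everywhere.
    """
    if n_parallels < 1:
        raise ValueError("n_parallels must be >= 1")
    expr1, expr2 = generate(spec)

    rankings: dict[str, list[list[tuple[str, str]]]] = {lt: [] for lt in LINK_TYPES}
    for j in range(n_parallels):
        s1 = bootstrap_correlation(expr1, n_iterations=n_iterations,
                                   seed=base_seed + 2 * j)
        s2 = bootstrap_correlation(expr2, n_iterations=n_iterations,
                                   seed=base_seed + 2 * j + 1)
        scores = scoring.score_pairs(s1, s2)
        for lt in LINK_TYPES:
            top = select_top(scores, lt, max_rank)
            rankings[lt].append(list(zip(top["gene_a"], top["gene_b"])))

    records = []
    for r in range(1, max_rank + 1):
        row = {"rank": r}
        for lt in LINK_TYPES:
            shared = set(rankings[lt][0][:r])
            for ranked in rankings[lt][1:]:
                shared &= set(ranked[:r])
            row[lt] = len(shared) / r
        records.append(row)
    return pd.DataFrame(records).set_index("rank")
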