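"""Empirical false-positive S-Score thresholds from random background queries.

For a fixed (genome, algorithm, score, region setting) hit index, many random
gene sets are drawn and each is run through the enrichment engine; the
S-Score of the top-ranking motif in each run forms the null distribution of
false-positive S-Scores. The 5% and 1% thresholds are its empirical 95th and
99th percentiles: a real query whose top motif exceeds the 5% threshold scores
higher than 95% of random gene sets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfbskit.enrichment import enrichment_stats
from tfbskit.hit_index import HitIndex


@dataclass(frozen=True)
class CalibrationConfig:
    n_sets: int = 10000
    set_size: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_sets < 100:
            raise ValueError("n_sets must be >= 100")
        if self.set_size < 1:
            raise ValueError("set_size must be positive")


@dataclass(frozen=True)
class ThresholdTable:
    setting: str
    s5: float  # 95th percentile of top null S-Scores (5% threshold)
    s1: float  # 99th percentile (1% threshold)
    n_sets: int
    set_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "setting": self.setting,
                    "s5": self.s5,
                    "s1": self.s1,
                    "n_sets": self.n_sets,
                    "set_size": self.set_size,
                    "seed": self.seed,
                }
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ThresholdTable":
        row = pd.read_csv(path, sep="\t").iloc[0]
        return cls(
            setting=str(row["setting"]),
            s5=float(row["s5"]),
            s1=float(row["s1"]),
            n_sets=int(row["n_sets"]),
            set_size=int(row["set_size"]),
            seed=int(row["seed"]),
        )


def top_scores_null(
    index: HitIndex, n_sets: int, set_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Top S-Score of each of ``n_sets`` uniform random gene sets.

    Gene sets are drawn without replacement within a set, independently across
    sets. A run in which no motif fires at all records the sentinel 0. Uses
    the same vectorized statistics as :func:`tfbskit.enrichment.enrich`.
    """
    M = index.M
    if set_size > M:
        raise ValueError(f"set_size {set_size} exceeds genome size {M}")
    motif_ids = index.motif_ids
    gene_pos = {g: i for i, g in enumerate(index.genes)}
    # membership matrix: genes x motifs
    member = np.zeros((M, len(motif_ids)), dtype=bool)
    for k, m in enumerate(motif_ids):
        idx = [gene_pos[g] for g in index.motif_genes[m]]
        member[idx, k] = True
    N = member.sum(axis=0).astype(np.int64)
    tops = np.empty(n_sets)
    for i in range(n_sets):
        sample = rng.choice(M, size=set_size, replace=False)
        x = member[sample].sum(axis=0)
        _P, _FE, S = enrichment_stats(x, set_size, N, M)
        finite = S[~np.isnan(S)]
        tops[i] = finite.max() if finite.size else 0.0
    return tops


def calibrate(index: HitIndex, cfg: CalibrationConfig) -> ThresholdTable:
    """Empirical 5% / 1% S-Score thresholds for one hit index.

    Percentiles use linear interpolation between order statistics; the seed
    is recorded in the output for reproducibility.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    tops = top_scores_null(index, cfg.n_sets, cfg.set_size, rng)
    s5, s1 = np.percentile(tops, [95.0, 99.0], method="linear")
    return ThresholdTable(
        setting=index.setting,
        s5=float(s5),
        s1=float(s1),
        n_sets=cfg.n_sets,
        set_size=cfg.set_size,
        seed=cfg.rng_seed,
    )
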