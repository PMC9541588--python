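"""Evaluation harness: target lists from peak tables, normalized ranking of
the expected motif, and ROC/AUC over positive vs negative query lists.

A benchmark case pairs a positive query (subsampled TF-bound genes) with a
negative query (subsampled non-bound genes). Both are run through the
enrichment engine; the rank of the expected motif, normalized to [0, 1]
(0 = top of the table, 1 = absent), is the score swept to build ROC curves.
Smaller r counts as "detected", so a perfect setting separates positive
cases (r near 0) from negative ones (r near 1) with AUC 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tfbskit.enrichment import EnrichmentTable, enrich
from tfbskit.hit_index import HitIndex

SUBSAMPLE_SIZES = (50, 100, 250, 500)


@dataclass(frozen=True)
class BenchmarkCase:
    tf_name: str
    expected_motif_ids: tuple
    positive_genes: tuple
    negative_genes: tuple
    subsample_size: int
    replicate: int
    rng_seed: int

    def __post_init__(self):
        if set(self.positive_genes) & set(self.negative_genes):
            raise ValueError("positive and negative lists overlap")


# -- target-list construction -------------------------------------------------


def targets_from_peaks(
    peaks: pd.DataFrame,
    upstream: int = 3000,
    downstream: int = 1000,
    top: int = 500,
) -> list[str]:
    """Target genes from a gene-relative peak table.

    ``peaks`` needs columns ``gene_id``, ``rel_start``, ``rel_end`` (bp
    relative to the TSS), ``qvalue``, and optionally ``gene_length`` (TES
    offset; 0 if absent). A gene qualifies when at least one peak overlaps
    [-upstream, gene_length + downstream]; the ``top`` genes by ascending
    minimum q-value are kept.
    """
    required = {"gene_id", "rel_start", "rel_end", "qvalue"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    glen = peaks["gene_length"] if "gene_length" in peaks.columns else 0
    ok = (peaks["rel_end"] >= -upstream) & (peaks["rel_start"] <= glen + downstream)
    per_gene = (
        peaks[ok]
        .groupby("gene_id")["qvalue"]
        .min()
        .sort_values(kind="mergesort")
    )
    return [str(g) for g in per_gene.index[:top]]


def make_cases(
    tf_name: str,
    expected_motif_ids: Sequence[str],
    positive_pool: Sequence[str],
    negative_pool: Sequence[str],
    sizes: Sequence[int] = SUBSAMPLE_SIZES,
    n_replicates: int = 10,
    rng_seed: int = 0,
) -> list[BenchmarkCase]:
    """Subsampled positive/negative case grid (sizes x replicates).

    Negative lists are sampled to the same size as positives.
    """
    rng = np.random.default_rng(rng_seed)
    cases = []
    for size in sizes:
        k = min(size, len(positive_pool), len(negative_pool))
        for rep in range(1, n_replicates + 1):
            seed = int(rng.integers(2**31 - 1))
            sub = np.random.default_rng(seed)
            pos = tuple(sub.choice(list(positive_pool), size=k, replace=False))
            neg = tuple(sub.choice(list(negative_pool), size=k, replace=False))
            cases.append(
                BenchmarkCase(
                    tf_name=tf_name,
                    expected_motif_ids=tuple(expected_motif_ids),
                    positive_genes=pos,
                    negative_genes=neg,
                    subsample_size=size,
                    replicate=rep,
                    rng_seed=seed,
                )
            )
    return cases


# -- ranking and ROC ----------------------------------------------------------


def rank_of_expected(
    table: EnrichmentTable, expected_motif_ids: Sequence[str], sort_key: str = "s_score"
) -> float:
    """Normalized rank r in [0, 1] of the best expected motif.

    r = (best rank - 1) / (table length - 1) with ties sharing the mean rank;
    an absent expected motif scores the defined worst case r = 1.
    """
    if sort_key not in {"s_score", "FDR"}:
        raise ValueError(f"unknown sort key {sort_key!r}")
    df = table.df
    if df.empty:
        raise ValueError("empty enrichment table")
    ascending = sort_key == "FDR"
    ranks = df[sort_key].rank(method="average", ascending=ascending)
    mask = df["motif_id"].isin(set(expected_motif_ids))
    if not mask.any():
        return 1.0
    best = float(ranks[mask].min())
    if len(df) == 1:
        return 0.0
    return (best - 1.0) / (len(df) - 1.0)


def roc_auc(positive_rs, negative_rs) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC from normalized ranks (smaller r = detected).

    The threshold sweep declares a case "detected" when r <= t; the AUC
    (trapezoid) equals the normalized Mann-Whitney U statistic of
    negative-vs-positive ranks, with ties credited 1/2.
    """
    pos = np.asarray(positive_rs, dtype=float)
    neg = np.asarray(negative_rs, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both rank lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos <= t).mean()))
        fpr.append(float((neg <= t).mean()))
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr.append(1.0)
        fpr.append(1.0)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    return curve, auc


# -- the grid -----------------------------------------------------------------


def run_grid(
    cases: Sequence[BenchmarkCase],
    indices: Mapping[str, HitIndex],
    metadata: pd.DataFrame | None = None,
    sort_keys: Sequence[str] = ("s_score", "FDR"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every case against every setting; rank under every sort key.

    Both sort keys are evaluated from the same enrichment tables (no
    re-scan). Returns (tidy per-case table, summary AUC table per
    (setting, sort_key, subsample size)).
    """
    rows = []
    for setting, index in indices.items():
        for case in cases:
            tables = {
                "positive": enrich(list(case.positive_genes), index, metadata),
                "negative": enrich(list(case.negative_genes), index, metadata),
            }
            for label, table in tables.items():
                for key in sort_keys:
                    rows.append(
                        {
                            "tf_name": case.tf_name,
                            "setting": setting,
                            "sort_key": key,
                            "subsample_size": case.subsample_size,
                            "replicate": case.replicate,
                            "label": label,
                            "r": rank_of_expected(
                                table, case.expected_motif_ids, key
                            ),
                        }
                    )
    tidy = pd.DataFrame(rows)
    summaries = []
    for (setting, key, size), sub in tidy.groupby(
        ["setting", "sort_key", "subsample_size"]
    ):
        pos = sub[sub["label"] == "positive"]["r"].to_numpy()
        neg = sub[sub["label"] == "negative"]["r"].to_numpy()
        _curve, auc = roc_auc(pos, neg)
        summaries.append(
            {
                "setting": setting,
                "sort_key": key,
                "subsample_size": size,
                "n_cases": len(pos),
                "auc": auc,
            }
        )
    return tidy, pd.DataFrame(summaries).sort_values(
        ["setting", "sort_key", "subsample_size"], kind="mergesort"
    ).reset_index(drop=True)
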