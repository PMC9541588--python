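"""Per-motif enrichment statistics for a query gene list.

For a genome of M genes in which N carry >= 1 hit of a motif, and a query of
n genes of which x carry a hit, enrichment is measured by:

* P — upper-tail hypergeometric p-value, P(X >= x) with X ~ Hypergeom(M, N, n)
  (``mode="pmf"`` gives the single mass at x instead);
* FDR — Benjamini-Hochberg adjusted P across all motifs tested in one run;
* FE — log2 fold enrichment, log2((x/n) / (N/M));
* S-Score — the ranking statistic, (-log10 P) * FE.

Results tables sort by S-Score descending (ties by P ascending then motif id)
and carry the motif metadata (TF, family, subfamily, source species) through
to the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tfbskit.hit_index import HitIndex

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # underflow floor for -log10

RESULT_COLUMNS = [
    "motif_id",
    "tf_name",
    "family",
    "subfamily",
    "source_species",
    "x",
    "n",
    "N",
    "M",
    "FE",
    "P",
    "FDR",
    "s_score",
    "passes_5pct",
    "passes_1pct",
]


def hypergeom_p(x: int, M: int, n: int, N: int, mode: str = "tail") -> float:
    """Hypergeometric enrichment p-value.

    ``mode="tail"`` (default): P(X >= x); ``mode="pmf"``: P(X = x).
    """
    if not (0 <= x <= min(n, N)) or n > M or N > M:
        raise ValueError(f"impossible configuration x={x}, M={M}, n={n}, N={N}")
    if mode == "tail":
        p = float(hypergeom.sf(x - 1, M, N, n))
    elif mode == "pmf":
        p = float(hypergeom.pmf(x, M, N, n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return min(max(p, 0.0), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_enrichment(x: int, n: int, N: int, M: int) -> float:
    """log2((x/n) / (N/M)); requires x, n, N, M > 0."""
    if min(x, n, N, M) <= 0:
        raise ValueError("fold enrichment requires positive x, n, N, M")
    return float(np.log2((x / n) / (N / M)))


def s_score(P: float, FE: float) -> float:
    """Significance Score: (-log10 P) * FE, with P floored at 1e-300."""
    return float(-np.log10(max(P, P_FLOOR)) * FE)


def enrichment_stats(x, n, N, M):
    """Vectorized (P, FE, S) for arrays of x and N at fixed n, M.

    Entries with x == 0 get P = 1, FE = nan, S = nan; shared by the
    enrichment table and the calibration resampler so both paths agree
    exactly.
    """
    x = np.asarray(x, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    P = hypergeom.sf(x - 1, M, N, n)
    P = np.clip(P, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        FE = np.where(
            (x > 0) & (N > 0), np.log2((x / n) / np.maximum(N, 1) * M), np.nan
        )
    S = np.where(np.isnan(FE), np.nan, -np.log10(np.maximum(P, P_FLOOR)) * FE)
    return P, FE, S


@dataclass
class EnrichmentTable:
    """Sorted per-motif enrichment results for one query run."""

    df: pd.DataFrame
    query_genes: list
    setting: str = ""
    n_zero_hit_motifs: int = 0  # motifs with x = 0, omitted from df

    def __len__(self) -> int:
        return len(self.df)

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.df.head(k)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrich(
    query: Sequence[str],
    index: HitIndex,
    metadata: pd.DataFrame | None = None,
    thresholds=None,
) -> EnrichmentTable:
    """Per-motif enrichment of a query gene list against a hit index.

    Unknown query IDs are dropped (logged); motifs with x = 0 are omitted
    from the table (counted in ``n_zero_hit_motifs``). ``thresholds`` is an
    optional :class:`~tfbskit.calibration.ThresholdTable` that sets the
    5% / 1% pass flags.
    """
    kept = index.filter_query(query)
    if not kept:
        raise ValueError("no recognized gene IDs in the query")
    n, M = len(kept), index.M
    query_set = set(kept)
    motif_ids = index.motif_ids
    x = np.array(
        [len(query_set & index.motif_genes[m]) for m in motif_ids], dtype=np.int64
    )
    N = np.array([index.N(m) for m in motif_ids], dtype=np.int64)
    keep = x > 0
    P, FE, S = enrichment_stats(x[keep], n, N[keep], M)
    sub_ids = [m for m, k in zip(motif_ids, keep) if k]
    df = pd.DataFrame(
        {
            "motif_id": sub_ids,
            "x": x[keep],
            "n": n,
            "N": N[keep],
            "M": M,
            "FE": FE,
            "P": P,
            "FDR": bh_fdr(P) if len(P) else np.array([]),
            "s_score": S,
        }
    )
    meta_cols = ["tf_name", "family", "subfamily", "source_species"]
    if metadata is not None:
        meta = metadata.set_index("motif_id")
        for c in meta_cols:
            df[c] = df["motif_id"].map(meta[c]).fillna("")
    else:
        for c in meta_cols:
            df[c] = ""
    s5 = s1 = np.inf
    if thresholds is not None:
        s5, s1 = thresholds.s5, thresholds.s1
    df["passes_5pct"] = df["s_score"] > s5
    df["passes_1pct"] = df["s_score"] > s1
    df = df.sort_values(
        ["s_score", "P", "motif_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return EnrichmentTable(
        df=df[RESULT_COLUMNS],
        query_genes=kept,
        setting=index.setting,
        n_zero_hit_motifs=int((~keep).sum()),
    )


# -- hit coordinate report ----------------------------------------------------


def hit_report(
    query: Sequence[str],
    motif_id: str,
    hits: pd.DataFrame,
    upstream_len: int,
    bin_size: int = 100,
) -> dict:
    """TIC-relative hit coordinates per query gene plus a position histogram.

    Histogram bins are fixed ``bin_size``-bp windows covering
    [-upstream_len, max offset]; an empty hit set yields an empty report.
    """
    query_set = set(query)
    sub = hits[(hits["motif_id"] == motif_id) & (hits["gene_id"].isin(query_set))]
    coords = {
        str(g): sorted(int(o) for o in s["offset"])
        for g, s in sub.groupby("gene_id")
    }
    if len(sub):
        hi = max(int(sub["offset"].max()) + 1, -upstream_len + bin_size)
        edges = np.arange(
            -upstream_len, hi + bin_size, bin_size, dtype=np.int64
        )
        counts, edges = np.histogram(sub["offset"], bins=edges)
    else:
        edges, counts = np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return {
        "motif_id": motif_id,
        "coordinates": coords,
        "bin_edges": edges,
        "bin_counts": counts,
    }


# -- family-level aggregation -------------------------------------------------

MAX_HEATMAP_TABLES = 20


def aggregate_families(
    tables: Sequence[EnrichmentTable],
    level: str = "family",
    metric: str = "s_score",
) -> pd.DataFrame:
    """Mean metric per family/subfamily/motif across up to 20 result tables.

    Returns a (group x table) matrix suitable for heatmap export; groups
    absent from a table are NaN.
    """
    if not tables:
        raise ValueError("need at least one table")
    if len(tables) > MAX_HEATMAP_TABLES:
        raise ValueError(f"at most {MAX_HEATMAP_TABLES} tables supported")
    if level not in {"family", "subfamily", "motif"}:
        raise ValueError(f"unknown level {level!r}")
    if metric not in {"P", "FE", "s_score"}:
        raise ValueError(f"unknown metric {metric!r}")
    key = "motif_id" if level == "motif" else level
    cols = {}
    for i, t in enumerate(tables):
        name = t.setting or f"table_{i + 1}"
        col = t.df.groupby(key)[metric].mean()
        cols[f"{name}#{i + 1}"] = col
    return pd.DataFrame(cols)
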