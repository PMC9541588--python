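"""PWM mapping onto regulatory regions.

Two algorithms are provided:

* **fimo mode** — a log-odds scanner in the style of FIMO: every window is
  scored on both strands against an order-0 background, an exact null
  distribution of the (discretized) score is computed by dynamic programming,
  and windows whose best-strand p-value is at most ``10**-s`` are reported
  (``s`` is the -log10 p score threshold). With ``max_strand`` only the better
  strand is reported per position.

* **cluster mode** — a dense-cluster scorer in the style of Cluster-Buster:
  candidate matches with log-odds score >= ``m`` are chained by a linear DP
  where a chain's score is the sum of its non-overlapping match scores minus a
  gap cost of ``d / g`` bits for ``d`` bp between consecutive matches
  (``g`` = expected gap). Maximal chains scoring >= ``c`` are clusters, and
  each constituent match becomes a hit attributed to its PWM.

Windows containing N are skipped in both modes. Hit coordinates are signed
TIC-relative offsets of the window's 5'-most base in gene orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from tfbskit.motifs import ALPHABET, LogOddsMatrix
from tfbskit.regions import RegulatoryRegion

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to integer codes A=0 C=1 G=2 T=3, other=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScanConfig:
    algorithm: str = "fimo"  # 'fimo' or 'cluster'
    fimo_score_threshold: float = 4.0  # s: hits need p <= 10**-s
    cluster_score_threshold: float = 5.0  # c: minimum cluster score
    motif_score_threshold: float = 5.0  # m: minimum match score inside clusters
    gap_param: float = 35.0  # g: expected inter-match gap (bp)
    pseudocount: float = 0.1  # fimo mode; cluster mode uses 0
    both_strands: bool = True
    max_strand: bool = True  # report only the better strand per position
    precision: int = 1000  # discretization bins for the exact p-value DP

    def __post_init__(self):
        if self.algorithm not in {"fimo", "cluster"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.fimo_score_threshold <= 0 or self.cluster_score_threshold <= 0:
            raise ValueError("score thresholds must be positive")
        if self.motif_score_threshold <= 0:
            raise ValueError("motif score threshold must be positive")

    @property
    def score(self) -> float:
        return (
            self.fimo_score_threshold
            if self.algorithm == "fimo"
            else self.cluster_score_threshold
        )

    def key(self) -> str:
        return f"{self.algorithm}{self.score:g}"


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    segment: str
    offset: int  # TIC-relative start (signed; negative upstream)
    strand: str
    score: float  # motif log-odds score (bits)
    pvalue: float = float("nan")  # fimo mode
    cluster_score: float = float("nan")  # cluster mode


HIT_COLUMNS = [
    "gene_id",
    "motif_id",
    "segment",
    "offset",
    "strand",
    "score",
    "pvalue",
    "cluster_score",
]


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    df = pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)
    return df.sort_values(["gene_id", "offset", "motif_id"], kind="mergesort").reset_index(
        drop=True
    )


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- exact score distribution -------------------------------------------------


class ScoreDistribution:
    """Exact null distribution of a discretized PWM log-odds score.

    Scores are discretized per cell to integer offsets from the per-column
    minimum at resolution ``delta = total score range / precision``; the
    distribution of the integer window score of a random W-mer under the
    order-0 background is then an exact column-wise convolution.
    """

    def __init__(self, lom: LogOddsMatrix, precision: int = 1000):
        scores = lom.scores
        if not np.isfinite(scores).all():
            raise ValueError(
                "log-odds matrix contains -inf; use a pseudocount > 0 for "
                "exact p-value computation"
            )
        mins = scores.min(axis=1)
        total_range = float((scores.max(axis=1) - mins).sum())
        self.delta = total_range / precision if total_range > 0 else 1.0
        self.min_total = float(mins.sum())
        self.int_matrix = np.rint((scores - mins[:, None]) / self.delta).astype(
            np.int64
        )
        bg = lom.background
        dist = np.zeros(int(self.int_matrix.max(axis=1).sum()) + 1)
        dist[0] = 1.0
        top = 0
        for j in range(scores.shape[0]):
            new = np.zeros(top + int(self.int_matrix[j].max()) + 1)
            for b in range(4):
                k = int(self.int_matrix[j, b])
                new[k : k + top + 1] += bg[b] * dist[: top + 1]
            dist = new
            top = len(dist) - 1
        # tail[i] = P(integer score >= i)
        self.tail = np.cumsum(dist[::-1])[::-1]
        self.tail = np.minimum(self.tail, 1.0)

    def raw_score(self, int_score) -> np.ndarray:
        return self.min_total + np.asarray(int_score) * self.delta

    def pvalue(self, int_score) -> np.ndarray:
        """P(score >= int_score) for integer scores (clipped to the support)."""
        i = np.clip(np.asarray(int_score, dtype=np.int64), 0, len(self.tail))
        out = np.where(i >= len(self.tail), 0.0, self.tail[np.minimum(i, len(self.tail) - 1)])
        return np.where(np.asarray(int_score) >= len(self.tail), 0.0, out)

    def min_int_for_pvalue(self, p: float) -> int:
        """Smallest integer score t with P(score >= t) <= p."""
        idx = np.searchsorted(-self.tail, -p, side="left")
        return int(idx)


# -- shared window scoring ----------------------------------------------------


def _window_int_scores(enc: np.ndarray, int_matrix: np.ndarray):
    """Integer window scores and N-validity for every window start."""
    W = int_matrix.shape[0]
    L = len(enc) - W + 1
    if L <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(L, dtype=np.int64)
    valid = np.ones(L, dtype=bool)
    for j in range(W):
        col = enc[j : j + L]
        valid &= col != 4
        scores += int_matrix[j, np.minimum(col, 3)]
    return scores, valid


def _window_float_scores(enc: np.ndarray, matrix: np.ndarray):
    W = matrix.shape[0]
    L = len(enc) - W + 1
    if L <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(L)
    valid = np.ones(L, dtype=bool)
    padded = np.hstack([matrix, np.full((W, 1), -np.inf)])
    for j in range(W):
        col = enc[j : j + L]
        valid &= col != 4
        with np.errstate(invalid="ignore"):
            scores += padded[j, col]
    return scores, valid


def _rc_int_matrix(int_matrix: np.ndarray) -> np.ndarray:
    return int_matrix[::-1, [3, 2, 1, 0]].copy()


# -- fimo mode ----------------------------------------------------------------


def scan_fimo(
    region: RegulatoryRegion,
    lom: LogOddsMatrix,
    cfg: ScanConfig,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan one region with one motif; report hits with p <= 10**-s."""
    if dist is None:
        dist = ScoreDistribution(lom, cfg.precision)
    enc = encode_sequence(region.sequence)
    offs = region.offsets()
    labels = region.segment_labels()
    rows = _scan_fimo_encoded(enc, lom, cfg, dist)
    return [
        MotifHit(
            gene_id=region.gene_id,
            motif_id=lom.motif_id,
            segment=str(labels[pos]),
            offset=int(offs[pos]),
            strand=strand,
            score=float(raw),
            pvalue=float(p),
        )
        for pos, strand, raw, p in rows
    ]


def _scan_fimo_encoded(enc, lom, cfg, dist):
    """Core fimo-mode scan on an encoded sequence; yields (pos, strand, score, p)."""
    W = lom.width
    if len(enc) < W:
        return []
    fwd, valid = _window_int_scores(enc, dist.int_matrix)
    if cfg.both_strands:
        rev, _ = _window_int_scores(enc, _rc_int_matrix(dist.int_matrix))
    else:
        rev = np.full_like(fwd, -1)
    t_int = dist.min_int_for_pvalue(10.0 ** (-cfg.fimo_score_threshold))
    rows = []
    if cfg.max_strand:
        best = np.maximum(fwd, rev)
        hit_pos = np.nonzero(valid & (best >= t_int))[0]
        for pos in hit_pos:
            strand = "+" if fwd[pos] >= rev[pos] else "-"
            i = int(best[pos])
            rows.append((int(pos), strand, dist.raw_score(i), float(dist.pvalue(i))))
    else:
        for strand, arr in (("+", fwd), ("-", rev)):
            for pos in np.nonzero(valid & (arr >= t_int))[0]:
                i = int(arr[pos])
                rows.append((int(pos), strand, dist.raw_score(i), float(dist.pvalue(i))))
        rows.sort()
    return rows


# -- cluster mode -------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    gene_id: str
    start_offset: int
    end_offset: int
    score: float
    n_matches: int


def write_clusters_bed(clusters: Iterable[Cluster], path) -> None:
    """BED of cluster intervals in TIC-relative coordinates (name = gene)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.gene_id}\t{c.start_offset}\t{c.end_offset}"
                f"\tcluster\t{c.score:.4g}\t.\n"
            )


def _candidate_matches(enc, loms, cfg):
    """All matches with best-strand log-odds score >= m, any motif.

    Returns a list of (start, end, motif_id, strand, score) sorted by start.
    """
    cands = []
    for lom in loms:
        fwd, valid = _window_float_scores(enc, lom.scores)
        if cfg.both_strands:
            rev, _ = _window_float_scores(enc, lom.reverse_complement().scores)
        else:
            rev = np.full_like(fwd, -np.inf)
        best = np.maximum(fwd, rev)
        for pos in np.nonzero(valid & (best >= cfg.motif_score_threshold))[0]:
            strand = "+" if fwd[pos] >= rev[pos] else "-"
            cands.append(
                (int(pos), int(pos) + lom.width, lom.motif_id, strand, float(best[pos]))
            )
    cands.sort()
    return cands


def _chain_candidates(cands, cfg):
    """Gap-penalized chaining DP; returns disjoint maximal chains >= c.

    Chains are built over non-overlapping candidates ordered by position;
    linking j before i costs ``(start_i - end_j) / g`` bits.
    """
    n = len(cands)
    if n == 0:
        return []
    g = cfg.gap_param
    starts = np.array([c[0] for c in cands])
    ends = np.array([c[1] for c in cands])
    scores = np.array([c[4] for c in cands])
    best = scores.copy()
    prev = np.full(n, -1, dtype=np.int64)
    # running max of best[j] + end_j/g over candidates with end_j <= start_i
    order_by_end = np.argsort(ends, kind="mergesort")
    # maximizing best[j] - (start_i - end_j)/g over j is maximizing
    # best[j] + end_j/g, the shared -start_i/g term aside
    run_best = -np.inf
    run_arg = -1
    ptr = 0
    for i in range(n):
        while ptr < n and ends[order_by_end[ptr]] <= starts[i]:
            j = order_by_end[ptr]
            val = best[j] + ends[j] / g
            if val > run_best:
                run_best, run_arg = val, j
            ptr += 1
        if run_arg >= 0:
            link = run_best - starts[i] / g
            if link > 0:
                best[i] = scores[i] + link
                prev[i] = run_arg
    used = np.zeros(n, dtype=bool)
    chains = []
    for i in np.argsort(-best, kind="mergesort"):
        if used[i] or best[i] < cfg.cluster_score_threshold:
            continue
        chain = []
        j = i
        ok = True
        while j >= 0:
            if used[j]:
                ok = False
                break
            chain.append(j)
            j = prev[j]
        if not ok:
            continue
        for j in chain:
            used[j] = True
        chains.append((float(best[i]), [cands[j] for j in reversed(chain)]))
    chains.sort(key=lambda c: c[1][0][0])
    return chains


def scan_cluster(
    region: RegulatoryRegion, loms: Sequence[LogOddsMatrix], cfg: ScanConfig
) -> tuple[list[Cluster], list[MotifHit]]:
    """Cluster-mode scan of one region against a motif set."""
    if not loms:
        raise ValueError("cluster mode needs at least one motif")
    enc = encode_sequence(region.sequence)
    offs = region.offsets()
    labels = region.segment_labels()
    cands = _candidate_matches(enc, loms, cfg)
    chains = _chain_candidates(cands, cfg)
    clusters, hits = [], []
    for total, members in chains:
        clusters.append(
            Cluster(
                gene_id=region.gene_id,
                start_offset=int(offs[members[0][0]]),
                end_offset=int(offs[members[-1][1] - 1]) + 1,
                score=total,
                n_matches=len(members),
            )
        )
        for start, _end, motif_id, strand, score in members:
            hits.append(
                MotifHit(
                    gene_id=region.gene_id,
                    motif_id=motif_id,
                    segment=str(labels[start]),
                    offset=int(offs[start]),
                    strand=strand,
                    score=score,
                    cluster_score=total,
                )
            )
    return clusters, hits


# -- multi-region driver ------------------------------------------------------


def scan_regions(
    regions: Sequence[RegulatoryRegion],
    loms: Sequence[LogOddsMatrix],
    cfg: ScanConfig,
) -> pd.DataFrame:
    """Scan many regions with many motifs; returns the sorted hits table.

    Regions are concatenated with an N separator so each motif is scanned in
    one vectorized pass; the separator invalidates windows spanning two genes.
    """
    if cfg.algorithm == "cluster":
        all_hits = []
        for region in regions:
            _clusters, hits = scan_cluster(region, loms, cfg)
            all_hits.extend(hits)
        return hits_to_frame(all_hits)

    parts, starts, pos = [], [], 0
    offs_parts, label_parts = [], []
    for r in regions:
        starts.append(pos)
        parts.append(r.sequence)
        offs_parts.append(r.offsets())
        label_parts.append(r.segment_labels())
        pos += len(r.sequence) + 1
        parts.append("N")
    enc_all = encode_sequence("".join(parts)) if parts else np.empty(0, np.int8)
    starts_arr = np.array(starts, dtype=np.int64)
    region_ids = [r.gene_id for r in regions]
    lengths = np.array([len(r.sequence) for r in regions], dtype=np.int64)

    all_rows = []
    for lom in loms:
        dist = ScoreDistribution(lom, cfg.precision)
        for pos_, strand, raw, p in _scan_fimo_encoded(enc_all, lom, cfg, dist):
            ri = int(np.searchsorted(starts_arr, pos_, side="right")) - 1
            local = pos_ - int(starts_arr[ri])
            if local >= lengths[ri]:  # window begins in the separator
                continue
            all_rows.append(
                MotifHit(
                    gene_id=region_ids[ri],
                    motif_id=lom.motif_id,
                    segment=str(label_parts[ri][local]),
                    offset=int(offs_parts[ri][local]),
                    strand=strand,
                    score=float(raw),
                    pvalue=float(p),
                )
            )
    return hits_to_frame(all_rows)
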