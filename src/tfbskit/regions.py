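"""Per-gene regulatory region construction from FASTA + GFF3.

Regions are anchored at the translation initiation codon (TIC) and translation
stop codon (TSC) rather than the transcription start/end sites, so that genomes
without full-length transcript support are comparable. The construction rules:

1. A full regulatory structure is the upstream window before the TIC, the
   introns of the representative isoform, and a downstream window after the
   TSC.
2. When a neighboring gene body overlaps the upstream/downstream window, the
   window is trimmed at the neighbor's boundary so only intergenic sequence
   remains.
3. When the gene body itself overlaps another gene on the opposite strand,
   full standard windows are used (no trimming).
4. The largest splicing variant (spliced exon length) represents the gene.
5. Introns longer than ``intron_max_len`` (default 5000 bp) are skipped.

Internally all intervals are 0-based half-open; GFF3 input is converted from
1-based inclusive and BED output is 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class RegionError(ValueError):
    """Raised for malformed gene annotations."""


@dataclass(frozen=True)
class GeneModel:
    """Representative-isoform gene model in 0-based half-open coordinates."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    tic: int  # genomic position of the first base of the start codon
    tsc: int  # genomic position of the last base of the stop codon
    exons: tuple  # ((start, end), ...) sorted by genomic start
    gene_start: int = 0  # gene body extent (for neighbor trimming)
    gene_end: int = 0
    cds: tuple = ()  # ((start, end, frame), ...) sorted by genomic start

    @property
    def introns(self) -> tuple:
        """Gaps between consecutive exons, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def __post_init__(self):
        for s, e in self.exons:
            if e < s:
                raise RegionError(
                    f"gene {self.gene_id}: malformed exon interval [{s}, {e})"
                )
        if self.strand not in "+-":
            raise RegionError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class RegionConfig:
    upstream_len: int = 1000  # bp before the TIC; {1000, 3000, 5000} in the UI
    downstream_len: int = 0  # bp after the TSC; 0 or 1000
    include_introns: bool = False
    intron_max_len: int = 5000
    trim_intergenic: bool = True
    strand_exception: bool = True  # rule 3: opposite-strand overlap keeps full windows

    def __post_init__(self):
        if self.upstream_len <= 0:
            raise ValueError("upstream_len must be positive")
        if self.downstream_len < 0:
            raise ValueError("downstream_len must be >= 0")
        if self.intron_max_len <= 0:
            raise ValueError("intron_max_len must be positive")

    def key(self) -> str:
        intr = f"+introns<={self.intron_max_len}" if self.include_introns else ""
        down = f"+down{self.downstream_len}" if self.downstream_len else ""
        trim = "" if self.trim_intergenic else "+notrim"
        return f"up{self.upstream_len}{intr}{down}{trim}"

    def to_dict(self) -> dict:
        return {
            "upstream_len": self.upstream_len,
            "downstream_len": self.downstream_len,
            "include_introns": self.include_introns,
            "intron_max_len": self.intron_max_len,
            "trim_intergenic": self.trim_intergenic,
            "strand_exception": self.strand_exception,
        }


@dataclass
class RegulatoryRegion:
    """Stitched searchable region of one gene.

    ``segments`` are (label, chrom, start, end, strand) in gene orientation
    order: upstream, then introns 5'->3', then downstream. ``sequence`` is the
    concatenation in gene orientation (minus-strand genes reverse-complemented)
    and is filled by :func:`extract_sequences`.
    """

    gene_id: str
    segments: list
    tic: int
    strand: str
    sequence: str = ""

    @property
    def length(self) -> int:
        return sum(e - s for _, _, s, e, _ in self.segments)

    def offsets(self) -> np.ndarray:
        """Signed TIC-relative offset of every sequence position.

        Upstream positions map to [-upstream_len, -1]; -1 is the base
        immediately 5' of the TIC. Positions 3' of the TIC are positive,
        with 0 being the TIC base itself.
        """
        parts = []
        for _label, _chrom, s, e, strand in self.segments:
            pos = np.arange(s, e, dtype=np.int64)
            off = pos - self.tic if strand == "+" else self.tic - pos[::-1]
            parts.append(off)
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)

    def segment_labels(self) -> np.ndarray:
        """Segment label of every sequence position."""
        parts = [
            np.full(e - s, label, dtype=object)
            for label, _c, s, e, _st in self.segments
        ]
        if not parts:
            return np.empty(0, dtype=object)
        return np.concatenate(parts)


# -- GFF3 reading -------------------------------------------------------------


def select_representative(transcripts: Sequence[dict]) -> str:
    """Pick the representative isoform: largest spliced length, ties broken by
    lexicographically smallest transcript ID.

    Each transcript dict needs ``transcript_id``, ``exons`` (0-based half-open
    intervals) and ``has_cds`` (bool).
    """
    with_cds = [t for t in transcripts if t.get("has_cds")]
    if not with_cds:
        raise RegionError("no transcript with CDS features")
    return min(
        with_cds,
        key=lambda t: (-sum(e - s for s, e in t["exons"]), t["transcript_id"]),
    )["transcript_id"]


def read_gene_models(gff_path) -> list[GeneModel]:
    """Parse a GFF3 into representative-isoform gene models.

    Genes without any CDS-bearing transcript are excluded with a warning.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                (c.start - 1, c.end)
                for c in db.children(t, featuretype="exon", order_by="start")
            ]
            cds = [
                (c.start - 1, c.end, int(c.frame) if c.frame in "012" else 0)
                for c in db.children(t, featuretype="CDS", order_by="start")
            ]
            for s, e in exons + [c[:2] for c in cds]:
                if e < s:
                    raise RegionError(
                        f"gene {gene.id}: malformed interval [{s}, {e}) in {t.id}"
                    )
            if not exons:
                exons = [c[:2] for c in cds]  # exon-less: fall back to CDS extent
            transcripts.append(
                {
                    "transcript_id": t.id,
                    "exons": exons,
                    "cds": cds,
                    "has_cds": bool(cds),
                }
            )
        try:
            rep_id = select_representative(transcripts)
        except RegionError:
            logger.warning("gene %s has no CDS-bearing transcript; excluded", gene.id)
            continue
        rep = next(t for t in transcripts if t["transcript_id"] == rep_id)
        cds = sorted(rep["cds"])
        cds_min = min(c[0] for c in cds)
        cds_max = max(c[1] for c in cds)
        strand = gene.strand
        tic = cds_min if strand == "+" else cds_max - 1
        tsc = cds_max - 1 if strand == "+" else cds_min
        models.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=rep_id,
                chrom=gene.seqid,
                strand=strand,
                tic=tic,
                tsc=tsc,
                exons=tuple(sorted(rep["exons"])),
                gene_start=gene.start - 1,
                gene_end=gene.end,
                cds=tuple(cds),
            )
        )
    return models


# -- region construction ------------------------------------------------------


def _trim_window(
    win: tuple[int, int],
    gene: GeneModel,
    neighbors: Iterable[GeneModel],
    anchor_left: bool,
) -> tuple[int, int]:
    """Cut a window at the boundary of any overlapping neighbor gene body.

    ``anchor_left`` is True when the gene-proximal edge is the window's right
    edge (e.g. plus-strand upstream window): the kept part is the rightmost
    neighbor-free stretch adjacent to the gene.
    """
    s, e = win
    for nb in neighbors:
        ns, ne = nb.gene_start, nb.gene_end
        if ne <= s or ns >= e:
            continue
        if anchor_left:
            s = max(s, ne)
        else:
            e = min(e, ns)
        s = min(s, e)
    return s, e


def build_region(
    gene: GeneModel,
    neighbors: Sequence[GeneModel],
    cfg: RegionConfig,
    chrom_len: int | None = None,
) -> RegulatoryRegion:
    """Build the stitched regulatory region of one gene.

    ``neighbors`` are other genes on the same chromosome (any strand);
    ``chrom_len`` truncates windows at the contig edge.
    """
    plus = gene.strand == "+"
    L, D = cfg.upstream_len, cfg.downstream_len

    if plus:
        up = (gene.tic - L, gene.tic)
        down = (gene.tsc + 1, gene.tsc + 1 + D)
    else:
        up = (gene.tic + 1, gene.tic + 1 + L)
        down = (gene.tsc - D, gene.tsc)

    # rule 3: opposite-strand overlap of the gene body itself => full windows
    overlapping_opposite = any(
        nb.strand != gene.strand
        and nb.gene_start < gene.gene_end
        and nb.gene_end > gene.gene_start
        for nb in neighbors
    )
    trim = cfg.trim_intergenic and not (cfg.strand_exception and overlapping_opposite)
    if trim:
        up = _trim_window(up, gene, neighbors, anchor_left=plus)
        down = _trim_window(down, gene, neighbors, anchor_left=not plus)

    def clamp(iv):
        s, e = iv
        s = max(s, 0)
        if chrom_len is not None:
            e = min(e, chrom_len)
        s = min(s, e)
        return s, e

    up, down = clamp(up), clamp(down)
    if up[1] - up[0] == 0:
        logger.warning("gene %s: zero-length upstream window after trimming", gene.gene_id)

    segments = []
    if up[1] > up[0]:
        segments.append(("upstream", gene.chrom, up[0], up[1], gene.strand))
    if cfg.include_introns:
        introns = list(gene.introns)
        if not plus:
            introns = introns[::-1]  # 5'->3' in gene orientation
        k = 0
        for s, e in introns:
            if e - s > cfg.intron_max_len:
                continue
            k += 1
            segments.append((f"intron_{k}", gene.chrom, s, e, gene.strand))
    if D and down[1] > down[0]:
        segments.append(("downstream", gene.chrom, down[0], down[1], gene.strand))
    return RegulatoryRegion(
        gene_id=gene.gene_id, segments=segments, tic=gene.tic, strand=gene.strand
    )


def build_regions(
    genes: Sequence[GeneModel],
    cfg: RegionConfig,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[RegulatoryRegion]:
    """Build regions for all genes, using per-chromosome neighbor lookup."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for g in genes:
        neighbors = [n for n in by_chrom[g.chrom] if n.gene_id != g.gene_id]
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        out.append(build_region(g, neighbors, cfg, chrom_len=clen))
    return out


# -- sequence extraction & IO -------------------------------------------------


def extract_sequences(regions: Sequence[RegulatoryRegion], fasta) -> None:
    """Fill ``region.sequence`` from an indexed FASTA (path or pyfaidx.Fasta).

    Minus-strand segments are reverse-complemented; N runs are preserved.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    for region in regions:
        parts = []
        for _label, chrom, s, e, strand in region.segments:
            if chrom not in fa:
                raise KeyError(f"chromosome {chrom!r} not in FASTA")
            raw = str(fa[chrom][s:e]).upper()
            parts.append(reverse_complement(raw) if strand == "-" else raw)
        region.sequence = "".join(parts)


def write_bed(regions: Sequence[RegulatoryRegion], path) -> None:
    """BED6 of all segments; name = ``gene_id|label``."""
    with open(path, "w") as fh:
        for r in regions:
            for label, chrom, s, e, strand in r.segments:
                fh.write(f"{chrom}\t{s}\t{e}\t{r.gene_id}|{label}\t0\t{strand}\n")


def read_bed(path) -> list[tuple]:
    """Read back segments written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            chrom, s, e, name, _score, strand = ln.rstrip("\n").split("\t")
            gene_id, label = name.split("|", 1)
            out.append((gene_id, label, chrom, int(s), int(e), strand))
    return out


def write_fasta(regions: Sequence[RegulatoryRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.gene_id}\n")
            seq = r.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            if not seq:
                fh.write("\n")


def write_manifest(regions: Sequence[RegulatoryRegion], cfg: RegionConfig, path) -> None:
    payload = {
        "config": cfg.to_dict(),
        "setting": cfg.key(),
        "M": len(regions),
        "genes": [r.gene_id for r in regions],
        "lengths": {r.gene_id: r.length for r in regions},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
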