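"""Likely-ortholog assignment by best reciprocal hit (BRH).

Two proteomes are compared by protein similarity (BLASTP tabular input, or
the built-in pairwise aligner for small fixtures); a pair of genes is called
a likely ortholog pair when each is the other's best hit and both E-values
pass the cutoff (default 1e-10). A query gene list can then be translated
between species, with unmapped genes reported separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from tfbskit.regions import GeneModel, read_gene_models, reverse_complement
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class BrhPair:
    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float
    bitscore_ab: float
    bitscore_ba: float


# -- proteome translation -----------------------------------------------------


def translate_gene(gene: GeneModel, fasta: Fasta) -> str | None:
    """Standard-code translation of the representative CDS.

    The phase of the 5'-most CDS segment (gene orientation) is honoured;
    a trailing stop is stripped; an internal stop or an empty CDS returns
    None (caller logs and excludes). Length not divisible by 3 is truncated
    to the codon boundary with a warning.
    """
    if not gene.cds:
        return None
    parts = [str(fasta[gene.chrom][s:e]).upper() for s, e, _f in gene.cds]
    if gene.strand == "+":
        seq = "".join(parts)
        phase = gene.cds[0][2]
    else:
        seq = "".join(reverse_complement(p) for p in reversed(parts))
        phase = gene.cds[-1][2]
    seq = seq[phase:]
    if len(seq) % 3:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3; truncated",
            gene.gene_id,
            len(seq),
        )
        seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return None
    prot = str(Seq(seq).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        return None
    return prot


def translate_proteomes(gff_path, fasta_path) -> dict[str, str]:
    """Per-gene protein sequences (representative isoform) from FASTA+GFF3.

    Genes with internal stop codons are excluded with a warning.
    """
    fasta = Fasta(str(fasta_path))
    out = {}
    for gene in read_gene_models(gff_path):
        prot = translate_gene(gene, fasta)
        if prot is None:
            logger.warning("gene %s: untranslatable CDS; excluded", gene.gene_id)
            continue
        out[gene.gene_id] = prot
    return out


def write_proteome(proteins: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(proteins):
            fh.write(f">{gid}\n{proteins[gid]}\n")


def read_proteome(path) -> dict[str, str]:
    out, gid, chunks = {}, None, []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip()
            if ln.startswith(">"):
                if gid is not None:
                    out[gid] = "".join(chunks)
                gid, chunks = ln[1:].split()[0], []
            elif ln:
                chunks.append(ln)
    if gid is not None:
        out[gid] = "".join(chunks)
    return out


# -- BLAST tabular input and BRH ----------------------------------------------


def read_blast6(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 table (12 standard columns, no header)."""
    return pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)


def _best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query: highest bitscore, ties by lowest evalue, then
    lexicographic subject id."""
    if df.empty:
        return df
    ordered = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("qseqid", as_index=False).first()


def brh(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, max_evalue: float = 1e-10
) -> list[BrhPair]:
    """Reciprocal best pairs between species A and B.

    A pair (a, b) is kept iff b is a's best hit in A->B, a is b's best hit
    in B->A, and both E-values are <= ``max_evalue``.
    """
    if hits_ab.empty or hits_ba.empty:
        return []
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    back = best_ba.set_index("qseqid")
    pairs = []
    for row in best_ab.itertuples():
        a, b = str(row.qseqid), str(row.sseqid)
        if b not in back.index:
            continue
        rb = back.loc[b]
        if str(rb["sseqid"]) != a:
            continue
        if row.evalue > max_evalue or float(rb["evalue"]) > max_evalue:
            continue
        pairs.append(
            BrhPair(
                gene_a=a,
                gene_b=b,
                evalue_ab=float(row.evalue),
                evalue_ba=float(rb["evalue"]),
                bitscore_ab=float(row.bitscore),
                bitscore_ba=float(rb["bitscore"]),
            )
        )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def map_query(
    query: Sequence[str], pairs: Sequence[BrhPair]
) -> tuple[list[str], list[str]]:
    """Translate a gene list through BRH pairs, preserving order.

    Returns (mapped target-species genes, unmapped source genes). Duplicate
    query IDs are deduplicated with a warning; an empty query is an error.
    """
    if not query:
        raise ValueError("empty query")
    seen = set()
    deduped = []
    for g in query:
        if g in seen:
            continue
        seen.add(g)
        deduped.append(g)
    if len(deduped) < len(query):
        logger.warning("%d duplicate query IDs removed", len(query) - len(deduped))
    lookup = {p.gene_a: p.gene_b for p in pairs}
    mapped = [lookup[g] for g in deduped if g in lookup]
    unmapped = [g for g in deduped if g not in lookup]
    return mapped, unmapped


def write_pairs(pairs: Sequence[BrhPair], path) -> None:
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(path, sep="\t", index=False)


# -- built-in aligner for small fixtures --------------------------------------

# gapped Karlin-Altschul parameters for BLOSUM62 (-11/-1 gaps)
_KA_LAMBDA = 0.267
_KA_K = 0.041


def align_proteomes(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    max_targets: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-all global-local protein alignment for tiny fixture proteomes.

    Produces two outfmt-6-style tables (A->B and B->A) using BLOSUM62 with
    affine gaps and Karlin-Altschul E-values, so the BRH logic can be
    exercised without an external aligner. Not a BLAST replacement: meant
    for proteome fixtures of tens of sequences.
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    db_size = sum(len(s) for s in proteins_b.values())

    def one_direction(qs, ss, db_len):
        rows = []
        for qid, qseq in qs.items():
            scored = []
            for sid, sseq in ss.items():
                raw = float(aligner.score(qseq, sseq))
                bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
                evalue = len(qseq) * db_len * 2.0**-bits
                scored.append((sid, raw, bits, evalue))
            scored.sort(key=lambda t: (-t[2], t[3], t[0]))
            for sid, _raw, bits, evalue in scored[:max_targets]:
                rows.append(
                    {
                        "qseqid": qid,
                        "sseqid": sid,
                        "pident": 0.0,
                        "length": len(qseq),
                        "mismatch": 0,
                        "gapopen": 0,
                        "qstart": 1,
                        "qend": len(qseq),
                        "sstart": 1,
                        "send": len(ss[sid]),
                        "evalue": evalue,
                        "bitscore": bits,
                    }
                )
        return pd.DataFrame(rows, columns=BLAST6_COLUMNS)

    qa_size = sum(len(s) for s in proteins_a.values())
    return (
        one_direction(proteins_a, proteins_b, db_size),
        one_direction(proteins_b, proteins_a, qa_size),
    )
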