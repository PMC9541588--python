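"""Self-contained synthetic genomes, PWMs, and planted-motif promoters.

The generator emulates the external inputs of the real pipeline at desk
scale: a single-chromosome plant-like genome with annotated multi-isoform
genes (including the annotation corner cases the region builder must handle
— a contig-edge gene, a tight same-strand neighbor pair, an opposite-strand
overlapping pair, and a > 5 kb intron), toy PWMs at two sharpness tiers, and
promoters with motif instances planted at controlled per-gene rates. A truth
table records every planted instance so scanner recovery and enrichment
statistics are checkable exactly.

Coding sequences are valid ORFs (ATG ... stop, no internal stops), so the
same fixture also exercises proteome translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tfbskit.motifs import ALPHABET, Pwm, write_meme, write_metadata
from tfbskit.regions import reverse_complement

_NONSTOP_CODONS = [
    a + b + c
    for a in ALPHABET
    for b in ALPHABET
    for c in ALPHABET
    if a + b + c not in {"TAA", "TAG", "TGA"}
]

# gene indices reserved for annotation corner cases (never planted/targeted)
N_SPECIAL = 6


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 2000
    target_set_size: int = 100
    p_target: float = 0.8  # planted fraction in target genes
    p_background: float = 0.05  # planted fraction in background genes
    gc_content: float = 0.40
    mean_spacing: int = 3000  # intergenic gap between consecutive genes
    min_spacing: int = 1500
    planted_motif: str = "M_planted"
    planted_consensus: str = "TGACGTCAG"
    sharpness: float = 0.97  # consensus probability of the planted PWM
    n_decoy_pwms: int = 9
    decoy_sharpness: float = 0.7
    decoy_width: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_background <= self.p_target <= 1):
            raise ValueError("need 0 <= p_background <= p_target <= 1")
        if self.n_genes < N_SPECIAL + 2:
            raise ValueError(f"need at least {N_SPECIAL + 2} genes")
        if self.target_set_size > self.n_genes - N_SPECIAL:
            raise ValueError("target set larger than plantable gene pool")


def consensus_pwm(motif_id: str, consensus: str, sharpness: float) -> Pwm:
    """PWM with ``sharpness`` probability on the consensus base per position."""
    w = len(consensus)
    off = (1.0 - sharpness) / 3.0
    m = np.full((w, 4), off)
    for i, b in enumerate(consensus.upper()):
        m[i, ALPHABET.index(b)] = sharpness
    return Pwm(motif_id=motif_id, matrix=m, tf_name=motif_id.replace("M_", "TF_"))


@dataclass
class FixtureGenome:
    """In-memory synthetic genome: sequences, annotation, motifs, truth."""

    spec: FixtureSpec
    chrom: str
    sequence: str
    gff_text: str
    truth: pd.DataFrame  # per gene: strand, tic, target, planted, offset, special
    pwms: list

    @property
    def gene_ids(self) -> list[str]:
        return list(self.truth["gene_id"])

    @property
    def target_genes(self) -> list[str]:
        return list(self.truth[self.truth["target"]]["gene_id"])

    @property
    def background_genes(self) -> list[str]:
        t = self.truth
        return list(t[~t["target"] & (t["special"] == "")]["gene_id"])

    @property
    def fasta_text(self) -> str:
        lines = [f">{self.chrom}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i : i + 70])
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
            "pwms": outdir / "pwms.meme",
            "metadata": outdir / "pwm_metadata.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff"].write_text(self.gff_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_meme(self.pwms, paths["pwms"])
        write_metadata(self.pwms, paths["metadata"])
        return paths


def _random_consensus(rng: np.random.Generator, width: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=width))


def _gene_structure(rng: np.random.Generator, special: str):
    """Exon/intron layout (gene-oriented), lengths in bp; exons carry the CDS.

    Exon lengths are multiples of 3 so the concatenated CDS is codon-complete.
    """
    if special == "long_intron":
        return [("exon", 300), ("intron", 6000), ("exon", 300)]
    n_exons = int(rng.integers(1, 4))
    parts = []
    for i in range(n_exons):
        parts.append(("exon", int(rng.integers(50, 134)) * 3))
        if i < n_exons - 1:
            parts.append(("intron", int(rng.integers(100, 501))))
    return parts


def _cds_sequence(rng: np.random.Generator, length: int) -> str:
    assert length % 3 == 0 and length >= 9
    n_mid = length // 3 - 2
    mid = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_mid)
    )
    return "ATG" + mid + "TAA"


def make_genome(spec: FixtureSpec) -> FixtureGenome:
    """Generate the synthetic genome; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.rng_seed)
    specials = ["edge", "tight_a", "tight_b", "olap_a", "olap_b", "long_intron"]

    # -- plan gene placement --------------------------------------------------
    plans = []
    cursor = 200  # first gene truncated at the contig edge
    for i in range(spec.n_genes):
        special = specials[i] if i < len(specials) else ""
        structure = _gene_structure(rng, special)
        body = sum(l for _k, l in structure)
        if special in {"edge", "tight_a", "olap_a", "long_intron"}:
            strand = "+"
        elif special == "tight_b":
            strand = "+"
        elif special == "olap_b":
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        plans.append(
            {
                "gene_id": f"g{i + 1:05d}",
                "special": special,
                "structure": structure,
                "strand": strand,
                "start": cursor,
                "body": body,
            }
        )
        if special == "tight_a":
            gap = 500  # rule-2 trimming: next upstream window cut to 500 bp
        elif special == "olap_a":
            gap = -300  # rule-3 pair: bodies overlap by 300 bp
        else:
            gap = max(
                spec.min_spacing, int(rng.normal(spec.mean_spacing, 500))
            )
        cursor += body + gap
    chrom_len = cursor + 6000

    # -- motifs ---------------------------------------------------------------
    pwms = [
        consensus_pwm(spec.planted_motif, spec.planted_consensus, spec.sharpness)
    ]
    for k in range(spec.n_decoy_pwms):
        pwms.append(
            consensus_pwm(
                f"M_decoy{k + 1:02d}",
                _random_consensus(rng, spec.decoy_width),
                spec.decoy_sharpness,
            )
        )

    # -- choose targets and plant ---------------------------------------------
    plantable = [p for p in plans if not p["special"]]
    target_idx = rng.choice(
        len(plantable), size=spec.target_set_size, replace=False
    )
    targets = {plantable[i]["gene_id"] for i in target_idx}
    W = len(spec.planted_consensus)
    plant_lo, plant_hi = -900, -(W + 20)  # gene-oriented offsets, within 1 kb

    seq = np.frombuffer(
        bytes(
            rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8),
                size=chrom_len,
                p=[
                    (1 - spec.gc_content) / 2,
                    spec.gc_content / 2,
                    spec.gc_content / 2,
                    (1 - spec.gc_content) / 2,
                ],
            )
        ),
        dtype=np.uint8,
    ).copy()

    def write_seq(pos: int, s: str):
        seq[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    gff = ["##gff-version 3"]
    truth_rows = []
    chrom = "chr1"
    for plan in plans:
        gid, strand, start = plan["gene_id"], plan["strand"], plan["start"]
        end = start + plan["body"]  # half-open

        # exon/intron genomic intervals; for minus-strand genes the 5'->3'
        # order is the reverse of genomic order but the intervals stand
        segs = []
        pos = start
        for kind, ln in plan["structure"]:
            segs.append((kind, pos, pos + ln))
            pos += ln
        exons = [(s, e) for k, s, e in segs if k == "exon"]
        cds_len = sum(e - s for s, e in exons)
        cds_seq = _cds_sequence(rng, cds_len)

        # write CDS codons into the genome, in gene orientation
        taken = 0
        order = exons if strand == "+" else exons[::-1]
        for s, e in order:
            chunk = cds_seq[taken : taken + (e - s)]
            taken += e - s
            if strand == "+":
                write_seq(s, chunk)
            else:
                write_seq(s, reverse_complement(chunk))

        tic = start if strand == "+" else end - 1

        # planting
        planted = False
        offset = np.nan
        if not plan["special"]:
            rate = spec.p_target if gid in targets else spec.p_background
            if rng.random() < rate:
                planted = True
                offset = int(rng.integers(plant_lo, plant_hi + 1))
                if strand == "+":
                    write_seq(tic + offset, spec.planted_consensus)
                else:
                    write_seq(
                        tic - offset - W + 1,
                        reverse_complement(spec.planted_consensus),
                    )

        # GFF emission (1-based inclusive); olap pair pads gene extent (UTR)
        gstart, gend = start, end
        if plan["special"] == "olap_a":
            gend = end + 350
        if plan["special"] == "olap_b":
            gstart = start - 350
        gff.append(
            f"{chrom}\tfixture\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        isoforms = [exons]
        if len(exons) >= 2 and rng.random() < 0.4:
            isoforms.append(exons[:-1] if strand == "+" else exons[1:])
        for iso_n, iso_exons in enumerate(isoforms, start=1):
            tid = f"{gid}.{iso_n}"
            t_start = min(s for s, _ in iso_exons)
            t_end = max(e for _, e in iso_exons)
            gff.append(
                f"{chrom}\tfixture\tmRNA\t{t_start + 1}\t{t_end}\t.\t{strand}\t."
                f"\tID={tid};Parent={gid}"
            )
            for s, e in iso_exons:
                gff.append(
                    f"{chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t{strand}\t."
                    f"\tParent={tid}"
                )
                gff.append(
                    f"{chrom}\tfixture\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0"
                    f"\tParent={tid}"
                )
        truth_rows.append(
            {
                "gene_id": gid,
                "strand": strand,
                "tic": tic,
                "target": gid in targets,
                "planted": planted,
                "motif_id": spec.planted_motif if planted else "",
                "offset": offset,
                "special": plan["special"],
            }
        )

    return FixtureGenome(
        spec=spec,
        chrom=chrom,
        sequence=seq.tobytes().decode(),
        gff_text="\n".join(gff) + "\n",
        truth=pd.DataFrame(truth_rows),
        pwms=pwms,
    )


# -- derived fixtures ---------------------------------------------------------


def make_peak_table(
    genome: FixtureGenome, rng_seed: int = 0, n_decoys: int = 10
) -> pd.DataFrame:
    """Gene-relative peak table emulating annotated significant peaks.

    Planted target genes get an in-window peak with a small adjusted q-value;
    ``n_decoys`` background genes get a peak outside the qualifying interval
    (upstream of -3000) and must be excluded by the target builder.
    """
    rng = np.random.default_rng(rng_seed)
    t = genome.truth
    rows = []
    planted_targets = t[t["target"] & t["planted"]]
    for row in planted_targets.itertuples():
        rows.append(
            {
                "gene_id": row.gene_id,
                "rel_start": int(row.offset) - 100,
                "rel_end": int(row.offset) + 100,
                "qvalue": float(10 ** rng.uniform(-8, -3)),
                "gene_length": 1000,
            }
        )
    decoys = t[~t["target"] & (t["special"] == "")]["gene_id"].iloc[:n_decoys]
    for gid in decoys:
        rows.append(
            {
                "gene_id": gid,
                "rel_start": -3600,
                "rel_end": -3400,
                "qvalue": 1e-9,
                "gene_length": 1000,
            }
        )
    return pd.DataFrame(rows)


def make_proteome_pair(
    n_pairs: int = 50,
    n_orphans_a: int = 5,
    n_orphans_b: int = 5,
    length: int = 120,
    mutation_rate: float = 0.05,
    rng_seed: int = 0,
):
    """Two toy proteomes with known homolog pairs.

    Species B proteins are point-mutated copies of their A counterparts
    (aK <-> bK); orphans exist on both sides. Returns
    (proteins_a, proteins_b, expected_pairs).
    """
    rng = np.random.default_rng(rng_seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def random_protein():
        return "".join(aa[i] for i in rng.integers(0, len(aa), size=length))

    def mutate(p):
        out = list(p)
        for i in range(len(out)):
            if rng.random() < mutation_rate:
                out[i] = aa[int(rng.integers(0, len(aa)))]
        return "".join(out)

    proteins_a, proteins_b, pairs = {}, {}, []
    for k in range(1, n_pairs + 1):
        p = random_protein()
        proteins_a[f"a{k:03d}"] = p
        proteins_b[f"b{k:03d}"] = mutate(p)
        pairs.append((f"a{k:03d}", f"b{k:03d}"))
    for k in range(1, n_orphans_a + 1):
        proteins_a[f"a_orph{k}"] = random_protein()
    for k in range(1, n_orphans_b + 1):
        proteins_b[f"b_orph{k}"] = random_protein()
    return proteins_a, proteins_b, pairs
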