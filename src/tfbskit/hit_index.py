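"""Per-setting index of genes carrying at least one hit per PWM.

The index is the pre-computed quantity behind the enrichment test: for each
PWM it stores the sorted set of genes with >= 1 hit under one
(genome, algorithm, score, region setting) combination, together with the
genome gene count M. ``N`` per motif is the size of that set.

Persistence is a gzipped TSV (one line per motif: motif_id, tab, comma-joined
gene ids) next to a JSON header carrying M, the setting key, and the gene
universe — inspectable with standard shell tools.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class HitIndexError(ValueError):
    pass


@dataclass
class HitIndex:
    genes: tuple  # the gene universe (sorted); M = len(genes)
    motif_genes: dict  # motif_id -> frozenset of gene_ids with >= 1 hit
    setting: str = ""

    @property
    def M(self) -> int:
        return len(self.genes)

    @property
    def motif_ids(self) -> list[str]:
        return sorted(self.motif_genes)

    def N(self, motif_id: str) -> int:
        return len(self.motif_genes.get(motif_id, frozenset()))

    def query_genes(self, motif_id: str, query: Sequence[str]) -> tuple[int, list[str]]:
        """x = |query ∩ hit set| and the sorted overlapping sublist."""
        if motif_id not in self.motif_genes:
            logger.warning("motif %s not in index; zero-hit result", motif_id)
            return 0, []
        hit = sorted(set(query) & self.motif_genes[motif_id])
        return len(hit), hit

    def filter_query(self, query: Sequence[str]) -> list[str]:
        """Deduplicate a query and drop IDs not in the genome (logged)."""
        universe = set(self.genes)
        seen, kept, dropped = set(), [], 0
        for g in query:
            if g in seen:
                continue
            seen.add(g)
            if g in universe:
                kept.append(g)
            else:
                dropped += 1
        if dropped:
            logger.warning("%d query gene IDs not in the genome; dropped", dropped)
        return kept

    def save(self, path) -> None:
        path = Path(path)
        with gzip.open(path, "wt") as fh:
            for motif_id in self.motif_ids:
                fh.write(
                    motif_id + "\t" + ",".join(sorted(self.motif_genes[motif_id])) + "\n"
                )
        header = {
            "M": self.M,
            "setting": self.setting,
            "genes": list(self.genes),
            "n_motifs": len(self.motif_genes),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(header, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path) -> "HitIndex":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        motif_genes = {}
        with gzip.open(path, "rt") as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln:
                    continue
                motif_id, _, genes = ln.partition("\t")
                motif_genes[motif_id] = frozenset(
                    g for g in genes.split(",") if g
                )
        return cls(
            genes=tuple(header["genes"]),
            motif_genes=motif_genes,
            setting=header.get("setting", ""),
        )


def build_index(
    hits: pd.DataFrame | Iterable[Mapping],
    manifest_genes: Sequence[str],
    setting: str = "",
    motif_ids: Sequence[str] | None = None,
) -> HitIndex:
    """Aggregate a hits table into a HitIndex.

    ``manifest_genes`` is the gene universe from the region manifest (defines
    M). Duplicate hits collapse; hits for unknown genes raise. Motifs listed
    in ``motif_ids`` but absent from the hit stream get empty sets (N = 0).
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(list(hits))
    universe = set(manifest_genes)
    motif_genes: dict[str, set] = {m: set() for m in (motif_ids or [])}
    if len(hits):
        unknown = sorted(set(hits["gene_id"]) - universe)
        if unknown:
            raise HitIndexError(f"hits reference unknown gene IDs: {unknown[:10]}")
        for motif_id, sub in hits.groupby("motif_id"):
            motif_genes.setdefault(str(motif_id), set()).update(sub["gene_id"])
    return HitIndex(
        genes=tuple(sorted(universe)),
        motif_genes={m: frozenset(s) for m, s in motif_genes.items()},
        setting=setting,
    )
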