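"""Position weight matrix models and readers (CisBP text, MEME minimal).

A :class:`Pwm` stores per-position nucleotide probabilities over A, C, G, T
plus the metadata carried through to results tables (TF name, family,
subfamily, source species). Scanning operates on a :class:`LogOddsMatrix`,
the log2-odds transform of a Pwm against an order-0 Markov background.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

ALPHABET = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on column indices


class MotifParseError(ValueError):
    """Raised when a PWM file cannot be parsed."""


@dataclass(frozen=True)
class Pwm:
    """A column-stochastic W x 4 probability matrix with metadata."""

    motif_id: str
    matrix: np.ndarray  # shape (W, 4), rows sum to 1
    tf_name: str = ""
    family: str = ""
    subfamily: str = ""
    source_species: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise MotifParseError(
                f"{self.motif_id}: matrix must be W x 4, got {m.shape}"
            )
        if m.shape[0] < 1:
            raise MotifParseError(f"{self.motif_id}: empty matrix")
        if (m < 0).any():
            raise MotifParseError(f"{self.motif_id}: negative probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise MotifParseError(f"{self.motif_id}: rows do not sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def with_metadata(self, **kw) -> "Pwm":
        return replace(self, **kw)


@dataclass(frozen=True)
class LogOddsMatrix:
    """log2-odds scores of a Pwm against an order-0 background."""

    motif_id: str
    scores: np.ndarray  # shape (W, 4)
    background: np.ndarray  # shape (4,), sums to 1

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(
            motif_id=self.motif_id,
            scores=self.scores[::-1, _COMPLEMENT].copy(),
            background=self.background[_COMPLEMENT].copy(),
        )


def _normalize_rows(rows: np.ndarray, motif_id: str) -> np.ndarray:
    """Normalize count or frequency rows to probabilities.

    Rows summing well above 1 are treated as counts (CisBP files mix both).
    """
    sums = rows.sum(axis=1)
    if (sums <= 0).any():
        bad = int(np.nonzero(sums <= 0)[0][0]) + 1
        raise MotifParseError(f"{motif_id}: row {bad} sums to zero")
    return rows / sums[:, None]


def read_cisbp(path_or_text, motif_id: str | None = None) -> Pwm:
    """Read one PWM in CisBP text format (header, then ``Pos A C G T`` rows)."""
    if (
        isinstance(path_or_text, (str, Path))
        and "\n" not in str(path_or_text)
        and Path(str(path_or_text) or ".").is_file()
    ):
        name = Path(path_or_text).stem
        text = Path(path_or_text).read_text()
    else:
        name = motif_id or "cisbp_motif"
        text = str(path_or_text)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MotifParseError(f"{name}: empty file")
    start = 0
    header = lines[0].split()
    if header and header[0].lower() in {"pos", "position"}:
        cols = [c.upper() for c in header[1:5]]
        if cols != list(ALPHABET):
            raise MotifParseError(f"{name}: expected columns A C G T, got {cols}")
        start = 1
    rows = []
    for i, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split()
        vals = parts[1:5] if len(parts) >= 5 else parts[:4]
        if len(vals) < 4:
            raise MotifParseError(f"{name}: line {i}: expected 4 values")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise MotifParseError(f"{name}: line {i}: non-numeric cell") from exc
    if len(rows) < 1:
        raise MotifParseError(f"{name}: no matrix rows")
    matrix = _normalize_rows(np.array(rows, dtype=float), name)
    return Pwm(motif_id=motif_id or name, matrix=matrix)


def read_meme(path_or_handle) -> list[Pwm]:
    """Read all motifs from a MEME minimal-format file."""
    if isinstance(path_or_handle, (str, Path)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
        close = False
    try:
        try:
            records = bio_motifs.parse(handle, "minimal")
            parsed = list(records)
        except Exception as exc:
            raise MotifParseError(f"MEME minimal parse failed: {exc}") from exc
    finally:
        if close:
            handle.close()
    out = []
    for m in parsed:
        if sorted(m.alphabet) != list(ALPHABET):
            raise MotifParseError(
                f"{m.name}: unsupported alphabet {m.alphabet!r} (alength must be 4)"
            )
        matrix = np.array([[m.pwm[b][i] for b in ALPHABET] for i in range(m.length)])
        out.append(Pwm(motif_id=m.name, matrix=_normalize_rows(matrix, m.name)))
    return out


def write_meme(pwms: Sequence[Pwm], path_or_handle, background=None) -> None:
    """Write motifs in MEME minimal format (readable back by :func:`read_meme`)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(ALPHABET)) + "\n\n")
    for p in pwms:
        buf.write(f"MOTIF {p.motif_id}\n")
        # large nsites so readers that reconstruct counts keep full precision
        buf.write(
            f"letter-probability matrix: alength= 4 w= {p.width} "
            f"nsites= 1000000000 E= 0\n"
        )
        for row in p.matrix:
            buf.write(" ".join(f"{v:.9f}" for v in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if isinstance(path_or_handle, (str, Path)):
        Path(path_or_handle).write_text(text)
    else:
        path_or_handle.write(text)


def to_log_odds(
    pwm: Pwm, background=None, pseudocount: float = 0.0
) -> LogOddsMatrix:
    """log2-odds transform of a Pwm against an order-0 background.

    The pseudocount is distributed proportionally to the background:
    p' = (p + eps * q) / (1 + eps). With ``pseudocount=0`` a zero-probability
    cell maps to ``-inf`` (cluster-mode convention); the exact p-value DP
    requires a strictly positive pseudocount.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must sum to 1")
    if (bg <= 0).any():
        raise ValueError("background must be strictly positive")
    p = (pwm.matrix + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log2(p) - np.log2(bg)[None, :]
    return LogOddsMatrix(motif_id=pwm.motif_id, scores=scores, background=bg)


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """Mononucleotide (Markov-0) frequencies over a set of sequences.

    Non-ACGT characters are ignored; an all-N input falls back to uniform.
    """
    counts = np.zeros(4, dtype=np.int64)
    table = {b: i for i, b in enumerate(ALPHABET)}
    for seq in sequences:
        for ch in seq.upper():
            i = table.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# -- metadata sidecar ---------------------------------------------------------

METADATA_COLUMNS = ["motif_id", "tf_name", "family", "subfamily", "source_species"]


def read_metadata(path) -> pd.DataFrame:
    """Read the motif metadata sidecar TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MotifParseError(f"metadata file missing columns: {missing}")
    return df[METADATA_COLUMNS]


def write_metadata(pwms: Sequence[Pwm], path) -> None:
    pd.DataFrame(
        [
            {
                "motif_id": p.motif_id,
                "tf_name": p.tf_name,
                "family": p.family,
                "subfamily": p.subfamily,
                "source_species": p.source_species,
            }
            for p in pwms
        ],
        columns=METADATA_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def attach_metadata(pwms: Sequence[Pwm], metadata: pd.DataFrame) -> list[Pwm]:
    meta = metadata.set_index("motif_id")
    out = []
    for p in pwms:
        if p.motif_id in meta.index:
            row = meta.loc[p.motif_id]
            p = p.with_metadata(
                tf_name=row["tf_name"],
                family=row["family"],
                subfamily=row["subfamily"],
                source_species=row["source_species"],
            )
        out.append(p)
    return out
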