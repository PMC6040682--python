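"""Shared domain types for the accessibility pipeline.

Coordinates are 0-based half-open (BED convention) everywhere except the
blast-style :class:`AlignmentHit`, which keeps the 1-based inclusive spans
of tabular blast output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other letter as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class GenomicInterval:
    """A located interval: ``chrom:[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


PEAK_STATES = ("opening", "closing", "unchanged")


@dataclass
class Peak:
    """An accessible-chromatin region with differential statistics.

    ``rank`` follows the signed-ranking convention: low ranks are the most
    strongly opening peaks, high ranks the most strongly closing ones.
    """

    interval: GenomicInterval
    id: str
    counts: np.ndarray | None = None
    log2fc: float | None = None
    pvalue: float | None = None
    padj: float | None = None
    rank: int | None = None
    state: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state is not None and self.state not in PEAK_STATES:
            raise ValueError(f"state must be one of {PEAK_STATES}")
        if self.pvalue is not None and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in [0, 1]")
        if self.padj is not None and self.pvalue is not None and self.padj < self.pvalue - 1e-12:
            raise ValueError("padj must be >= pvalue")
        if self.state == "opening" and self.log2fc is not None and self.log2fc <= 0:
            raise ValueError("opening peaks must have log2fc > 0")
        if self.state == "closing" and self.log2fc is not None and self.log2fc >= 0:
            raise ValueError("closing peaks must have log2fc < 0")


@dataclass
class PWM:
    """Position weight matrix with background model and log-odds scoring.

    ``probs`` holds the pseudocount-regularized per-position probabilities
    (rows over A, C, G, T); log-odds scores are in bits against
    ``background``.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be an L x 4 matrix with L >= 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"row {bad} of motif {self.name!r} sums to {row_sums[bad]:.4f}, not 1"
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        probs = (probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-3:
            raise ValueError("background must be 4 positive probabilities summing to 1")
        object.__setattr__(self, "background", bg / bg.sum())
        if np.any(self.probs <= 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in (0, 1] after pseudocount")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p / background) score matrix."""
        return np.log2(self.probs / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1].copy()
        return PWM(self.name, rc, self.background[::-1].copy(), pseudocount=0.0)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def score(self, seq: str) -> float:
        """Log-odds score of a sequence of exactly the motif length."""
        if len(seq) != len(self):
            raise ValueError("sequence length must equal motif length")
        idx = encode_sequence(seq)
        if np.any(idx > 3):
            return float("-inf")
        return float(self.log_odds[np.arange(len(self)), idx].sum())


@dataclass
class RepeatInstance:
    """One genomic copy of a transposable element or other repeat."""

    interval: GenomicInterval
    family: str
    subfamily: str = ""
    consensus_length: int = 0

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.consensus_length <= 0:
            raise ValueError("consensus_length must be positive")


@dataclass
class Gene:
    """A gene reduced to its strand-aware transcription start site."""

    id: str
    tss: GenomicInterval
    log2fc_expression: float | None = None

    def __post_init__(self) -> None:
        if self.tss.end != self.tss.start + 1:
            raise ValueError("tss must be a width-1 interval")


@dataclass
class AlignmentHit:
    """One row of 12-column blast-style tabular output (1-based spans)."""

    query_id: str
    subject: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity_pct: float
    bitscore: float
    evalue: float = 0.0
    aligned_length: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if min(self.query_span) < 1:
            raise ValueError("query_span must be 1-based positive")

    @property
    def subject_strand(self) -> str:
        s, e = self.subject_span
        return "+" if e >= s else "-"


@dataclass
class MotifHit:
    """A PWM match on one strand of the genome."""

    motif: str
    interval: GenomicInterval
    score: float
    pvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass
class TripleMotifHit:
    """A same-strand ESR -> bZIP -> Pax arrangement within a short span."""

    esr_hit: MotifHit
    bzip_hit: MotifHit
    pax_hit: MotifHit
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        hits = (self.esr_hit, self.bzip_hit, self.pax_hit)
        strands = {h.interval.strand for h in hits}
        if strands != {self.strand}:
            raise ValueError("component hits must all lie on the arrangement strand")


@dataclass
class CutProfile:
    """Aggregate per-base, per-strand Tn5 cut counts over a fixed window."""

    window: int
    plus_counts: np.ndarray
    minus_counts: np.ndarray
    n_sites: int
    motif_width: int

    def __post_init__(self) -> None:
        plus = np.asarray(self.plus_counts, dtype=float)
        minus = np.asarray(self.minus_counts, dtype=float)
        if plus.shape != (self.window,) or minus.shape != (self.window,):
            raise ValueError("count arrays must have length == window")
        if np.any(plus < 0) or np.any(minus < 0):
            raise ValueError("counts must be non-negative")
        self.plus_counts = plus
        self.minus_counts = minus


PRESENCE_STATES = ("present", "absent", "inconclusive")


@dataclass
class PresenceCall:
    """Per-locus, per-species ortholog state of an Alu insertion."""

    locus_id: str
    species: str
    state: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in PRESENCE_STATES:
            raise ValueError(f"state must be one of {PRESENCE_STATES}")
        ev = self.evidence
        if self.state == "present":
            if not (ev.get("flank5_mapped") and ev.get("flank3_mapped") and ev.get("colinear")):
                raise ValueError("present calls require both flanks mapped and colinear")
        if self.state == "absent":
            if not (ev.get("flank5_mapped") and ev.get("flank3_mapped") and ev.get("colinear")):
                raise ValueError("absent calls require both flanks mapped and colinear")
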