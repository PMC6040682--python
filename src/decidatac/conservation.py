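"""Flank-based presence/absence calling of Alu insertions across species.

For each Alu copy in the reference genome, two 100-bp queries spanning
its 5' and 3' boundaries (50 bp inside the element, 50 bp outside) are
mapped to each target genome. If both queries map uniquely and
colinearly, the separation of the mapped element-boundary points implies
the length of sequence between the flanks: about the element length when
the insertion is present, about zero when it is absent. Junction
support (the inner halves aligning) corroborates presence. Everything
else is inconclusive, mirroring how loci without confidently established
orthology are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentHit, GenomicInterval, PresenceCall, RepeatInstance, revcomp

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 100
SEED_K = 13
MIN_ALIGNED_LEN = 40
MIN_IDENTITY = 0.80
UNIQUENESS_MARGIN_BITS = 5.0
JUNCTION_MIN_IDENTITY = 0.60
PRESENT_LENGTH_TOL = 0.30
ABSENT_MAX_GAP = 60
MISMATCH_PENALTY = 2.0
BITS_PER_SCORE = 2.0


@dataclass
class FlankHit:
    """Best local ungapped alignment of a flank query on one diagonal.

    ``q_start``/``q_end`` are 0-based query coordinates; ``diag`` encodes
    the query-to-subject mapping: subject_pos = diag + qpos on '+', and
    diag + (qlen - 1 - qpos) on '-'.
    """

    contig: str
    strand: str
    diag: int
    qlen: int
    q_start: int
    q_end: int
    score: float
    identity: float
    matches: np.ndarray = field(repr=False, default=None)

    @property
    def bitscore(self) -> float:
        return BITS_PER_SCORE * self.score

    def subject_pos(self, qpos: int) -> int:
        if self.strand == "+":
            return self.diag + qpos
        return self.diag + (self.qlen - 1 - qpos)

    def range_identity(self, a: int, b: int) -> float:
        """Identity over query range [a, b) along this diagonal (out-of-bounds
        positions count as mismatches)."""
        if self.matches is None or b <= a:
            return 0.0
        seg = self.matches[a:b]
        return float(np.sum(seg == 1)) / (b - a)


def extract_flank_queries(
    instance: RepeatInstance,
    genome: Mapping[str, str],
    flank_len: int = DEFAULT_FLANK_LEN,
) -> dict[str, str] | None:
    """100-bp queries centered on each element boundary, strand-aware.

    q5 spans the element's 5' boundary (half outside, half inside), q3 the
    3' boundary; minus-strand instances have the roles swapped and the
    sequences reverse-complemented, so query offset flank_len/2 always
    marks the element boundary reading 5'-to-3' along the element.
    Returns None (exclusion) for instances too close to a contig edge.
    """
    iv = instance.interval
    half = flank_len // 2
    seq = genome[iv.chrom]
    if iv.start - half < 0 or iv.end + half > len(seq):
        logger.info("instance %s:%d-%d too close to contig edge; excluded",
                    iv.chrom, iv.start, iv.end)
        return None
    left = seq[iv.start - half : iv.start + half]
    right = seq[iv.end - half : iv.end + half]
    if iv.strand == "-":
        return {"q5": revcomp(right), "q3": revcomp(left)}
    return {"q5": left, "q3": right}


class KmerIndex:
    """Exact k-mer index of a target genome for seed-and-extend mapping."""

    def __init__(self, genome: Mapping[str, str], k: int = SEED_K):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((contig, pos))

    def candidates(self, query: str) -> set[tuple[str, str, int]]:
        """(contig, strand, diagonal) triples seeded by exact k-mer matches."""
        out: set[tuple[str, str, int]] = set()
        k = self.k
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(len(q) - k + 1):
                for contig, pos in self.index.get(q[i : i + k], ()):
                    diag = pos - i
                    if strand == "-":
                        # store diag in original-query convention:
                        # subject_pos = diag + (qlen - 1 - qpos)
                        diag = pos - i
                    out.add((contig, strand, diag))
        return out


def _score_diagonal(query: str, target: str, strand: str, diag: int) -> FlankHit | None:
    """Best local ungapped segment (match +1, mismatch -2) on one diagonal."""
    qlen = len(query)
    q = query if strand == "+" else revcomp(query)
    # q index j maps to target position diag + j
    matches = np.full(qlen, -1, dtype=np.int8)  # -1 out of bounds, else 0/1
    for j in range(qlen):
        t = diag + j
        if 0 <= t < len(target):
            matches[j] = 1 if q[j] == target[t] else 0
    # Kadane over in-bounds run
    best = (0.0, 0, 0)  # score, start, end (in q coords)
    cur = 0.0
    cur_start = 0
    for j in range(qlen):
        if matches[j] < 0:
            cur, cur_start = 0.0, j + 1
            continue
        step = 1.0 if matches[j] == 1 else -MISMATCH_PENALTY
        if cur + step < 0:
            cur, cur_start = 0.0, j + 1
        else:
            cur += step
            if cur > best[0]:
                best = (cur, cur_start, j + 1)
    score, a, b = best
    if b <= a:
        return None
    n_match = int(np.sum(matches[a:b] == 1))
    identity = n_match / (b - a)
    if strand == "-":
        # convert q-coords (rc) back to original query coords; matches array too
        a_orig, b_orig = qlen - b, qlen - a
        m_orig = matches[::-1].copy()
        a, b = a_orig, b_orig
        matches = m_orig
    return FlankHit(
        contig="", strand=strand, diag=diag, qlen=qlen,
        q_start=int(a), q_end=int(b), score=float(score),
        identity=float(identity), matches=matches,
    )


def map_query(
    query: str,
    index: KmerIndex,
    min_aligned: int = MIN_ALIGNED_LEN,
    min_identity: float = MIN_IDENTITY,
    margin_bits: float = UNIQUENESS_MARGIN_BITS,
) -> FlankHit | None:
    """Best unique hit of a query in the indexed genome, or None.

    A query is mapped when its best hit clears the aligned-length and
    identity floors and out-scores the second-best location by at least
    the uniqueness margin.
    """
    hits: list[FlankHit] = []
    for contig, strand, diag in index.candidates(query):
        hit = _score_diagonal(query, index.genome[contig], strand, diag)
        if hit is None:
            continue
        hit.contig = contig
        hits.append(hit)
    if not hits:
        return None
    # merge near-identical diagonals (same locus seeded several times)
    hits.sort(key=lambda h: -h.score)
    kept: list[FlankHit] = []
    for h in hits:
        if any(
            k.contig == h.contig and k.strand == h.strand and abs(k.diag - h.diag) <= 5
            for k in kept
        ):
            continue
        kept.append(h)
    best = kept[0]
    if best.q_end - best.q_start < min_aligned or best.identity < min_identity:
        return None
    if len(kept) > 1 and best.bitscore - kept[1].bitscore < margin_bits:
        return None  # ambiguous placement
    return best


def call_presence(
    q5_hit: FlankHit | None,
    q3_hit: FlankHit | None,
    element_length: int,
    locus_id: str = "",
    species: str = "",
    flank_len: int = DEFAULT_FLANK_LEN,
    length_tol: float = PRESENT_LENGTH_TOL,
    absent_max_gap: int = ABSENT_MAX_GAP,
    require_junction: bool = True,
) -> PresenceCall:
    """Combine the two flank hits into a present/absent/inconclusive call.

    The element boundary sits at query offset flank_len/2 in both queries;
    extrapolating each hit's diagonal to that offset gives the two mapped
    boundary points, whose separation D is the implied length of sequence
    between the flanks. present: |D - L| <= length_tol * L with junction
    support (inner halves aligned at >= 60% identity); absent: |D| <=
    absent_max_gap (flanks nearly adjacent); otherwise inconclusive.
    """
    if element_length <= 0:
        raise ValueError("element_length must be positive")
    half = flank_len // 2
    ev = {
        "flank5_mapped": q5_hit is not None,
        "flank3_mapped": q3_hit is not None,
        "colinear": False,
        "junction_support": False,
    }
    if q5_hit is None or q3_hit is None:
        return PresenceCall(locus_id, species, "inconclusive", ev)
    if q5_hit.contig != q3_hit.contig or q5_hit.strand != q3_hit.strand:
        return PresenceCall(locus_id, species, "inconclusive", ev)
    b5 = q5_hit.subject_pos(half)
    b3 = q3_hit.subject_pos(half)
    d = b3 - b5 if q5_hit.strand == "+" else b5 - b3
    if d < -absent_max_gap:
        return PresenceCall(locus_id, species, "inconclusive", ev)
    ev["colinear"] = True
    # junction (inner-half) support: q5 inner = [half, flank), q3 inner = [0, half)
    j5 = q5_hit.range_identity(half, flank_len)
    j3 = q3_hit.range_identity(0, half)
    ev["junction_support"] = bool(
        j5 >= JUNCTION_MIN_IDENTITY and j3 >= JUNCTION_MIN_IDENTITY
    )
    ev["implied_length"] = int(d)
    if abs(d - element_length) <= length_tol * element_length and (
        ev["junction_support"] or not require_junction
    ):
        return PresenceCall(locus_id, species, "present", ev)
    if abs(d) <= absent_max_gap:
        return PresenceCall(locus_id, species, "absent", ev)
    return PresenceCall(locus_id, species, "inconclusive", ev)


def hits_from_alignment_table(
    alignment_hits: Sequence[AlignmentHit], query_id: str, qlen: int = DEFAULT_FLANK_LEN
) -> FlankHit | None:
    """Adapt precomputed blast-style tabular hits to the FlankHit interface.

    The best hit is taken; uniqueness requires a >= 5-bit margin over the
    second best. Junction support is approximated from span coverage since
    per-base matches are unavailable in tabular output.
    """
    mine = sorted(
        (h for h in alignment_hits if h.query_id == query_id),
        key=lambda h: -h.bitscore,
    )
    if not mine:
        return None
    best = mine[0]
    if len(mine) > 1 and best.bitscore - mine[1].bitscore < UNIQUENESS_MARGIN_BITS:
        return None
    if best.aligned_length < MIN_ALIGNED_LEN or best.identity_pct < 100 * MIN_IDENTITY:
        return None
    qs, qe = best.query_span
    ss, se = best.subject_span
    strand = "+" if se >= ss else "-"
    q_start, q_end = qs - 1, qe  # to 0-based half-open
    if strand == "+":
        diag = (ss - 1) - q_start
    else:
        # subject_pos = diag + (qlen - 1 - qpos); at qpos=q_start subject is ss-1
        diag = (ss - 1) - (qlen - 1 - q_start)
    matches = np.full(qlen, -1, dtype=np.int8)
    matches[q_start:q_end] = 1  # coverage stands in for per-base identity
    return FlankHit(
        contig=best.subject, strand=strand, diag=diag, qlen=qlen,
        q_start=q_start, q_end=q_end,
        score=best.bitscore / BITS_PER_SCORE,
        identity=best.identity_pct / 100.0, matches=matches,
    )


def call_species(
    instances: Sequence[RepeatInstance],
    ref_genome: Mapping[str, str],
    target_genome: Mapping[str, str],
    species: str,
    flank_len: int = DEFAULT_FLANK_LEN,
    require_junction: bool = True,
    index: KmerIndex | None = None,
) -> list[PresenceCall]:
    """Presence calls for every (non-edge) instance in one target genome."""
    if index is None:
        index = KmerIndex(target_genome)
    calls = []
    for n, rep in enumerate(instances):
        locus_id = f"{rep.interval.chrom}:{rep.interval.start}-{rep.interval.end}"
        queries = extract_flank_queries(rep, ref_genome, flank_len)
        if queries is None:
            continue
        q5 = map_query(queries["q5"], index)
        q3 = map_query(queries["q3"], index)
        calls.append(
            call_presence(
                q5, q3, len(rep.interval), locus_id=locus_id, species=species,
                flank_len=flank_len, require_junction=require_junction,
            )
        )
    return calls


STATE_CODE = {"present": 1.0, "absent": 0.0, "inconclusive": float("nan")}


def conservation_matrix(calls: Sequence[PresenceCall]) -> tuple[pd.DataFrame, pd.Series]:
    """Locus x species state matrix ({1, 0, NA}) and per-species present
    fraction over conclusive calls."""
    seen = set()
    for c in calls:
        key = (c.locus_id, c.species)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    df = pd.DataFrame(
        [(c.locus_id, c.species, STATE_CODE[c.state]) for c in calls],
        columns=["locus", "species", "state"],
    )
    matrix = df.pivot(index="locus", columns="species", values="state")
    fractions = matrix.mean(axis=0, skipna=True)
    return matrix, fractions
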