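"""Transposable-element overlap statistics and per-consensus-position Alu
analyses.

Family-level enrichment against a bp-fraction expectation, proportional
mapping of genomic positions onto repeat-consensus coordinates,
per-position peak-overlap frequency, the 5'-vs-3' end asymmetry test,
per-position information content in nats, and aggregate cut profiles in
consensus coordinates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CutProfile, GenomicInterval, RepeatInstance

logger = logging.getLogger(__name__)


def _merged_bp(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merged (start, end) arrays per chrom."""
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in groups.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)
    return out


def _total_bp(merged: Mapping[str, np.ndarray]) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in merged.values()))


def _intersect_bp(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]) -> int:
    total = 0
    for chrom, arr_a in a.items():
        arr_b = b.get(chrom)
        if arr_b is None:
            continue
        i = j = 0
        while i < len(arr_a) and j < len(arr_b):
            lo = max(arr_a[i, 0], arr_b[j, 0])
            hi = min(arr_a[i, 1], arr_b[j, 1])
            if hi > lo:
                total += hi - lo
            if arr_a[i, 1] < arr_b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def family_overlap_enrichment(
    peaks: Sequence[GenomicInterval],
    repeats: Sequence[RepeatInstance],
    genome_length: int,
) -> pd.DataFrame:
    """Per-family peak-overlap enrichment at 1-bp resolution.

    The 2x2 table cross-classifies every genomic bp as in-peak vs not and
    in-family vs not; the two-sided Fisher exact p and the odds ratio give
    the direction (depleted OR < 1, enriched OR > 1). The expected overlap
    is the family's genomic bp fraction applied to total peak bp. Also
    reports the count of peaks overlapping >= 1 instance of the family.
    """
    peak_merged = _merged_bp(peaks)
    peak_bp = _total_bp(peak_merged)
    families = sorted({r.family for r in repeats})
    rows = []
    for family in families:
        fam_ivs = [r.interval for r in repeats if r.family == family]
        fam_merged = _merged_bp(fam_ivs)
        fam_bp = _total_bp(fam_merged)
        overlap_bp = _intersect_bp(peak_merged, fam_merged)
        expected_bp = peak_bp * fam_bp / genome_length
        table = np.array(
            [
                [overlap_bp, peak_bp - overlap_bp],
                [fam_bp - overlap_bp, genome_length - peak_bp - fam_bp + overlap_bp],
            ]
        )
        if np.any(table < 0):
            raise ValueError("bp accounting exceeded genome_length")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        n_peaks_overlapping = sum(
            1
            for iv in peaks
            if _point_in_merged(fam_merged, iv.chrom, iv.start, iv.end)
        )
        rows.append(
            {
                "family": family,
                "family_bp": fam_bp,
                "observed_overlap_bp": overlap_bp,
                "expected_overlap_bp": expected_bp,
                "n_peaks_overlapping": n_peaks_overlapping,
                "odds_ratio": float(odds),
                "fisher_p": float(p),
                "direction": "enriched" if overlap_bp > expected_bp else "depleted",
            }
        )
    return pd.DataFrame(rows).set_index("family")


def _point_in_merged(merged: Mapping[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    arr = merged.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = np.searchsorted(arr[:, 0], end, side="left")
    return bool(np.any(arr[:i, 1] > start))


def map_to_consensus(instance: RepeatInstance, genomic_pos: int) -> int:
    """Map a genomic position inside a repeat copy to consensus coordinates.

    Proportional scaling, strand-aware: a minus-strand instance is read
    from its genomic right edge, so its genomic left edge maps to the
    consensus 3' end.
    """
    iv = instance.interval
    if not iv.start <= genomic_pos < iv.end:
        raise ValueError(f"position {genomic_pos} outside instance [{iv.start}, {iv.end})")
    length = len(iv)
    if iv.strand == "-":
        along = iv.end - genomic_pos
    else:
        along = genomic_pos - iv.start
    return int(round(along / length * instance.consensus_length))


def _consensus_to_genomic(instance: RepeatInstance, consensus_pos: int) -> int:
    """Inverse proportional mapping; consensus positions outside [0, CL]
    land in the strand-aware genomic flanks."""
    iv = instance.interval
    length = len(iv)
    offset = int(round(consensus_pos / instance.consensus_length * length))
    if iv.strand == "-":
        return iv.end - offset
    return iv.start + offset


def position_overlap_frequency(
    instances: Sequence[RepeatInstance],
    peaks: Sequence[GenomicInterval],
    min_len: int = 300,
    flank: int = 50,
) -> pd.DataFrame:
    """Fraction of repeat copies whose base at each consensus position lies
    in a peak.

    Instances shorter than ``min_len`` are dropped; ``flank`` consensus-
    flank positions are evaluated on each side (strand-aware genomic
    flanks).
    """
    kept = [r for r in instances if len(r.interval) >= min_len]
    if not kept:
        raise ValueError(f"no instances of length >= {min_len}")
    peak_merged = _merged_bp(peaks)
    cl = max(r.consensus_length for r in kept)
    positions = np.arange(-flank, cl + flank + 1)
    frac = np.zeros(len(positions), dtype=float)
    n_eval = np.zeros(len(positions), dtype=np.int64)
    for rep in kept:
        for j, cpos in enumerate(positions):
            if cpos > rep.consensus_length + flank:
                continue
            gpos = _consensus_to_genomic(rep, int(cpos))
            n_eval[j] += 1
            if _point_in_merged(peak_merged, rep.interval.chrom, gpos, gpos + 1):
                frac[j] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(n_eval > 0, frac / np.maximum(n_eval, 1), np.nan)
    return pd.DataFrame({"consensus_pos": positions, "overlap_fraction": frac, "n": n_eval})


def end_asymmetry_test(
    instances: Sequence[RepeatInstance],
    peaks: Sequence[GenomicInterval],
    end_window: int = 50,
    min_len: int = 0,
) -> dict:
    """Two-sided exact binomial test of 3'-only vs 5'-only peak overlap.

    For each instance the strand-aware 5' and 3' terminal windows are
    tested for >= 1 bp peak overlap; instances with exactly one
    overlapping end are informative; the test is binomial(n_3prime_only,
    n_informative, 0.5). Returns NA when nothing is informative.
    """
    peak_merged = _merged_bp(peaks)
    n3 = n5 = 0
    for rep in instances:
        iv = rep.interval
        if len(iv) < max(min_len, end_window):
            continue
        left = (iv.start, iv.start + end_window)
        right = (iv.end - end_window, iv.end)
        if iv.strand == "-":
            w5, w3 = right, left
        else:
            w5, w3 = left, right
        in5 = _point_in_merged(peak_merged, iv.chrom, *w5)
        in3 = _point_in_merged(peak_merged, iv.chrom, *w3)
        if in3 and not in5:
            n3 += 1
        elif in5 and not in3:
            n5 += 1
    n = n3 + n5
    if n == 0:
        return {"n_3prime_only": 0, "n_5prime_only": 0, "binomial_p": float("nan")}
    p = float(stats.binomtest(n3, n, 0.5).pvalue)
    return {"n_3prime_only": n3, "n_5prime_only": n5, "binomial_p": p}


LN4 = float(np.log(4.0))
ENTROPY_PSEUDOCOUNT = 0.25
MIN_COLUMN_OBS = 10


def entropy_profile(columns: Sequence[str]) -> pd.DataFrame:
    """Per-position information content in nats, ln(4) - H.

    Each element of ``columns`` is the string of base calls observed at
    one consensus position across aligned repeat copies. Base frequencies
    use a pseudocount of 0.25 per base; H is the Shannon entropy in nats,
    so fully conserved columns approach ln 4 ~ 1.386 and uniform columns
    approach 0. Columns with fewer than 10 observations are flagged;
    empty columns give NA.
    """
    rows = []
    for pos, col in enumerate(columns):
        bases = [b for b in col.upper() if b in "ACGT"]
        n = len(bases)
        if n == 0:
            rows.append({"consensus_pos": pos, "information_nats": float("nan"),
                         "n": 0, "low_coverage": True})
            continue
        freqs = np.array(
            [bases.count(b) + ENTROPY_PSEUDOCOUNT for b in "ACGT"], dtype=float
        )
        freqs /= freqs.sum()
        h = float(-(freqs * np.log(freqs)).sum())
        rows.append(
            {
                "consensus_pos": pos,
                "information_nats": LN4 - h,
                "n": n,
                "low_coverage": n < MIN_COLUMN_OBS,
            }
        )
    return pd.DataFrame(rows)


def aggregate_cut_profile_over_elements(
    cuts: pd.DataFrame,
    instances: Sequence[RepeatInstance],
    min_len: int = 300,
    flank: int = 50,
) -> CutProfile:
    """Average stranded cut counts in consensus coordinates over repeat copies.

    Each instance's window (element plus ``flank`` bp of strand-aware
    surrounding sequence) is oriented by strand, cut positions are mapped
    proportionally onto the consensus, and per-position counts are
    averaged over instances. Strand labels are swapped for minus-strand
    copies so plus always means the element's sense strand.
    """
    kept = [r for r in instances if len(r.interval) >= min_len]
    if not kept:
        raise ValueError(f"no instances of length >= {min_len}")
    cl = max(r.consensus_length for r in kept)
    width = cl + 2 * flank + 1
    plus = np.zeros(width, dtype=float)
    minus = np.zeros(width, dtype=float)
    arrays: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), grp in cuts.groupby(["chrom", "strand"], sort=False):
        arrays[(str(chrom), str(strand))] = np.sort(grp["pos"].to_numpy())
    for rep in kept:
        iv = rep.interval
        length = len(iv)
        g_lo, g_hi = iv.start - flank, iv.end + flank
        for strand in ("+", "-"):
            positions = arrays.get((iv.chrom, strand))
            if positions is None or len(positions) == 0:
                continue
            lo = np.searchsorted(positions, g_lo, side="left")
            hi = np.searchsorted(positions, g_hi, side="left")
            sel = positions[lo:hi]
            if iv.strand == "-":
                along = iv.end - sel  # bp from the element's 5' end, flanks negative left
                out_strand = "-" if strand == "+" else "+"
            else:
                along = sel - iv.start
                out_strand = strand
            cpos = np.rint(along / length * rep.consensus_length).astype(np.int64) + flank
            cpos = cpos[(cpos >= 0) & (cpos < width)]
            counts = np.bincount(cpos, minlength=width).astype(float)
            if out_strand == "+":
                plus += counts
            else:
                minus += counts
    n = len(kept)
    return CutProfile(
        window=width, plus_counts=plus / n, minus_counts=minus / n, n_sites=n, motif_width=cl
    )
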