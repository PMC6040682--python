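"""Tn5 cut-site extraction and aggregate footprint profiles.

A bound factor protects its motif from transposition, producing a notch
in the aggregate cut profile flanked by excess plus-strand cuts 5' of
the motif and minus-strand cuts 3' of it. The depth/asymmetry statistic
summarizes that geometry per aggregated profile.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CutProfile, MotifHit

logger = logging.getLogger(__name__)

# Tn5 insertion offsets: the transposase cuts 4 bp in from the plus-strand
# fragment end and 5 bp in from the minus-strand end.
TN5_PLUS_OFFSET = 4
TN5_MINUS_OFFSET = 5
MIN_FRAGMENT_LEN = 10


def fragments_to_cuts(fragments: pd.DataFrame) -> pd.DataFrame:
    """Convert fragments to stranded single-base cut positions.

    Each fragment ``[start, end)`` yields a plus-strand cut at start+4 and
    a minus-strand cut at end-5. Fragments shorter than 10 bp are skipped
    with a warning. Returns a DataFrame with columns chrom, pos, strand.
    """
    lengths = fragments["end"] - fragments["start"]
    short = lengths < MIN_FRAGMENT_LEN
    if short.any():
        logger.warning("skipping %d fragments shorter than %d bp", int(short.sum()), MIN_FRAGMENT_LEN)
    frag = fragments.loc[~short]
    plus = pd.DataFrame(
        {"chrom": frag["chrom"], "pos": frag["start"] + TN5_PLUS_OFFSET, "strand": "+"}
    )
    minus = pd.DataFrame(
        {"chrom": frag["chrom"], "pos": frag["end"] - TN5_MINUS_OFFSET, "strand": "-"}
    )
    return pd.concat([plus, minus], ignore_index=True)


def cut_arrays(cuts: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """Sorted cut-position arrays keyed by (chrom, strand); precompute once
    when profiling many motif sites individually."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), grp in cuts.groupby(["chrom", "strand"], sort=False):
        out[(str(chrom), str(strand))] = np.sort(grp["pos"].to_numpy())
    return out


def aggregate_profile(
    cuts: pd.DataFrame | dict, motif_hits: Sequence[MotifHit], window: int = 200
) -> CutProfile:
    """Average stranded cut counts in windows centered on motif hits.

    Windows around minus-strand hits are flipped and their strand labels
    swapped, so every aggregated window reads 5'-to-3' along the motif.
    Counts are divided by the number of aggregated sites.
    """
    if not motif_hits:
        raise ValueError("need at least one motif hit")
    widths = {len(h.interval) for h in motif_hits}
    motif_width = max(widths)
    if window < motif_width:
        raise ValueError("window must be at least the motif width")
    arrays = cuts if isinstance(cuts, dict) else cut_arrays(cuts)
    half = window // 2
    plus = np.zeros(window, dtype=float)
    minus = np.zeros(window, dtype=float)
    offsets = np.arange(window)
    for hit in motif_hits:
        center = hit.interval.midpoint
        w_start = center - half
        flip = hit.interval.strand == "-"
        for strand_label, arr_key in (("+", "+"), ("-", "-")):
            key = (hit.interval.chrom, arr_key)
            positions = arrays.get(key)
            if positions is None or len(positions) == 0:
                continue
            lo = np.searchsorted(positions, w_start, side="left")
            hi = np.searchsorted(positions, w_start + window, side="left")
            rel = positions[lo:hi] - w_start
            counts = np.bincount(rel, minlength=window)[:window].astype(float)
            if flip:
                counts = counts[::-1]
                strand_label = "-" if strand_label == "+" else "+"
            if strand_label == "+":
                plus += counts
            else:
                minus += counts
    n = len(motif_hits)
    return CutProfile(
        window=window,
        plus_counts=plus / n,
        minus_counts=minus / n,
        n_sites=n,
        motif_width=motif_width,
    )


def footprint_depth(profile: CutProfile, flank: int = 50) -> dict:
    """Depth and strand asymmetry of an aggregate footprint.

    depth = log2((mean total cuts over the flanks + eps) /
                 (mean total cuts over the motif core + eps)),
    eps = 0.5 / n_sites. The core is the central ``motif_width`` bp of the
    window; the flanks are the ``flank`` bp immediately 5' and 3' of it.
    asymmetry = (P5' - P3') / (P5' + P3') on plus-strand cuts in the two
    flanks: positive when plus-strand cuts pile up 5' of the motif, the
    bound-factor geometry.
    """
    w, mw = profile.window, profile.motif_width
    if 2 * flank + mw > w:
        raise ValueError("flanks plus motif core exceed the window")
    core_lo = (w - mw) // 2
    core_hi = core_lo + mw
    f5 = slice(core_lo - flank, core_lo)
    f3 = slice(core_hi, core_hi + flank)
    total = profile.plus_counts + profile.minus_counts
    eps = 0.5 / max(profile.n_sites, 1)
    flank_mean = float(np.concatenate([total[f5], total[f3]]).mean())
    core_mean = float(total[core_lo:core_hi].mean())
    depth = float(np.log2((flank_mean + eps) / (core_mean + eps)))
    p5 = float(profile.plus_counts[f5].sum())
    p3 = float(profile.plus_counts[f3].sum())
    asym = (p5 - p3) / (p5 + p3) if (p5 + p3) > 0 else 0.0
    return {"depth": depth, "asymmetry": asym, "flank_mean": flank_mean, "core_mean": core_mean}


def profile_to_frame(profile: CutProfile) -> pd.DataFrame:
    """Tabular export: offset (centered), plus_mean, minus_mean."""
    half = profile.window // 2
    return pd.DataFrame(
        {
            "offset": np.arange(profile.window) - half,
            "plus_mean": profile.plus_counts,
            "minus_mean": profile.minus_counts,
        }
    )
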