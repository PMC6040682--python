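"""Differential chromatin accessibility between two conditions.

Fragment counting in peaks, a transparent negative-binomial Wald test
(median-of-ratios normalization, method-of-moments dispersion, no
shrinkage), signed ranking in which low ranks are the most strongly
opening peaks and high ranks the most strongly closing, Bonferroni-based
dynamic-state classification, genomic annotation, and generic peak-set
overlap utilities.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Gene, GenomicInterval, Peak

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


def count_fragments(
    fragments: pd.DataFrame, peaks: Sequence[Peak], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Count fragments overlapping each peak by >= 1 bp, per sample.

    Peaks must be non-overlapping after merge; a fragment spanning two
    peaks increments both (union-style counting). Returns a peak x sample
    integer DataFrame indexed by peak id, with per-sample totals in
    ``df.attrs['totals']``.
    """
    if samples is None:
        samples = sorted(fragments["sample"].unique())
    counts = pd.DataFrame(
        0, index=[p.id for p in peaks], columns=list(samples), dtype=np.int64
    )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.interval.chrom for p in peaks}:
        ps = [(i, p) for i, p in enumerate(peaks) if p.interval.chrom == chrom]
        ps.sort(key=lambda x: x[1].interval.start)
        starts = np.array([p.interval.start for _, p in ps])
        ends = np.array([p.interval.end for _, p in ps])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"peaks overlap on {chrom}; merge before counting")
        by_chrom[chrom] = (starts, ends, np.array([i for i, _ in ps]))

    totals: dict[str, int] = {}
    for sample in samples:
        sub = fragments[fragments["sample"] == sample]
        if len(sub) == 0:
            raise ValueError(f"sample {sample!r} has zero fragments")
        totals[sample] = len(sub)
        col = counts.columns.get_loc(sample)
        for chrom, grp in sub.groupby("chrom", sort=False):
            entry = by_chrom.get(str(chrom))
            if entry is None:
                continue
            starts, ends, order = entry
            fs = grp["start"].to_numpy()
            fe = grp["end"].to_numpy()
            # with disjoint sorted peaks, a fragment overlaps peaks
            # j in [searchsorted(ends, fs, 'right'), searchsorted(starts, fe, 'left'))
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            valid = hi > lo
            inc = np.zeros(len(starts) + 1, dtype=np.int64)
            np.add.at(inc, lo[valid], 1)
            np.add.at(inc, hi[valid], -1)
            per_peak = np.cumsum(inc[:-1])
            counts.iloc[order, col] += per_peak
    counts.attrs["totals"] = totals
    return counts


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference)."""
    mat = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        logger.warning("no all-positive rows; falling back to total-count scaling")
        totals = mat.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    ref = log_mat[positive].mean(axis=1)
    sf = np.exp(np.median(log_mat[positive] - ref[:, None], axis=0))
    return sf


def nb_differential(counts: pd.DataFrame, condition: Sequence[str]) -> pd.DataFrame:
    """Simplified negative-binomial Wald test on a two-condition counts matrix.

    Size factors by median-of-ratios; dispersion by method of moments on
    normalized counts, pooled across peaks and conditions into a single
    common value (floored at 1e-8) — with 3 + 3 replicates a per-peak
    estimate is too unstable to calibrate the Wald test; Wald z on the
    log2 fold change of normalized condition means (pseudocount 0.5);
    two-sided normal p; Bonferroni adjustment. All-zero peaks get
    log2fc = 0 and p = 1 by convention.
    """
    condition = np.asarray(condition)
    levels = pd.unique(condition)
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {list(levels)}")
    for lev in levels:
        if (condition == lev).sum() < 2:
            raise ValueError(f"condition {lev!r} has fewer than 2 samples")
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    sf = size_factors(mat)
    norm = mat / sf[None, :]
    mask_a = condition == levels[0]
    mask_b = condition == levels[1]
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    mu_a = norm[:, mask_a].mean(axis=1)
    mu_b = norm[:, mask_b].mean(axis=1)
    var_a = norm[:, mask_a].var(axis=1, ddof=1)
    var_b = norm[:, mask_b].var(axis=1, ddof=1)

    # method-of-moments dispersion (var = mu + a*mu^2) pooled across peaks
    # and conditions into one common estimate
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (var_a - mu_a) / mu_a**2
        disp_b = (var_b - mu_b) / mu_b**2
    per_peak = np.nanmean(np.stack([disp_a, disp_b]), axis=0)
    finite = per_peak[np.isfinite(per_peak)]
    pooled = float(np.mean(finite)) if len(finite) else 0.0
    disp = np.full(mat.shape[0], max(pooled, DISPERSION_FLOOR))

    log2fc = np.log2((mu_b + LOG2FC_PSEUDOCOUNT) / (mu_a + LOG2FC_PSEUDOCOUNT))
    # delta-method variance of log2 of an NB condition mean
    def _se2(mu: np.ndarray, n: int) -> np.ndarray:
        var_mean = (mu + disp * mu**2) / n
        return var_mean / ((mu + LOG2FC_PSEUDOCOUNT) ** 2 * np.log(2) ** 2)

    se = np.sqrt(_se2(mu_a, na) + _se2(mu_b, nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    zero = mat.sum(axis=1) == 0
    log2fc[zero] = 0.0
    pvalue[np.isnan(pvalue)] = 1.0
    pvalue[zero] = 1.0
    m = mat.shape[0]
    padj = np.minimum(pvalue * m, 1.0)
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "dispersion": disp,
        },
        index=counts.index,
    )


def rank_peaks(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Signed ranking: rank 1 = most significant opening peak, rank m = most
    significant closing peak; log2fc == 0 peaks sit between, least
    significant first among the closing/zero block. Ties break by input
    order (stable sort). Returns the frame with a ``rank`` column added.
    """
    if stats_df["pvalue"].isna().any():
        raise ValueError("every peak needs a p-value before ranking")
    fc = stats_df["log2fc"].to_numpy()
    p = stats_df["pvalue"].to_numpy()
    block = np.where(fc > 0, 0, np.where(fc == 0, 1, 2))
    key_p = np.where(block == 0, p, -p)
    order = np.lexsort((np.arange(len(p)), key_p, block))
    rank = np.empty(len(p), dtype=np.int64)
    rank[order] = np.arange(1, len(p) + 1)
    out = stats_df.copy()
    out["rank"] = rank
    return out


def classify_dynamic(ranked: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-thresholded opening/closing/unchanged states."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    padj = ranked["padj"].to_numpy()
    fc = ranked["log2fc"].to_numpy()
    state = np.where(
        (padj < alpha) & (fc > 0),
        "opening",
        np.where((padj < alpha) & (fc < 0), "closing", "unchanged"),
    )
    out = ranked.copy()
    out["state"] = state
    return out


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    exons: Sequence[GenomicInterval] = (),
    introns: Sequence[GenomicInterval] = (),
    upstream: int = 10_000,
) -> pd.DataFrame:
    """Categorize peaks as upstream_10kb / exon / intron / intergenic.

    Precedence: strand-aware 10-kb upstream window of any TSS beats exon
    beats intron beats intergenic.
    """
    if not genes:
        raise ValueError("gene list with TSSs required")
    upstream_windows = []
    for g in genes:
        t = g.tss
        if t.strand == "-":
            win = (t.chrom, t.start + 1, t.start + 1 + upstream)
        else:
            win = (t.chrom, max(0, t.start - upstream), t.start)
        if win[2] > win[1]:
            upstream_windows.append(win)

    def _sorted_arrays(items):
        groups: dict[str, list[tuple[int, int]]] = {}
        for it in items:
            if isinstance(it, tuple):
                chrom, s, e = it
            else:
                chrom, s, e = it.chrom, it.start, it.end
            groups.setdefault(chrom, []).append((s, e))
        out = {}
        for chrom, ivs in groups.items():
            ivs.sort()
            out[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        return out

    def _hits(arrays, chrom, s, e) -> bool:
        entry = arrays.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = np.searchsorted(starts, e, side="left")
        return bool(np.any(ends[:i] > s))

    up_arr = _sorted_arrays(upstream_windows)
    ex_arr = _sorted_arrays(exons)
    in_arr = _sorted_arrays(introns)
    rows = []
    for p in peaks:
        iv = p.interval
        if _hits(up_arr, iv.chrom, iv.start, iv.end):
            cat = "upstream_10kb"
        elif _hits(ex_arr, iv.chrom, iv.start, iv.end):
            cat = "exon"
        elif _hits(in_arr, iv.chrom, iv.start, iv.end):
            cat = "intron"
        else:
            cat = "intergenic"
        rows.append((p.id, cat))
    return pd.DataFrame(rows, columns=["id", "category"]).set_index("id")


def category_fractions(annotation: pd.DataFrame, subset: Sequence[str] | None = None) -> pd.Series:
    ann = annotation if subset is None else annotation.loc[list(subset)]
    return ann["category"].value_counts(normalize=True)


def peak_overlap_fraction(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    expected_fraction: float | None = None,
) -> dict:
    """Fraction of A intervals overlapped (>= 1 bp) by any B interval.

    With an ``expected_fraction``, adds an exact binomial p-value on the
    overlapped count.
    """
    if not set_a:
        raise ValueError("set A is empty")
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in set_b:
        groups.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrays = {}
    for chrom, ivs in groups.items():
        ivs.sort()
        arrays[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
    n_overlap = 0
    for iv in set_a:
        entry = arrays.get(iv.chrom)
        if entry is None:
            continue
        starts, ends = entry
        i = np.searchsorted(starts, iv.end, side="left")
        if np.any(ends[:i] > iv.start):
            n_overlap += 1
    result = {
        "n_a": len(set_a),
        "n_overlapping": n_overlap,
        "fraction": n_overlap / len(set_a),
    }
    if expected_fraction is not None:
        result["binomial_p"] = float(
            stats.binomtest(n_overlap, len(set_a), expected_fraction).pvalue
        )
    return result


def rank_bin_frequency(
    ranked: pd.DataFrame,
    hits: set[str],
    bin_size: int = 10_000,
    expected_fraction: float | None = None,
) -> pd.DataFrame:
    """Per-bin hit fraction across rank-ordered peaks.

    Bins partition ranks 1..m in order (last bin may be short); the
    expected background fraction — motif frequency in size-matched random
    regions, or a TE family's genomic bp fraction — is whatever the caller
    supplies and is repeated per bin for plotting.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = ranked.sort_values("rank")
    ids = df.index.to_numpy()
    is_hit = np.array([i in hits for i in ids], dtype=float)
    m = len(ids)
    rows = []
    for b, lo in enumerate(range(0, m, bin_size)):
        chunk = is_hit[lo : lo + bin_size]
        rows.append(
            {
                "bin": b,
                "rank_lo": lo + 1,
                "rank_hi": min(lo + bin_size, m),
                "n_peaks": len(chunk),
                "hit_fraction": float(chunk.mean()),
                "expected_fraction": expected_fraction,
            }
        )
    return pd.DataFrame(rows)
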