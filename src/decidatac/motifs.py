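"""PWM scanning with exact score calibration and composite-motif discovery.

The score-threshold machinery computes the exact distribution of the
log-odds score under the background model by position-wise convolution
over granularity-discretized scores, so hit p-values are calibrated the
way FIMO calibrates them. On top of that sit enrichment against
GC/CpG-matched backgrounds and the ESR -> bZIP -> Pax triple-motif
scanner used to characterize the 3' end of Alu elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import PWM, GenomicInterval, MotifHit, RepeatInstance, TripleMotifHit, encode_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact background distribution of a PWM's log-odds score.

    ``scores`` ascending (bits, discretized to the granularity used);
    ``tail[i]`` = P(score >= scores[i]).
    """

    scores: np.ndarray
    tail: np.ndarray
    granularity: float

    def pvalue(self, score: float) -> float:
        """P(background score >= observed), discretization-conservative.

        Grid scores are floor-discretized, so the tail at the largest grid
        score <= the observed score bounds the true p-value from above.
        """
        idx = int(np.searchsorted(self.scores, score + 1e-12, side="right")) - 1
        if idx < 0:
            return 1.0
        return float(self.tail[idx])


def score_distribution(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact DP over discretized per-position scores under the background.

    Per-position scores are floor-discretized to multiples of
    ``granularity`` (so grid sums never exceed true sums and thresholds
    stay conservative); the support is merged after every position, so the
    cost is bounded by the score span over the granularity (and by 4^L for
    short motifs, where the result is effectively exact). Total
    discretization error <= L * granularity.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    ks = np.floor(pwm.log_odds / granularity).astype(np.int64)  # L x 4
    bg = pwm.background
    support = np.zeros(1, dtype=np.int64)
    probs = np.ones(1, dtype=float)
    for i in range(len(pwm)):
        sums = (support[:, None] + ks[i][None, :]).ravel()
        ps = (probs[:, None] * bg[None, :]).ravel()
        support, inverse = np.unique(sums, return_inverse=True)
        merged = np.zeros(len(support), dtype=float)
        np.add.at(merged, inverse, ps)
        probs = merged
    scores = support * granularity
    tail = np.cumsum(probs[::-1])[::-1]
    return ScoreDistribution(scores=scores, tail=np.minimum(tail, 1.0), granularity=granularity)


def score_threshold(
    pwm: PWM, alpha: float, granularity: float = 1e-3
) -> tuple[float, ScoreDistribution]:
    """Smallest achievable score t with P(score >= t) <= alpha.

    If even the maximal score is more probable than alpha (e.g. a uniform
    motif), the maximal achievable score is returned, so scanning reports
    only top-scoring matches.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    dist = score_distribution(pwm, granularity=granularity)
    ok = dist.tail <= alpha
    if ok.any():
        threshold = float(dist.scores[int(np.argmax(ok))])
    else:
        threshold = float(dist.scores[-1])
    return threshold, dist


def _window_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every length-L window; windows touching N -> -inf."""
    L = log_odds.shape[0]
    n = enc.shape[0]
    if n < L:
        return np.empty(0, dtype=float)
    lut = np.full((L, 5), -np.inf)
    lut[:, :4] = log_odds
    total = np.zeros(n - L + 1, dtype=float)
    for i in range(L):
        total += lut[i, enc[i : n - L + 1 + i]]
    return total


def scan(
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan both strands of every sequence; report hits with score >= threshold.

    A minus-strand hit at ``[pos, pos+L)`` means the reverse complement of
    that window matches the motif. Hit p-values come from the exact score
    distribution when supplied.
    """
    L = len(pwm)
    hits: list[MotifHit] = []
    rc = pwm.reverse_complement()
    for chrom, seq in sequences.items():
        if len(seq) < L:
            continue
        enc = encode_sequence(seq)
        for strand, mat in (("+", pwm.log_odds), ("-", rc.log_odds)):
            scores = _window_scores(enc, mat)
            idx = np.nonzero(scores >= threshold)[0]
            for pos in idx:
                s = float(scores[pos])
                hits.append(
                    MotifHit(
                        motif=pwm.name,
                        interval=GenomicInterval(chrom, int(pos), int(pos) + L, strand),
                        score=s,
                        pvalue=dist.pvalue(s) if dist is not None else float("nan"),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def cpg_observed_expected(seq: str) -> float:
    """CpG o/e = (#CG dinucleotides * length) / (#C * #G); 0 if C or G absent."""
    s = seq.upper()
    c, g = s.count("C"), s.count("G")
    if c == 0 or g == 0:
        return 0.0
    return s.count("CG") * len(s) / (c * g)


def sample_matched_background(
    input_peaks: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    tss_list: Sequence,
    n_per_input: int = 1,
    seed: int = 0,
    tss_window: int = 50_000,
    gc_bin: float = 0.05,
    cpg_bin: float = 0.1,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Draw width-, GC- and CpG-matched background intervals near TSSs.

    Each background interval has the width of its matched input peak, lies
    within ``tss_window`` of some TSS, and falls in the same GC-fraction
    bin (width ``gc_bin``) and CpG observed/expected bin (width
    ``cpg_bin``). Sampling is without replacement; a bin exhausted after
    ``max_tries`` draws falls back to the nearest candidate seen, with a
    warning.
    """
    rng = np.random.default_rng(seed)
    # candidate start ranges: union of TSS +/- window per chrom
    regions: list[tuple[str, int, int]] = []
    for gene in tss_list:
        t = gene.tss
        chrom_len = len(genome[t.chrom])
        lo = max(0, t.start - tss_window)
        hi = min(chrom_len, t.start + tss_window)
        if hi > lo:
            regions.append((t.chrom, lo, hi))
    if not regions:
        raise ValueError("no TSS regions available for background sampling")
    lengths = np.array([hi - lo for _, lo, hi in regions], dtype=float)
    region_p = lengths / lengths.sum()

    used: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for peak in input_peaks:
        width = len(peak)
        seq = genome[peak.chrom][peak.start : peak.end]
        gbin = int(gc_fraction(seq) / gc_bin)
        cbin = int(cpg_observed_expected(seq) / cpg_bin)
        for _ in range(n_per_input):
            best: tuple[float, GenomicInterval] | None = None
            found = False
            for _try in range(max_tries):
                ridx = rng.choice(len(regions), p=region_p)
                chrom, lo, hi = regions[ridx]
                if hi - lo < width:
                    continue
                start = int(rng.integers(lo, hi - width + 1))
                key = (chrom, start, width)
                if key in used:
                    continue
                cand_seq = genome[chrom][start : start + width]
                cg = int(gc_fraction(cand_seq) / gc_bin)
                cc = int(cpg_observed_expected(cand_seq) / cpg_bin)
                dist = abs(cg - gbin) + abs(cc - cbin)
                cand = GenomicInterval(chrom, start, start + width)
                if dist == 0:
                    used.add(key)
                    out.append(cand)
                    found = True
                    break
                if best is None or dist < best[0]:
                    best = (dist, cand)
            if not found:
                if best is None:
                    raise ValueError("no background candidate wide enough for peak")
                logger.warning(
                    "GC/CpG bin (%d, %d) exhausted after %d draws; nearest-bin fallback",
                    gbin, cbin, max_tries,
                )
                used.add((best[1].chrom, best[1].start, len(best[1])))
                out.append(best[1])
    return out


def motif_enrichment(
    target_peaks: Sequence[GenomicInterval],
    background_peaks: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float,
) -> dict:
    """Fraction of peaks featuring >= 1 motif hit, target vs background.

    Returns target/background percentages, the sample odds ratio and the
    two-sided Fisher exact p-value of the 2x2 with/without table.
    """
    if not target_peaks:
        raise ValueError("target peak set is empty")

    def _n_with(peaks: Sequence[GenomicInterval]) -> int:
        n = 0
        for p in peaks:
            seqs = {p.chrom: genome[p.chrom][p.start : p.end]}
            if scan(seqs, pwm, threshold):
                n += 1
        return n

    a = _n_with(target_peaks)
    b = len(target_peaks) - a
    c = _n_with(background_peaks)
    d = len(background_peaks) - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {
        "target_n": len(target_peaks),
        "background_n": len(background_peaks),
        "target_pct": 100.0 * a / len(target_peaks),
        "background_pct": 100.0 * c / len(background_peaks) if background_peaks else np.nan,
        "odds_ratio": odds,
        "fisher_p": float(p),
        "table": table,
    }


def _strand_coords(hit: MotifHit) -> tuple[int, int]:
    """Along-strand (start, end) via mirroring for minus-strand hits."""
    iv = hit.interval
    if iv.strand == "+":
        return iv.start, iv.end
    return -iv.end, -iv.start


def _normalize_gap_range(gap_range) -> tuple[tuple[int, int], tuple[int, int]]:
    gr = tuple(gap_range)
    if len(gr) == 2 and np.isscalar(gr[0]):
        return (gr, gr)  # type: ignore[return-value]
    return (tuple(gr[0]), tuple(gr[1]))  # type: ignore[return-value]


def find_triple_motif(
    sequences: Mapping[str, str],
    pwm_esr: PWM,
    pwm_bzip: PWM,
    pwm_pax: PWM,
    alphas: tuple[float, float, float] = (1e-4, 1e-4, 1e-4),
    max_span: int = 50,
    gap_range=(0, 15),
    granularity: float = 1e-3,
    component_hits: tuple[list[MotifHit], list[MotifHit], list[MotifHit]] | None = None,
) -> list[TripleMotifHit]:
    """Find every same-strand ordered ESR -> bZIP -> Pax arrangement.

    Components are calibrated at their per-motif alphas, then joined under
    the geometry constraints: 5'-to-3' order ESR, bZIP, Pax on a common
    strand; inter-hit gaps within ``gap_range`` (one pair applied to both
    junctions, or a pair of pairs); total span <= ``max_span``. Overlapping
    arrangements are each reported; output is sorted by (chrom, start,
    strand).
    """
    pwms = (pwm_esr, pwm_bzip, pwm_pax)
    if max_span < sum(len(p) for p in pwms):
        raise ValueError("max_span smaller than the summed motif lengths")
    (g1min, g1max), (g2min, g2max) = _normalize_gap_range(gap_range)

    if component_hits is None:
        component_hits = tuple(  # type: ignore[assignment]
            scan(sequences, pwm, *score_threshold(pwm, a, granularity))
            for pwm, a in zip(pwms, alphas)
        )
    esr_hits, bzip_hits, pax_hits = component_hits

    # index bzip/pax hits by (chrom, strand), sorted by along-strand start
    def _index(hits: list[MotifHit]):
        idx: dict[tuple[str, str], tuple[np.ndarray, list[MotifHit]]] = {}
        groups: dict[tuple[str, str], list[MotifHit]] = {}
        for h in hits:
            groups.setdefault((h.interval.chrom, h.interval.strand), []).append(h)
        for key, hs in groups.items():
            hs.sort(key=lambda h: _strand_coords(h)[0])
            idx[key] = (np.array([_strand_coords(h)[0] for h in hs]), hs)
        return idx

    bzip_idx = _index(bzip_hits)
    pax_idx = _index(pax_hits)

    out: list[TripleMotifHit] = []
    for eh in esr_hits:
        key = (eh.interval.chrom, eh.interval.strand)
        if key not in bzip_idx or key not in pax_idx:
            continue
        e_start, e_end = _strand_coords(eh)
        b_starts, bs = bzip_idx[key]
        lo = np.searchsorted(b_starts, e_end + g1min, side="left")
        hi = np.searchsorted(b_starts, e_end + g1max, side="right")
        for bh in bs[lo:hi]:
            b_start, b_end = _strand_coords(bh)
            p_starts, ps = pax_idx[key]
            plo = np.searchsorted(p_starts, b_end + g2min, side="left")
            phi = np.searchsorted(p_starts, b_end + g2max, side="right")
            for ph in ps[plo:phi]:
                p_start, p_end = _strand_coords(ph)
                if p_end - e_start > max_span:
                    continue
                g_start = min(eh.interval.start, ph.interval.start)
                g_end = max(eh.interval.end, ph.interval.end)
                out.append(
                    TripleMotifHit(
                        esr_hit=eh,
                        bzip_hit=bh,
                        pax_hit=ph,
                        interval=GenomicInterval(
                            eh.interval.chrom, g_start, g_end, eh.interval.strand
                        ),
                        strand=eh.interval.strand,
                    )
                )
    out.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.strand))
    return out


def triple_motif_repeat_overlap(
    hits: Sequence[TripleMotifHit], repeats: Sequence[RepeatInstance]
) -> dict:
    """Assign each triple-motif hit to the repeat containing its midpoint.

    Returns per-family counts (hits outside any repeat under ``"none"``)
    and the fraction of all hits lying in the strand-aware 3' half of an
    Alu copy — the geometry the genome-wide scan attributes to the Alu
    right arm.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[RepeatInstance]]] = {}
    groups: dict[str, list[RepeatInstance]] = {}
    for rep in repeats:
        groups.setdefault(rep.interval.chrom, []).append(rep)
    for chrom, reps in groups.items():
        reps.sort(key=lambda r: r.interval.start)
        by_chrom[chrom] = (
            np.array([r.interval.start for r in reps]),
            np.array([r.interval.end for r in reps]),
            reps,
        )

    family_counts: dict[str, int] = {}
    n_alu_3prime = 0
    assignments = []
    for hit in hits:
        mid = hit.interval.midpoint
        rep = None
        entry = by_chrom.get(hit.interval.chrom)
        if entry is not None:
            starts, ends, reps = entry
            i = int(np.searchsorted(starts, mid, side="right")) - 1
            if i >= 0 and mid < ends[i]:
                rep = reps[i]
        if rep is None:
            family_counts["none"] = family_counts.get("none", 0) + 1
            assignments.append(("none", "", False))
            continue
        family_counts[rep.family] = family_counts.get(rep.family, 0) + 1
        riv = rep.interval
        rel = mid - riv.start
        half = len(riv) / 2.0
        three_prime = rel >= half if riv.strand != "-" else rel < half
        if rep.family == "Alu" and three_prime:
            n_alu_3prime += 1
        assignments.append((rep.family, rep.subfamily, bool(three_prime)))
    n = len(hits)
    return {
        "family_counts": family_counts,
        "n_hits": n,
        "alu_3prime_fraction": n_alu_3prime / n if n else float("nan"),
        "assignments": assignments,
    }
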