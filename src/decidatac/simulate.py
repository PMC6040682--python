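"""Synthetic two-condition ATAC-seq data with planted ground truth.

Generates everything downstream stages consume: a genome with planted
repeat families (Alu copies carrying an ESR -> bZIP -> Pax triple motif
in their 3' half), gene models, accessibility peaks with planted opening
and closing effects, negative-binomial fragment counts with protected
(footprinted) motif cores and strand-asymmetric flanking cut excess, a
clade-structured set of primate-like genomes with lineage-specific Alu
insertions, and an expression table coupled to peak dynamics. Truth
tables accompany every output so each stage can be scored.

The fragment model is deliberately simple: unstranded fragments of
60-120 bp whose ends define Tn5 cut sites; no nucleosome positioning and
no sequence-dependent Tn5 bias beyond the planted motif-core protection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .core import PWM, Gene, GenomicInterval, Peak, RepeatInstance

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

# stable synthetic stand-in consensi for the three motif components and the
# generic footprint motif planted in differential peaks
ESR_CONSENSUS = "AGGTCACG"
BZIP_CONSENSUS = "TGACGTCA"
PAX_CONSENSUS = "GGCGTGACC"
FOOTPRINT_CONSENSUS = "TGACGTAA"  # non-palindromic, so hit strand is unambiguous


def _motif_pwm(name: str, consensus: str, dominant: float = 0.85) -> PWM:
    probs = np.full((len(consensus), 4), (1 - dominant) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = dominant
    return PWM(name, probs, pseudocount=0.0)


def default_pwms() -> dict[str, PWM]:
    """Synthetic stand-in PWMs for the ESR, bZIP and Pax components and the
    footprint motif (real analyses would take database PWMs as input)."""
    return {
        "ESR": _motif_pwm("ESR", ESR_CONSENSUS),
        "bZIP": _motif_pwm("bZIP", BZIP_CONSENSUS),
        "Pax": _motif_pwm("Pax", PAX_CONSENSUS),
        "footprint": _motif_pwm("footprint", FOOTPRINT_CONSENSUS),
    }


def _default_alu_consensus() -> str:
    """~310-bp Alu-like consensus carrying the ordered triple motif in its
    3' half and a short A-rich tail. Built once from a fixed generator so
    it is a stable constant."""
    rng = np.random.default_rng(20240917)
    seq = list("".join(rng.choice(BASES, size=310)))
    pos = 205
    for motif, gap in ((ESR_CONSENSUS, 4), (BZIP_CONSENSUS, 5), (PAX_CONSENSUS, 0)):
        seq[pos : pos + len(motif)] = motif
        pos += len(motif) + gap
    seq[-12:] = "A" * 12
    return "".join(seq)


ALU_CONSENSUS = _default_alu_consensus()
# consensus spans that must stay intact when copies are mutated
_ALU_PROTECTED = [(205, 205 + 8), (217, 217 + 8), (230, 230 + 9)]

FAMILY_LENGTHS: dict[str, tuple[int, int]] = {
    "L1": (900, 3000),
    "CR1": (500, 1500),
    "ERVL": (400, 1000),
    "ERVK": (400, 1000),
    "hAT-Charlie": (200, 500),
    "Satellite": (200, 800),
    "Low_complexity": (50, 150),
    "Simple_repeat": (30, 100),
}

DEFAULT_TE_WEIGHTS: dict[str, float] = {
    "Alu": 0.08,
    "L1": 0.12,
    "ERVL": 0.02,
    "ERVK": 0.01,
    "hAT-Charlie": 0.02,
    "CR1": 0.01,
    "Satellite": 0.01,
    "Low_complexity": 0.01,
    "Simple_repeat": 0.01,
}

# caterpillar primate-like tree: (species, divergence from the reference);
# the per-base substitution probability is substitution_rate * divergence
DEFAULT_SPECIES_TREE: tuple[tuple[str, float], ...] = (
    ("chimp", 0.2),
    ("gorilla", 0.35),
    ("macaque", 0.7),
    ("saimiri", 1.0),
    ("callithrix", 1.1),
    ("galago", 2.0),
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study conditions as
    defaults: 5,000 peaks of which 200 open and 50 close at
    effect_log2fc = 2, negative-binomial dispersion 0.1, 3 + 3
    replicates."""

    seed: int = 0
    genome_length: int = 20_000_000
    n_genes: int = 300
    n_peaks: int = 5_000
    n_opening: int = 200
    n_closing: int = 50
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates_per_condition: int = 3
    baseline_mean: float = 100.0
    baseline_log_sd: float = 0.4
    te_family_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_WEIGHTS)
    )
    alu_consensus: str = ALU_CONSENSUS
    alu_divergence: float = 0.08
    alu_peak_fraction: float = 0.3
    footprint_protection: float = 0.8
    footprint_excess: float = 1.0
    footprint_flank: int = 20
    motif_peak_fraction: float = 0.2
    occupied_fraction: float = 0.5
    fragment_length_range: tuple[int, int] = (60, 120)
    background_fragment_fraction: float = 0.05
    species_tree: tuple[tuple[str, float], ...] = DEFAULT_SPECIES_TREE
    substitution_rate: float = 0.05
    expression_effect: float = 1.0
    expression_sd: float = 0.5
    gc_range: tuple[float, float] = (0.35, 0.55)
    gc_block: int = 10_000

    def __post_init__(self) -> None:
        if sum(self.te_family_weights.values()) > 1.0:
            raise ValueError("te_family_weights must sum to <= 1")
        for name in ("n_genes", "n_peaks", "n_opening", "n_closing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.footprint_protection < 1.0:
            raise ValueError("footprint_protection must lie in [0, 1)")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.n_opening + self.n_closing > self.n_peaks:
            raise ValueError("opening + closing cannot exceed n_peaks")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["te_family_weights"] = dict(d["te_family_weights"])
        d["species_tree"] = [list(x) for x in d["species_tree"]]
        d["fragment_length_range"] = list(d["fragment_length_range"])
        d["gc_range"] = list(d["gc_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("fragment_length_range", "gc_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "species_tree" in d:
            d["species_tree"] = tuple((s, float(t)) for s, t in d["species_tree"])
        return cls(**d)


@dataclass
class GenomeBundle:
    """In-memory result of make_genome, plus the planted truth."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[Gene]
    exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    repeats: list[RepeatInstance]
    peaks: list[Peak]
    peak_truth: pd.DataFrame  # id, chrom, start, end, state, baseline_mean
    motif_truth: pd.DataFrame  # chrom, start, end, strand, peak_id, occupied

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_fasta(self.genome, outdir / "genome.fa")
        dio.write_tss_bed(self.genes, outdir / "tss.bed")
        dio.write_repeatmasker_out(self.repeats, outdir / "repeats.out")
        dio.write_bed(self.peaks, outdir / "peaks.bed")
        self.peak_truth.to_csv(outdir / "peak_truth.tsv", sep="\t", index=False)
        self.motif_truth.to_csv(outdir / "motif_truth.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for lo, hi in protected:
        hit[lo:hi] = False
    idx = np.nonzero(hit)[0]
    if len(idx):
        shifts = rng.integers(1, 4, size=len(idx))
        lut = {b: i for i, b in enumerate("ACGT")}
        cur = np.array([lut[b] for b in arr[idx]])
        arr[idx] = np.array(list("ACGT"))[(cur + shifts) % 4]
    return "".join(arr)


class _Placer:
    """Greedy non-overlapping interval placement over one chromosome."""

    def __init__(self, length: int, min_gap: int = 20):
        self.length = length
        self.min_gap = min_gap
        self.starts: list[int] = []
        self.ends: list[int] = []

    def try_place(self, start: int, width: int) -> bool:
        import bisect

        end = start + width
        if start < 0 or end > self.length:
            return False
        i = bisect.bisect_left(self.starts, end + self.min_gap)
        if i > 0 and self.ends[i - 1] + self.min_gap > start:
            return False
        if i < len(self.starts) and self.starts[i] < end + self.min_gap:
            return False
        self.starts.insert(i, start)
        self.ends.insert(i, end)
        return True

    def place_random(
        self, rng: np.random.Generator, width: int, tries: int = 200, reject=None
    ) -> int | None:
        for _ in range(tries):
            start = int(rng.integers(0, self.length - width))
            if reject is not None and reject(start, start + width):
                continue
            if self.try_place(start, width):
                return start
        return None


def make_genome(config: SimulationConfig) -> GenomeBundle:
    """Build the reference genome with planted repeats, genes and peaks.

    Repeats never overlap one another; every planted Alu copy carries the
    ESR -> bZIP -> Pax arrangement of the configured consensus in its 3'
    half (its site coordinates are protected from copy divergence); a
    ground-truth table of all planted features accompanies the sequence.
    """
    if config.genome_length < 100_000:
        raise ValueError("genome_length must be >= 100 kb")
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    L = config.genome_length

    # background with per-block GC structure
    blocks = []
    for lo in range(0, L, config.gc_block):
        size = min(config.gc_block, L - lo)
        gc = rng.uniform(*config.gc_range)
        blocks.append(_random_sequence(rng, size, gc))
    seq = np.concatenate(blocks)

    placer = _Placer(L)
    repeats: list[RepeatInstance] = []
    family_consensus: dict[str, str] = {}
    total_repeat_bp = sum(w for w in config.te_family_weights.values()) * L
    if total_repeat_bp > 0.8 * L:
        raise ValueError("requested repeat bp exceeds what the genome can hold")
    for family, weight in config.te_family_weights.items():
        target_bp = int(weight * L)
        placed_bp = 0
        if family == "Alu":
            consensus = config.alu_consensus
        else:
            lo_len, hi_len = FAMILY_LENGTHS.get(family, (200, 600))
            consensus = "".join(rng.choice(BASES, size=hi_len))
            family_consensus[family] = consensus
        while placed_bp < target_bp:
            if family == "Alu":
                copy = _mutate(rng, consensus, config.alu_divergence, _ALU_PROTECTED)
            else:
                lo_len, hi_len = FAMILY_LENGTHS.get(family, (200, 600))
                width = int(rng.integers(lo_len, hi_len + 1))
                copy = _mutate(rng, consensus[:width], 0.1)
            strand = "+" if rng.random() < 0.5 else "-"
            start = placer.place_random(rng, len(copy))
            if start is None:
                logger.warning("placement saturated for family %s", family)
                break
            inserted = copy if strand == "+" else _revcomp_str(copy)
            seq[start : start + len(copy)] = list(inserted)
            repeats.append(
                RepeatInstance(
                    interval=GenomicInterval(chrom, start, start + len(copy), strand),
                    family=family,
                    subfamily=f"{family}Syn",
                    consensus_length=len(consensus) if family == "Alu" else len(copy),
                )
            )
            placed_bp += len(copy)
    repeats.sort(key=lambda r: r.interval.start)

    # genes: TSS + body with exons/introns
    genes: list[Gene] = []
    exons: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    gene_placer = _Placer(L, min_gap=2_000)
    for gi in range(config.n_genes):
        body_len = int(rng.integers(5_000, 15_000))
        start = gene_placer.place_random(rng, body_len)
        if start is None:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        tss_pos = start if strand == "+" else start + body_len - 1
        genes.append(
            Gene(id=f"gene_{gi:04d}", tss=GenomicInterval(chrom, tss_pos, tss_pos + 1, strand))
        )
        n_exons = int(rng.integers(2, 6))
        bounds = np.sort(rng.choice(np.arange(200, body_len - 200), size=2 * n_exons, replace=False))
        prev_end = start
        for k in range(n_exons):
            ex_s, ex_e = start + int(bounds[2 * k]), start + int(bounds[2 * k + 1])
            if ex_e <= ex_s:
                continue
            exons.append(GenomicInterval(chrom, ex_s, ex_e, strand))
            if ex_s > prev_end:
                introns.append(GenomicInterval(chrom, prev_end, ex_s, strand))
            prev_end = ex_e
        if start + body_len > prev_end:
            introns.append(GenomicInterval(chrom, prev_end, start + body_len, strand))

    # peaks: opening/closing near gene TSSs, a fraction over Alu 3' halves,
    # the rest anywhere; all non-overlapping
    peak_placer = _Placer(L, min_gap=50)
    peaks: list[Peak] = []
    truth_rows = []
    motif_rows = []
    states = (
        ["opening"] * config.n_opening
        + ["closing"] * config.n_closing
        + ["unchanged"] * (config.n_peaks - config.n_opening - config.n_closing)
    )
    # each opening/closing peak is coupled to a distinct gene, so the
    # planted expression truth is unambiguous
    gene_pool = list(rng.permutation(len(genes))) if genes else []

    # non-differential peaks stay out of the 10-kb TSS neighborhoods: on a
    # miniature genome, uniform placement would put peaks near genes at a
    # density ~100x that of a full-size genome and wash out the planted
    # peak-to-gene coupling with spurious links
    import bisect as _bisect

    excl: list[tuple[int, int]] = []
    for g in genes:
        excl.append((max(0, g.tss.start - 11_000), g.tss.start + 11_000))
    excl.sort()
    merged_excl: list[list[int]] = []
    for s, e in excl:
        if merged_excl and s <= merged_excl[-1][1]:
            merged_excl[-1][1] = max(merged_excl[-1][1], e)
        else:
            merged_excl.append([s, e])
    excl_starts = [s for s, _ in merged_excl]
    excl_ends = [e for _, e in merged_excl]

    def _near_tss(s: int, e: int) -> bool:
        i = _bisect.bisect_right(excl_starts, e)
        return i > 0 and excl_ends[i - 1] > s

    n_alu_peaks = int(config.alu_peak_fraction * sum(1 for r in repeats if r.family == "Alu"))
    alu_for_peaks = [r for r in repeats if r.family == "Alu"][:n_alu_peaks]
    alu_iter = iter(alu_for_peaks)

    footprint_w = len(FOOTPRINT_CONSENSUS)
    pid = 0
    for state in states:
        width = int(rng.integers(300, 601))
        start = None
        on_alu = False
        if state in ("opening", "closing") and len(genes):
            # strand-aware upstream placement within 10 kb of an unused gene
            for _ in range(20):
                if not gene_pool:
                    break
                g = genes[int(gene_pool.pop())]
                d = int(rng.integers(500, 8_000))
                if g.tss.strand == "-":
                    cand = g.tss.start + d
                else:
                    cand = g.tss.start - d - width
                if cand is not None and peak_placer.try_place(cand, width):
                    start = cand
                    break
        elif state == "unchanged":
            rep = next(alu_iter, None)
            if rep is not None:
                iv = rep.interval
                # cover the strand-aware 3' half plus a little flank, but
                # keep clear of the 5' end
                width = len(iv) // 2 + 80
                if iv.strand == "-":
                    cand = iv.start - 40
                else:
                    cand = iv.end + 40 - width
                if not _near_tss(cand, cand + width) and peak_placer.try_place(cand, width):
                    start = cand
                    on_alu = True
        if start is None:
            reject = _near_tss if state == "unchanged" else None
            start = peak_placer.place_random(rng, width, reject=reject)
        if start is None:
            logger.warning("peak placement saturated at %d peaks", pid)
            break
        peak_id = f"peak_{pid:05d}"
        pid += 1
        baseline = float(
            config.baseline_mean * np.exp(rng.normal(0.0, config.baseline_log_sd))
        )
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + width),
                id=peak_id,
                metadata={"truth_state": state, "baseline_mean": baseline},
            )
        )
        truth_rows.append(
            {
                "id": peak_id, "chrom": chrom, "start": start, "end": start + width,
                "state": state, "baseline_mean": baseline,
            }
        )
        # plant a footprint motif in a fraction of peaks (always in opening
        # peaks so motif enrichment has signal); never inside an Alu-covering
        # peak, whose 3' half already carries the triple motif
        plant = not on_alu and (
            state == "opening" or rng.random() < config.motif_peak_fraction
        )
        if plant:
            m_start = start + width // 2 - footprint_w // 2
            seq[m_start : m_start + footprint_w] = list(FOOTPRINT_CONSENSUS)
            occupied = state == "opening" or rng.random() < config.occupied_fraction
            motif_rows.append(
                {
                    "chrom": chrom, "start": m_start, "end": m_start + footprint_w,
                    "strand": "+", "peak_id": peak_id, "occupied": occupied,
                }
            )

    genome = {chrom: "".join(seq)}
    return GenomeBundle(
        config=config,
        genome=genome,
        genes=genes,
        exons=exons,
        introns=introns,
        repeats=repeats,
        peaks=peaks,
        peak_truth=pd.DataFrame(truth_rows),
        motif_truth=pd.DataFrame(
            motif_rows, columns=["chrom", "start", "end", "strand", "peak_id", "occupied"]
        ),
    )


def _revcomp_str(s: str) -> str:
    from .core import revcomp

    return revcomp(s)


def sample_labels(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Sample names and their condition labels (ctrl first, then dec)."""
    n = config.n_replicates_per_condition
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"dec_{i + 1}" for i in range(n)]
    conditions = ["ctrl"] * n + ["dec"] * n
    return samples, conditions


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def make_counts(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Count-level shortcut: a peak x sample NB counts matrix and the truth
    states, without genome or fragments (used for calibration studies)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    states = pd.Series(
        ["opening"] * config.n_opening
        + ["closing"] * config.n_closing
        + ["unchanged"] * (config.n_peaks - config.n_opening - config.n_closing),
        index=[f"peak_{i:05d}" for i in range(config.n_peaks)],
    )
    base = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=config.n_peaks)
    )
    effect = np.where(
        states == "opening", config.effect_log2fc,
        np.where(states == "closing", -config.effect_log2fc, 0.0),
    )
    samples, conditions = sample_labels(config)
    cols = {}
    for s, cond in zip(samples, conditions):
        mean = base * np.power(2.0, effect) if cond == "dec" else base
        cols[s] = _nb_draw(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=states.index)
    return counts, states


def _cut_weights(
    width: int,
    motif_rel: tuple[int, int] | None,
    occupied: bool,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position acceptance weights for + and - strand cuts in a peak."""
    wp = np.ones(width)
    wm = np.ones(width)
    if motif_rel is not None:
        lo, hi = motif_rel
        fl = config.footprint_flank
        if occupied and config.footprint_protection > 0:
            wp[max(lo, 0) : hi] *= 1.0 - config.footprint_protection
            wm[max(lo, 0) : hi] *= 1.0 - config.footprint_protection
            boost = 1.0 + config.footprint_excess
            wp[max(lo - fl, 0) : max(lo, 0)] *= boost  # + strand excess 5' of motif
            wm[hi : min(hi + fl, width)] *= boost  # - strand excess 3' of motif
    return wp / wp.max(), wm / wm.max()


def make_fragments(
    config: SimulationConfig, bundle: GenomeBundle, seed: int | None = None
) -> pd.DataFrame:
    """Simulate per-sample fragment intervals over the planted peaks.

    Per-peak fragment counts are negative binomial with the mean shifted
    by +/- effect_log2fc in the decidualized condition for opening and
    closing peaks. Within occupied motif instances the cut probability is
    multiplied by (1 - footprint_protection), with a planted plus-strand
    cut excess immediately 5' of the motif and a minus-strand excess 3'
    of it. A small fraction of background fragments falls genome-wide.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    samples, conditions = sample_labels(config)
    motif_by_peak: dict[str, tuple[int, int, bool]] = {}
    for _, row in bundle.motif_truth.iterrows():
        motif_by_peak[row["peak_id"]] = (int(row["start"]), int(row["end"]), bool(row["occupied"]))
    lo_len, hi_len = config.fragment_length_range
    chrom = bundle.peaks[0].interval.chrom if bundle.peaks else "chr1"
    L = len(bundle.genome[chrom])
    frames = []
    for sample, cond in zip(samples, conditions):
        starts_all: list[np.ndarray] = []
        ends_all: list[np.ndarray] = []
        for peak in bundle.peaks:
            state = peak.metadata["truth_state"]
            mean = peak.metadata["baseline_mean"]
            if cond == "dec" and state == "opening":
                mean *= 2.0**config.effect_log2fc
            elif cond == "dec" and state == "closing":
                mean *= 2.0**-config.effect_log2fc
            n = int(_nb_draw(rng, np.array([mean]), config.nb_dispersion)[0])
            if n == 0:
                continue
            iv = peak.interval
            width = len(iv)
            motif = motif_by_peak.get(peak.id)
            if motif is not None:
                m_lo, m_hi, occ = motif
                weights = _cut_weights(width, (m_lo - iv.start, m_hi - iv.start), occ, config)
            else:
                weights = None
            starts = np.empty(n, dtype=np.int64)
            ends = np.empty(n, dtype=np.int64)
            filled = 0
            for _attempt in range(8):
                need = n - filled
                if need <= 0:
                    break
                draw = need * 2 + 8
                ln = rng.integers(lo_len, hi_len + 1, size=draw)
                st = iv.start + rng.integers(0, np.maximum(width - ln, 1), size=draw)
                en = st + ln
                if weights is not None:
                    wp, wm = weights
                    cp = np.clip(st + 4 - iv.start, 0, width - 1)
                    cm = np.clip(en - 5 - iv.start, 0, width - 1)
                    acc = rng.random(draw) < wp[cp] * wm[cm]
                else:
                    acc = np.ones(draw, dtype=bool)
                st, en = st[acc], en[acc]
                take = min(len(st), need)
                starts[filled : filled + take] = st[:take]
                ends[filled : filled + take] = en[:take]
                filled += take
            starts_all.append(starts[:filled])
            ends_all.append(ends[:filled])
        n_peak_frags = int(sum(len(a) for a in starts_all))
        n_bg = int(
            n_peak_frags * config.background_fragment_fraction / max(1e-9, 1 - config.background_fragment_fraction)
        )
        if n_bg:
            ln = rng.integers(lo_len, hi_len + 1, size=n_bg)
            st = rng.integers(0, L - hi_len, size=n_bg)
            starts_all.append(st)
            ends_all.append(st + ln)
        starts_cat = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=np.int64)
        ends_cat = np.concatenate(ends_all) if ends_all else np.empty(0, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts_cat, "end": ends_cat, "sample": sample}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SpeciesBundle:
    """Simulated target genomes with per-locus, per-species presence truth."""

    genomes: dict[str, dict[str, str]]
    truth: pd.DataFrame  # locus, species, present
    divergence: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, genome in self.genomes.items():
            dio.write_fasta(genome, outdir / f"{species}.fa")
        self.truth.to_csv(outdir / "ortholog_truth.tsv", sep="\t", index=False)


def make_species_genomes(
    config: SimulationConfig, bundle: GenomeBundle, seed: int | None = None
) -> SpeciesBundle:
    """Derive clade-structured species genomes with lineage-specific Alus.

    Each Alu copy is assigned an insertion age uniform over the tree depth
    (plus a margin, so some insertions predate every split); a species
    carries the copy iff the insertion is older than its divergence from
    the reference. Species sequences are the reference with absent Alu
    spans excised and substitutions applied at substitution_rate times
    the species divergence.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    chrom = next(iter(bundle.genome))
    ref = bundle.genome[chrom]
    alus = [r for r in bundle.repeats if r.family == "Alu"]
    max_div = max(d for _, d in config.species_tree)
    ages = rng.uniform(0.0, 1.2 * max_div, size=len(alus))
    truth_rows = []
    genomes: dict[str, dict[str, str]] = {}
    divergence = dict(config.species_tree)
    for species, div in config.species_tree:
        keep = ages > div
        drop_spans = [
            (a.interval.start, a.interval.end)
            for a, present in zip(alus, keep)
            if not present
        ]
        drop_spans.sort()
        pieces = []
        cursor = 0
        for s, e in drop_spans:
            pieces.append(ref[cursor:s])
            cursor = e
        pieces.append(ref[cursor:])
        seq = "".join(pieces)
        rate = config.substitution_rate * div
        seq = _mutate(rng, seq, rate)
        genomes[species] = {chrom: seq}
        for a, present in zip(alus, keep):
            locus = f"{a.interval.chrom}:{a.interval.start}-{a.interval.end}"
            truth_rows.append({"locus": locus, "species": species, "present": bool(present)})
    return SpeciesBundle(
        genomes=genomes,
        truth=pd.DataFrame(truth_rows),
        divergence=divergence,
    )


def make_expression(
    config: SimulationConfig,
    bundle: GenomeBundle,
    links: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expression table coupled to the planted peak dynamics.

    Genes linked (within 10 kb) to a planted opening peak draw their
    log2 fold change from N(+expression_effect, sd), closing from the
    negative, everything else from N(0, sd).
    """
    from . import linkage

    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    if links is None:
        links = linkage.link_peaks_to_genes(bundle.peaks, bundle.genes)
    state_by_peak = dict(zip(bundle.peak_truth["id"], bundle.peak_truth["state"]))
    gene_state: dict[str, str] = {}
    for _, row in links.iterrows():
        st = state_by_peak.get(row["peak_id"], "unchanged")
        cur = gene_state.get(row["gene_id"], "unchanged")
        if st == "opening" or (st == "closing" and cur == "unchanged"):
            gene_state[row["gene_id"]] = st
    rows = []
    for g in bundle.genes:
        st = gene_state.get(g.id, "unchanged")
        mu = {"opening": config.expression_effect, "closing": -config.expression_effect}.get(st, 0.0)
        rows.append(
            {
                "gene_id": g.id,
                "log2fc": float(rng.normal(mu, config.expression_sd)),
                "truth_state": st,
            }
        )
    return pd.DataFrame(rows)
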