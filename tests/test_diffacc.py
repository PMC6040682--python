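"""Fragment counting, the NB Wald test, signed ranking and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from decidatac import diffacc
from decidatac import simulate as sim
from decidatac.core import Gene, GenomicInterval, Peak


def _peak(pid, start, end, chrom="chr1"):
    return Peak(interval=GenomicInterval(chrom, start, end), id=pid)


def _frags(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])


class TestCountFragments:
    def test_one_bp_overlap_counts(self):
        frags = _frags([("chr1", 100, 150, "s1")])
        counts = diffacc.count_fragments(frags, [_peak("p1", 140, 200)])
        assert counts.loc["p1", "s1"] == 1

    def test_abutting_fragment_does_not_count(self):
        frags = _frags([("chr1", 100, 140, "s1")])
        counts = diffacc.count_fragments(frags, [_peak("p1", 140, 200)])
        assert counts.loc["p1", "s1"] == 0

    def test_three_in_one_out(self):
        frags = _frags(
            [("chr1", 150, 170, "s1"), ("chr1", 160, 180, "s1"),
             ("chr1", 190, 199, "s1"), ("chr1", 500, 550, "s1")]
        )
        counts = diffacc.count_fragments(frags, [_peak("p1", 140, 200)])
        assert counts.loc["p1", "s1"] == 3
        assert counts.attrs["totals"]["s1"] == 4

    def test_spanning_fragment_counts_in_both_peaks(self):
        frags = _frags([("chr1", 195, 305, "s1")])
        counts = diffacc.count_fragments(
            frags, [_peak("a", 100, 200), _peak("b", 300, 400)]
        )
        assert counts.loc["a", "s1"] == 1
        assert counts.loc["b", "s1"] == 1

    def test_zero_fragment_sample_errors(self):
        frags = _frags([("chr1", 0, 50, "s1")])
        with pytest.raises(ValueError, match="s2"):
            diffacc.count_fragments(frags, [_peak("p1", 0, 100)], samples=["s1", "s2"])

    def test_overlapping_peaks_rejected(self):
        frags = _frags([("chr1", 0, 50, "s1")])
        with pytest.raises(ValueError, match="overlap"):
            diffacc.count_fragments(frags, [_peak("a", 0, 100), _peak("b", 50, 150)])

    def test_conservation_with_contained_fragments(self):
        """With disjoint peaks and fully contained fragments, the matrix total
        equals the fragment count."""
        rng = np.random.default_rng(0)
        peaks = [_peak(f"p{i}", i * 1000, i * 1000 + 400) for i in range(10)]
        rows = []
        for _ in range(200):
            i = int(rng.integers(0, 10))
            s = int(rng.integers(i * 1000, i * 1000 + 300))
            rows.append(("chr1", s, s + 80, "s1"))
        counts = diffacc.count_fragments(_frags(rows), peaks)
        assert counts["s1"].sum() == 200


class TestNBDifferential:
    def test_identical_counts_null(self):
        counts = pd.DataFrame(
            {s: [10, 55, 200] for s in ["a1", "a2", "b1", "b2"]},
            index=["p1", "p2", "p3"],
        )
        res = diffacc.nb_differential(counts, ["c", "c", "d", "d"])
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_size_factor_doubled_sample(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=200)
        counts = np.stack([base, base, base, base * 2], axis=1)
        sf = diffacc.size_factors(counts)
        assert sf[3] / sf[0] == pytest.approx(2.0, rel=1e-6)

    def test_all_zero_peak_convention(self):
        counts = pd.DataFrame(
            {"a1": [0, 100], "a2": [0, 110], "b1": [0, 95], "b2": [0, 105]},
            index=["z", "p"],
        )
        res = diffacc.nb_differential(counts, ["c", "c", "d", "d"])
        assert res.loc["z", "log2fc"] == 0.0
        assert res.loc["z", "pvalue"] == 1.0

    def test_single_replicate_condition_errors(self):
        counts = pd.DataFrame({"a1": [1], "a2": [2], "b1": [3]}, index=["p"])
        with pytest.raises(ValueError):
            diffacc.nb_differential(counts, ["c", "c", "d"])

    def test_sensitivity_on_planted_simulation(self):
        """Planted effect_log2fc = 2 with dispersion 0.1, 3+3 replicates and
        1000 peaks at Bonferroni 0.05. The delta-method power of the Wald
        test at these conditions is ~0.89 (SE of the log2 fold change
        ~ sqrt(2(a + 1/mu)/n)/ln 2 ~ 0.38 against a 4.06-sigma threshold),
        so sensitivity is asserted against that analytic expectation."""
        cfg = sim.SimulationConfig(
            seed=42, n_peaks=1000, n_opening=50, n_closing=25,
            effect_log2fc=2.0, nb_dispersion=0.1,
        )
        counts, states = sim.make_counts(cfg)
        res = diffacc.nb_differential(counts, ["ctrl"] * 3 + ["dec"] * 3)
        called = diffacc.classify_dynamic(diffacc.rank_peaks(res))
        truth_dyn = states[states != "unchanged"]
        hit = (called.loc[truth_dyn.index, "state"] == truth_dyn).mean()
        assert hit >= 0.85
        # and essentially no false calls among unchanged peaks
        unchanged = states[states == "unchanged"]
        false = (called.loc[unchanged.index, "state"] != "unchanged").sum()
        assert false <= 2

    def test_against_pydeseq2_oracle(self):
        """The simplified Wald test tracks DESeq2 on a small matrix: near-
        identical fold changes and concordant significant sets."""
        import logging

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = sim.SimulationConfig(
            seed=9, n_peaks=300, n_opening=30, n_closing=15,
            effect_log2fc=2.0, nb_dispersion=0.05,
        )
        counts, _ = sim.make_counts(cfg)
        mine = diffacc.nb_differential(counts, ["ctrl"] * 3 + ["dec"] * 3)
        logging.getLogger().setLevel(logging.ERROR)
        dds = DeseqDataSet(
            counts=counts.T.reset_index(drop=True),
            metadata=pd.DataFrame({"condition": ["ctrl"] * 3 + ["dec"] * 3}),
            design="~condition", quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "dec", "ctrl"], quiet=True)
        ds.summary()
        theirs = ds.results_df
        rho = sstats.spearmanr(mine["log2fc"], theirs["log2FoldChange"]).statistic
        assert rho > 0.95
        m = len(counts)
        sig_mine = set(mine.index[mine["padj"] < 0.05])
        sig_theirs = set(counts.index[np.minimum(theirs["pvalue"] * m, 1) < 0.05])
        jaccard = len(sig_mine & sig_theirs) / max(len(sig_mine | sig_theirs), 1)
        assert jaccard > 0.8


class TestRankPeaks:
    def test_signed_ranking_example(self):
        stats_df = pd.DataFrame(
            {"log2fc": [1.0, 1.0, -1.0], "pvalue": [0.01, 0.5, 0.01]},
            index=["A", "B", "C"],
        )
        ranked = diffacc.rank_peaks(stats_df)
        assert ranked.loc["A", "rank"] == 1
        assert ranked.loc["B", "rank"] == 2
        assert ranked.loc["C", "rank"] == 3

    def test_tie_break_by_input_order(self):
        stats_df = pd.DataFrame(
            {"log2fc": [1.0] * 4, "pvalue": [0.2] * 4}, index=list("wxyz")
        )
        ranked = diffacc.rank_peaks(stats_df)
        assert ranked["rank"].tolist() == [1, 2, 3, 4]

    def test_zero_fc_block_sits_between(self):
        stats_df = pd.DataFrame(
            {"log2fc": [2.0, 0.0, 0.0, -2.0], "pvalue": [0.01, 0.9, 0.1, 0.01]},
            index=list("abcd"),
        )
        ranked = diffacc.rank_peaks(stats_df)
        assert ranked.loc["a", "rank"] == 1
        assert ranked.loc["d", "rank"] == 4
        # zero block ordered by descending p
        assert ranked.loc["b", "rank"] == 2
        assert ranked.loc["c", "rank"] == 3

    def test_missing_pvalue_errors(self):
        stats_df = pd.DataFrame({"log2fc": [1.0], "pvalue": [np.nan]}, index=["a"])
        with pytest.raises(ValueError):
            diffacc.rank_peaks(stats_df)

    def test_rank_is_permutation_large(self):
        rng = np.random.default_rng(0)
        m = 50_000
        stats_df = pd.DataFrame(
            {"log2fc": rng.normal(size=m), "pvalue": rng.uniform(size=m)}
        )
        ranked = diffacc.rank_peaks(stats_df)
        assert sorted(ranked["rank"]) == list(range(1, m + 1))

    def test_opening_ranks_precede_closing_with_shared_pvalues(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        pv = np.concatenate([p[:50], p[:50]])
        stats_df = pd.DataFrame(
            {"log2fc": np.where(np.arange(100) % 2 == 0, 1.0, -1.0),
             "pvalue": pv, "padj": pv}
        )
        ranked = diffacc.classify_dynamic(diffacc.rank_peaks(stats_df), alpha=0.9999)
        opening_ranks = ranked.loc[ranked.state == "opening", "rank"]
        closing_ranks = ranked.loc[ranked.state == "closing", "rank"]
        assert opening_ranks.max() < closing_ranks.min()


class TestClassifyDynamic:
    def test_bonferroni_arithmetic(self):
        stats_df = pd.DataFrame(
            {"log2fc": [1.0, 0.5], "pvalue": [0.001, 0.2],
             "padj": [0.004, 0.8]},
        )
        ranked = diffacc.rank_peaks(stats_df)
        out = diffacc.classify_dynamic(ranked, alpha=0.05)
        assert out["state"].tolist() == ["opening", "unchanged"]

    def test_alpha_validation(self):
        stats_df = pd.DataFrame({"log2fc": [1.0], "pvalue": [0.5], "padj": [0.5]})
        with pytest.raises(ValueError):
            diffacc.classify_dynamic(diffacc.rank_peaks(stats_df), alpha=1.5)


class TestAnnotate:
    def _setup(self):
        genes = [
            Gene(id="g+", tss=GenomicInterval("chr1", 100_000, 100_001, "+")),
            Gene(id="g-", tss=GenomicInterval("chr1", 200_000, 200_001, "-")),
        ]
        exons = [GenomicInterval("chr1", 100_000, 100_500)]
        introns = [GenomicInterval("chr1", 100_500, 130_000)]
        return genes, exons, introns

    def test_upstream_strand_aware(self):
        genes, exons, introns = self._setup()
        peaks = [
            _peak("up_plus", 95_000, 95_400),     # 5 kb upstream of g+
            _peak("up_minus", 205_000, 205_400),  # 5 kb upstream of g- (right side)
            _peak("down_minus", 195_000, 195_400),  # downstream of g-, intergenic
        ]
        ann = diffacc.annotate_peaks(peaks, genes, exons, introns)
        assert ann.loc["up_plus", "category"] == "upstream_10kb"
        assert ann.loc["up_minus", "category"] == "upstream_10kb"
        assert ann.loc["down_minus", "category"] == "intergenic"

    def test_precedence_and_intron(self):
        genes, exons, introns = self._setup()
        peaks = [
            _peak("in_intron", 120_000, 120_300),
            # overlaps both the exon and the upstream window boundary
            _peak("both", 99_900, 100_200),
        ]
        ann = diffacc.annotate_peaks(peaks, genes, exons, introns)
        assert ann.loc["in_intron", "category"] == "intron"
        assert ann.loc["both", "category"] == "upstream_10kb"

    def test_no_genes_errors(self):
        with pytest.raises(ValueError):
            diffacc.annotate_peaks([_peak("p", 0, 10)], [])


class TestOverlapFraction:
    def test_identity_disjoint_partial(self):
        a = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(3)]
        assert diffacc.peak_overlap_fraction(a, a)["fraction"] == 1.0
        b = [GenomicInterval("chr2", 0, 50)]
        assert diffacc.peak_overlap_fraction(a, b)["fraction"] == 0.0
        c = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 100, 150)]
        assert diffacc.peak_overlap_fraction(a, c)["fraction"] == pytest.approx(2 / 3)

    def test_empty_a_errors(self):
        with pytest.raises(ValueError):
            diffacc.peak_overlap_fraction([], [])


class TestRankBinFrequency:
    def test_two_bins(self):
        ranked = pd.DataFrame(
            {"rank": range(1, 21)}, index=[f"p{i}" for i in range(20)]
        )
        hits = {f"p{i}" for i in range(10)}  # ranks 1..10
        out = diffacc.rank_bin_frequency(ranked, hits, bin_size=10)
        assert out["hit_fraction"].tolist() == [1.0, 0.0]
        assert out["rank_hi"].tolist() == [10, 20]

    def test_uniform_hits_flat(self):
        rng = np.random.default_rng(3)
        m = 5000
        ranked = pd.DataFrame({"rank": range(1, m + 1)},
                              index=[f"p{i}" for i in range(m)])
        hits = {f"p{i}" for i in rng.choice(m, size=1000, replace=False)}
        out = diffacc.rank_bin_frequency(ranked, hits, bin_size=500)
        frac = out["hit_fraction"].to_numpy()
        # each bin ~ Binomial(500, 0.2)/500
        sd = np.sqrt(0.2 * 0.8 / 500)
        assert np.all(np.abs(frac - 0.2) < 4 * sd)

    def test_bin_size_validation(self):
        ranked = pd.DataFrame({"rank": [1]}, index=["p"])
        with pytest.raises(ValueError):
            diffacc.rank_bin_frequency(ranked, set(), bin_size=0)
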