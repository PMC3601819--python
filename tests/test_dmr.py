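"""DMR caller: Fisher test, BH, binning, merging, summaries."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from dmrpipe.dmr import (
    DMR,
    DMRCallingParams,
    bh_adjust,
    bin_counts,
    call_dmrs,
    dmr_genome_coverage,
    dmr_size_histogram,
    dmrs_to_frame,
    estimate_error_rate,
    fisher_exact_many,
    fisher_exact_two_sided,
    read_dmr_bed,
    write_dmr_bed,
)
from dmrpipe.intervals import IntervalIndex
from tests.conftest import make_sample


class TestFisher:
    def test_extreme_table_exact_value(self):
        # 2 / C(20, 10): only the two perfectly separated tables are as extreme
        assert fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(
            2 / 184756, rel=1e-9
        )

    @pytest.mark.parametrize("table", [(5, 5, 5, 5), (3, 7, 3, 7), (0, 0, 0, 0)])
    def test_balanced_tables_give_one(self, table):
        assert fisher_exact_two_sided(*table) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_scipy(self, table):
        ours = fisher_exact_two_sided(*table)
        ref = scipy_fisher([[table[0], table[1]], [table[2], table[3]]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        a, b, c, d = rng.integers(0, 50, size=(4, 200))
        vec = fisher_exact_many(a, b, c, d)
        for i in range(200):
            assert vec[i] == fisher_exact_two_sided(a[i], b[i], c[i], d[i])


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.001, 0.01, 0.02, 0.8])
        assert q == pytest.approx([0.004, 0.02, 2 / 75, 0.8], rel=1e-9)

    def test_degenerate_cases(self):
        assert bh_adjust([]).size == 0
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_adjust([0.03]) == pytest.approx([0.03])  # m=1 identity

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_preserves_order(self, p):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(ref, rel=1e-12, abs=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone in p order


class TestErrorRate:
    def test_pooled_arithmetic(self, sample_factory):
        sample = sample_factory(
            [("chrC", i, "+", "CG", 1 if i < 10 else 0, 10) for i in range(100)],
            organelle=("chrC",),
        )
        assert estimate_error_rate(sample, "CG") == pytest.approx(0.01)

    def test_zero_methylation(self, sample_factory):
        sample = sample_factory(
            [("chrC", i, "+", "CHH", 0, 10) for i in range(100)], organelle=("chrC",)
        )
        assert estimate_error_rate(sample, "CHH") == 0.0

    def test_no_organelle_coverage_is_explicit_error(self, sample_factory):
        sample = sample_factory([("chr1", 0, "+", "CG", 1, 2)])
        with pytest.raises(ValueError, match="undefined"):
            estimate_error_rate(sample, "CG")

    def test_recovers_simulated_error_rate(self, small_sim):
        # binomial oracle: pooled estimate within 3 SE of the generating rate
        truth = small_sim["truth"]
        rate = truth.config.error_rate
        sample = small_sim["samples"]["WT1"]
        org = sample.organelle_calls()
        n = int(org["n_total"].sum())
        se = math.sqrt(rate * (1 - rate) / n)
        pooled = int(org["n_meth"].sum()) / n
        assert abs(pooled - rate) < 3 * se
        for ctx in ("CG", "CHG", "CHH"):
            assert estimate_error_rate(sample, ctx) == pytest.approx(rate, abs=6 * se)


def dense_pair(bin_levels, n_sites=12, reads=15, context="CG"):
    """Sample/control pair with n_sites cytosines in each listed bin.

    bin_levels: {bin_index: (sample_level, control_level)} with deterministic
    counts (level * reads, exact) so significance is driven by design.
    """
    s_rows, c_rows = [], []
    for b, (lvl_s, lvl_c) in bin_levels.items():
        for i in range(n_sites):
            pos = b * 100 + (i * 100) // n_sites
            s_rows.append(("chr1", pos, "+", context, int(round(lvl_s * reads)), reads))
            c_rows.append(("chr1", pos, "+", context, int(round(lvl_c * reads)), reads))
    return make_sample(s_rows, "S"), make_sample(c_rows, "C")


class TestBinCounts:
    def test_half_open_bin_assignment(self, sample_factory):
        sample = sample_factory(
            [("chr1", 99, "+", "CG", 5, 10), ("chr1", 100, "+", "CG", 5, 10)]
        )
        control = sample_factory([("chr1", 99, "+", "CG", 5, 10)], "c")
        params = DMRCallingParams()
        bins = bin_counts(sample, control, params, "CG", {"chr1": 1000})
        assert list(bins["start"]) == [0, 100]

    def test_informative_filter_requires_both_sides(self):
        sample, control = dense_pair({0: (0.9, 0.0)}, n_sites=9)
        _, control12 = dense_pair({0: (0.9, 0.0)}, n_sites=12)
        params = DMRCallingParams()
        bins = bin_counts(sample, control12, params, "CG", {"chr1": 1000})
        assert not bins["eligible"].iloc[0]  # 9 informative in sample, 12 in control
        assert bins["n_informative_sample"].iloc[0] == 9
        assert bins["n_informative_control"].iloc[0] == 12

    def test_pooled_fraction_arithmetic(self, sample_factory):
        sample = sample_factory(
            [("chr1", 0, "+", "CG", 18, 20), ("chr1", 50, "-", "CG", 0, 0)]
        )
        control = sample_factory([("chr1", 10, "+", "CG", 0, 20)], "c")
        bins = bin_counts(sample, control, DMRCallingParams(), "CG", {"chr1": 1000})
        row = bins.iloc[0]
        assert row["frac_sample"] == pytest.approx(0.9)
        assert row["frac_control"] == pytest.approx(0.0)
        assert row["diff"] == pytest.approx(0.9)

    def test_unknown_chromosome_rejected(self, sample_factory):
        sample = sample_factory([("chrX", 0, "+", "CG", 1, 2)])
        with pytest.raises(KeyError):
            bin_counts(sample, sample, DMRCallingParams(), "CG", {"chr1": 1000})


class TestCallDmrs:
    sizes = {"chr1": 10_000}

    def test_identical_counts_give_no_dmrs(self):
        sample, control = dense_pair({0: (0.8, 0.8), 3: (0.1, 0.1)})
        assert call_dmrs(sample, control, DMRCallingParams(), "CG", self.sizes) == []

    def test_self_comparison_warns(self):
        sample, _ = dense_pair({0: (0.8, 0.8)})
        with pytest.warns(UserWarning, match="self-comparison"):
            call_dmrs(sample, sample, DMRCallingParams(), "CG", self.sizes)

    def test_gap_of_100_merges_two_bins(self):
        # significant hypo bins [0,100) and [200,300); gap exactly merge_gap
        sample, control = dense_pair({0: (0.0, 0.9), 2: (0.0, 0.9)}, n_sites=20)
        dmrs = call_dmrs(sample, control, DMRCallingParams(), "CG", self.sizes)
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end, dmrs[0].direction) == (0, 300, "hypo")
        assert dmrs[0].n_bins == 2

    def test_gap_above_merge_gap_stays_split(self):
        sample, control = dense_pair({0: (0.0, 0.9), 3: (0.0, 0.9)}, n_sites=20)
        dmrs = call_dmrs(sample, control, DMRCallingParams(), "CG", self.sizes)
        assert [(d.start, d.end) for d in dmrs] == [(0, 100), (300, 400)]

    def test_opposite_directions_never_merge(self):
        sample, control = dense_pair({0: (0.0, 0.9), 1: (0.9, 0.0)}, n_sites=20)
        dmrs = call_dmrs(sample, control, DMRCallingParams(), "CG", self.sizes)
        assert {d.direction for d in dmrs} == {"hypo", "hyper"}
        assert len(dmrs) == 2

    def test_diff_below_threshold_not_called(self):
        sample, control = dense_pair({0: (0.3, 0.9)}, n_sites=20)  # diff 0.6 < 0.7
        assert call_dmrs(sample, control, DMRCallingParams(), "CG", self.sizes) == []

    def test_threshold_monotonicity(self):
        sample, control = dense_pair(
            {0: (0.0, 0.9), 2: (0.2, 0.9), 5: (0.35, 0.9)}, n_sites=20
        )
        counts = []
        for cut in (0.5, 0.7, 0.9):
            params = DMRCallingParams(min_abs_diff={"CG": cut, "CHG": 0.5, "CHH": 0.1})
            counts.append(len(call_dmrs(sample, control, params, "CG", self.sizes)))
        assert counts == sorted(counts, reverse=True)

    def test_planted_cg_dmrs_recovered(self, small_sim):
        truth = small_sim["truth"]
        samples = small_sim["samples"]
        dmrs = call_dmrs(
            samples["R1_T2"], samples["WT1"], DMRCallingParams(), "CG", small_sim["nuclear"]
        )
        hypo = [d for d in dmrs if d.direction == "hypo"]
        planted = truth.planted_of_context("CG")
        lost = planted[truth.loss["R1_T2"].reindex(planted["dmr_id"]).to_numpy()]
        assert len(lost) > 0
        truth_idx = IntervalIndex(
            lost["chrom"].to_numpy(), lost["start"].to_numpy(), lost["end"].to_numpy()
        )
        called = pd.DataFrame(
            [(d.chrom, d.start, d.end) for d in hypo], columns=["chrom", "start", "end"]
        )
        # every called hypo-DMR lands on a truly lost region, and most lost
        # regions are found (full sensitivity/precision bounds are checked at
        # acceptance scale)
        assert truth_idx.count_overlapping(called) == len(hypo)
        call_idx = IntervalIndex(
            called["chrom"].to_numpy(), called["start"].to_numpy(), called["end"].to_numpy()
        )
        assert call_idx.count_overlapping(lost) >= 0.75 * len(lost)

    def test_output_sorted_and_disjoint(self, small_sim):
        samples = small_sim["samples"]
        dmrs = call_dmrs(
            samples["R2_T2"], samples["WT1"], DMRCallingParams(), "CG", small_sim["nuclear"]
        )
        frame = dmrs_to_frame(dmrs)
        for _, grp in frame.groupby(["direction", "chrom"]):
            assert grp["start"].is_monotonic_increasing
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()


class TestSummaries:
    def mk(self, chrom, start, end, direction="hypo"):
        return DMR(chrom, start, end, "CG", direction, 0.1, 0.9, (end - start) // 100)

    def test_genome_coverage(self):
        dmrs = [self.mk("chr1", 0, 100), self.mk("chr1", 500, 800)]
        assert dmr_genome_coverage(dmrs, 372_000_000) == pytest.approx(400 / 372e6)
        assert dmr_genome_coverage([], 1000) == 0.0
        assert dmr_genome_coverage([self.mk("chr1", 0, 1000)], 1000) == 1.0

    def test_overlapping_set_rejected(self):
        dmrs = [self.mk("chr1", 0, 200), self.mk("chr1", 100, 300)]
        with pytest.raises(ValueError, match="overlap"):
            dmr_genome_coverage(dmrs, 1000)

    def test_size_histogram(self):
        dmrs = [self.mk("chr1", 0, 100), self.mk("chr1", 500, 800), self.mk("chr2", 0, 100)]
        hist = dmr_size_histogram(dmrs)
        assert hist == {100: 2, 300: 1}

    def test_bed_roundtrip(self, tmp_path):
        dmrs = [self.mk("chr1", 0, 300), self.mk("chr2", 100, 200, "hyper")]
        path = tmp_path / "dmrs.bed"
        write_dmr_bed(dmrs, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t")[:5] == ["chr1", "0", "300", "CG:hypo", "800"]
        back = read_dmr_bed(path)
        assert [(d.chrom, d.start, d.end, d.direction) for d in back] == [
            ("chr1", 0, 300, "hypo"),
            ("chr2", 100, 200, "hyper"),
        ]
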