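"""Generator contracts: determinism, marginals, truth consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrpipe.simulate import (
    ORGANELLE_CHROM,
    SimConfig,
    draw_counts,
    read_truth,
    simulate_genome,
    simulate_methylomes,
    simulate_mrna,
    simulate_smrna,
    write_truth,
)

TINY = dict(
    n_chroms=1,
    chrom_length_bp=200_000,
    n_genes=20,
    n_te_genes=6,
    n_planted_dmrs={"CG": 5, "CHG": 3, "CHH": 3},
    n_callus_hyper=5,
)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        config = SimConfig(seed=5, **TINY)
        g1, genes1, sizes1, org1 = simulate_genome(config)
        g2, genes2, sizes2, org2 = simulate_genome(SimConfig(seed=5, **TINY))
        assert g1 == g2 and sizes1 == sizes2 and org1 == org2
        assert [(g.gene_id, g.start, g.end, g.exons) for g in genes1] == [
            (g.gene_id, g.start, g.end, g.exons) for g in genes2
        ]

    def test_different_seeds_differ(self):
        g1, *_ = simulate_genome(SimConfig(seed=1, **TINY))
        g2, *_ = simulate_genome(SimConfig(seed=2, **TINY))
        assert g1["chr1"] != g2["chr1"]

    def test_gc_content_near_target(self):
        genome, *_ = simulate_genome(SimConfig(seed=3, **TINY))
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.43, abs=0.01)

    def test_no_protein_coding_genes(self):
        cfg = dict(TINY, n_genes=0)
        _, genes, *_ = simulate_genome(SimConfig(seed=1, **cfg))
        assert genes and all(g.is_te for g in genes)

    def test_genome_too_short(self):
        cfg = dict(TINY, chrom_length_bp=10_000, n_genes=50)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(SimConfig(seed=1, **cfg))

    def test_organelle_chromosome_present(self):
        genome, _, sizes, org = simulate_genome(SimConfig(seed=1, **TINY))
        assert org == {ORGANELLE_CHROM}
        assert sizes[ORGANELLE_CHROM] == SimConfig().chloroplast_length_bp


class TestSimulateMethylomes:
    def test_deterministic(self, small_sim):
        config = small_sim["config"]
        genome, genes, sizes, _ = simulate_genome(config)
        samples2, truth2 = simulate_methylomes(genome, genes, sizes, config)
        assert samples2["WT1"].calls.equals(small_sim["samples"]["WT1"].calls)
        assert truth2.planted.equals(small_sim["truth"].planted)
        assert truth2.loss.equals(small_sim["truth"].loss)

    def test_chloroplast_error_rate_oracle(self, small_sim):
        """Pooled organelle methylation ~ error_rate within 3 binomial SE."""
        truth = small_sim["truth"]
        for sid in ("WT1", "R1_T2", "Callus"):
            org = small_sim["samples"][sid].organelle_calls()
            n = int(org["n_total"].sum())
            rate = truth.config.error_rate
            se = math.sqrt(rate * (1 - rate) / n)
            assert int(org["n_meth"].sum()) / n == pytest.approx(rate, abs=3 * se)

    def test_observed_marginals_match_truth(self, small_sim):
        """Per-context mean observed methylation ~ mean true p (+error) within 3 SE."""
        truth = small_sim["truth"]
        sample = small_sim["samples"]["WT1"]
        calls = sample.nuclear_calls()
        nuclear = ~truth.site_table["organelle"].to_numpy()
        p = truth.p_true["WT1"]
        err = truth.config.error_rate
        for ctx in ("CG", "CHG", "CHH"):
            sub = calls[calls["context"] == ctx]
            observed = sub["n_meth"].sum() / sub["n_total"].sum()
            sel = nuclear & (truth.site_table["context"].to_numpy() == ctx)
            expected = float(np.mean(p[sel] + (1 - p[sel]) * err))
            n_reads = int(sub["n_total"].sum())
            se = math.sqrt(expected * (1 - expected) / n_reads)
            # 5 SE: per-read draws are clustered by site, so the binomial SE
            # understates the true spread a little
            assert observed == pytest.approx(expected, abs=max(5 * se, 0.003))

    def test_truth_planted_regions_are_callable(self, small_sim):
        """Every planted DMR overlaps >= 10 context cytosines (informative filter)."""
        truth = small_sim["truth"]
        sites = truth.site_table
        for row in truth.planted.itertuples(index=False):
            n = (
                (sites["chrom"] == row.chrom)
                & (sites["pos"] >= row.start)
                & (sites["pos"] < row.end)
                & (sites["context"] == row.context)
            ).sum()
            assert n >= 10

    def test_planted_levels_fall_by_delta(self, small_sim):
        truth = small_sim["truth"]
        p_wt = truth.p_true["WT1"]
        p_rg = truth.p_true["R1_T2"]
        sites = truth.site_table
        for row in truth.planted.itertuples(index=False):
            sel = (
                (sites["chrom"] == row.chrom)
                & (sites["pos"] >= row.start)
                & (sites["pos"] < row.end)
                & (sites["context"] == row.context)
            ).to_numpy()
            if truth.loss.at[row.dmr_id, "R1_T2"]:
                drop = p_wt[sel].mean() - p_rg[sel].mean()
                assert drop == pytest.approx(min(row.delta, row.level), abs=0.02)
            else:
                assert (p_wt[sel] == p_rg[sel]).all()

    def test_shared_site_fraction_one_loses_everything(self):
        config = SimConfig(seed=2, shared_site_fraction=1.0, **TINY)
        genome, genes, sizes, _ = simulate_genome(config)
        _, truth = simulate_methylomes(genome, genes, sizes, config)
        t2_cols = [c for c in truth.loss.columns if c.endswith("_T2")]
        assert truth.loss[t2_cols].to_numpy().all()

    def test_callus_gains_chh_where_regenerants_do_not(self, small_sim):
        truth = small_sim["truth"]
        sites = truth.site_table
        assert len(truth.callus_hyper) > 0
        row = truth.callus_hyper.iloc[0]
        sel = (
            (sites["chrom"] == row["chrom"])
            & (sites["pos"] >= row["start"])
            & (sites["pos"] < row["end"])
            & (sites["context"] == "CHH")
        ).to_numpy()
        gain = truth.p_true["Callus"][sel] - truth.p_true["WT1"][sel]
        assert gain == pytest.approx(truth.config.callus_hyper_gain, abs=1e-6)
        assert (truth.p_true["R1_T2"][sel] == truth.p_true["WT1"][sel]).all()

    def test_inheritance_consistency(self, small_sim):
        truth = small_sim["truth"]
        lost_t2 = truth.loss["R1_T2"]
        for dmr_id, category in truth.stability.items():
            if not lost_t2[dmr_id]:
                assert pd.isna(category) or category is None
                continue
            t4, t6 = truth.loss.at[dmr_id, "R1_T4"], truth.loss.at[dmr_id, "R1_T6"]
            expected = {
                "stable_loss": (True, True),
                "recovered_T4": (False, False),
                "recovered_T6_only": (True, False),
                "transient_T4": (False, True),
            }[category]
            assert (t4, t6) == expected

    def test_draw_counts_replicates_differ_but_share_truth(self, small_sim):
        truth = small_sim["truth"]
        a = draw_counts(truth, "WT1", 100, contexts=["CG"])
        b = draw_counts(truth, "WT1", 101, contexts=["CG"])
        assert not a.calls["n_meth"].equals(b.calls["n_meth"])
        assert set(a.calls["context"]) == {"CG"}


class TestSmallRNA:
    def test_length_histogram_only_21_and_24(self, small_sim):
        smrna = simulate_smrna(small_sim["truth"], sample_ids=["WT1"])
        assert set(smrna["WT1"]["length"].unique()) <= {21, 24}

    def test_24nt_track_methylation_loss(self, small_sim):
        truth = small_sim["truth"]
        smrna = simulate_smrna(truth, sample_ids=["WT1", "R1_T2"])
        chh = truth.planted_of_context("CHH")
        lost = chh[truth.loss["R1_T2"].reindex(chh["dmr_id"]).to_numpy()]
        assert len(lost) > 0

        def reads_in(table, row):
            t24 = table[table["length"] == 24]
            sel = (
                (t24["chrom"] == row.chrom)
                & (t24["start"] >= row.start - 50)
                & (t24["start"] < row.end)
            )
            return t24[sel]["count"].sum()

        wt_total = sum(reads_in(smrna["WT1"], r) for r in lost.itertuples(index=False))
        rg_total = sum(reads_in(smrna["R1_T2"], r) for r in lost.itertuples(index=False))
        assert wt_total > rg_total

    def test_deterministic(self, small_sim):
        a = simulate_smrna(small_sim["truth"], sample_ids=["WT1"])["WT1"]
        b = simulate_smrna(small_sim["truth"], sample_ids=["WT1"])["WT1"]
        assert a.equals(b)


class TestMRNA:
    def test_zero_responsiveness_means_no_de_truth(self, small_sim):
        truth = small_sim["truth"]
        config = SimConfig(**{**truth.config.__dict__, "responsiveness": 0.0})
        counts, libs = simulate_mrna(truth, small_sim["genes"], config)
        assert all(len(v) == 0 for v in truth.de_genes.values())
        assert (libs > 0).all()

    def test_full_responsiveness_upregulates_promoter_hit_genes(self, small_sim):
        truth = small_sim["truth"]
        config = SimConfig(
            **{**truth.config.__dict__, "responsiveness": 1.0, "mrna_dispersion": 0.0}
        )
        counts, _ = simulate_mrna(truth, small_sim["genes"], config)
        de = truth.de_genes["R1_T2"]
        assert de  # some promoters overlap lost regions by construction
        non_de = [g for g in counts.index if g not in de]
        assert counts.loc[sorted(de), "R1_T2"].mean() > 2.5 * counts.loc[non_de, "R1_T2"].mean()

    def test_deterministic(self, small_sim):
        truth = small_sim["truth"]
        a, _ = simulate_mrna(truth, small_sim["genes"])
        b, _ = simulate_mrna(truth, small_sim["genes"])
        assert a.equals(b)


class TestTruthLedger:
    def test_roundtrip_sections(self, small_sim, tmp_path):
        truth = small_sim["truth"]
        simulate_mrna(truth, small_sim["genes"])  # populate de_genes
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert len(back["planted"]) == len(truth.planted)
        assert set(back["planted"]["context"]) == set(truth.planted["context"])
        assert "lost_R1_T2" in back["planted"].columns

    def test_version_check(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("#something-else\n")
        with pytest.raises(ValueError, match="truth ledger"):
            read_truth(bad)
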