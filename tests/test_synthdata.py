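"""Generator contracts: determinism, conservation, moment match, effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, poisson

from zdose import SimulationDesign, synthdata
from zdose.types import Genotype, TelegraphParams


class TestMakeAnnotation:
    def test_no_z_genes_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            synthdata.make_annotation(
                SimulationDesign(n_genes_per_chrom={"1": 10, "Z": 0, "W": 1}, seed=0)
            )

    def test_same_seed_identical(self, small_design, small_annotation):
        again = synthdata.make_annotation(small_design)
        pd.testing.assert_frame_equal(small_annotation, again)

    def test_lengths_within_range(self, small_annotation):
        assert small_annotation["exonic_length_bp"].between(300, 30_000).all()

    def test_tata_rate_within_binomial_ci(self):
        design = SimulationDesign(
            n_genes_per_chrom={"1": 500, "Z": 150}, tata_rate=0.15, seed=9
        )
        ann = synthdata.make_annotation(design)
        n = len(ann)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.15) / n
        assert lo <= ann["tata"].mean() <= hi


class TestSampleTelegraphCounts:
    def test_zero_synthesis_all_zero(self):
        counts = synthdata.sample_telegraph_counts(TelegraphParams(1, 1, 0), 100, 0)
        assert np.all(counts == 0)

    def test_mean_matches_closed_form(self):
        # E[n] = k_syn * k_on / (k_on + k_off) = 5
        counts = synthdata.sample_telegraph_counts(TelegraphParams(1, 1, 10), 100_000, 1)
        se = counts.std() / np.sqrt(counts.size)
        assert abs(counts.mean() - 5.0) < 3 * se

    def test_poisson_limit_total_variation(self):
        counts = synthdata.sample_telegraph_counts(TelegraphParams(1e4, 1e4, 10), 200_000, 2)
        ns = np.arange(0, 40)
        emp = np.bincount(counts, minlength=40)[:40] / counts.size
        tv = 0.5 * np.abs(emp - poisson.pmf(ns, 5.0)).sum()
        assert tv < 0.01

    @pytest.mark.parametrize("params", [(0.5, 5, 50), (2, 4, 30), (1, 6, 50)])
    def test_moment_match_at_10k_cells(self, params):
        tp = TelegraphParams(*params)
        counts = synthdata.sample_telegraph_counts(tp, 10_000, 3)
        s = params[0] + params[1]
        var_cf = tp.mean_expression + params[2] ** 2 * params[0] * params[1] / (s**2 * (s + 1))
        se = np.sqrt(var_cf / 10_000)
        assert abs(counts.mean() - tp.mean_expression) < 4 * se

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            synthdata.sample_telegraph_counts(TelegraphParams(np.inf, 1, 1), 10, 0)


class TestSimulateBulk:
    def test_allelic_layers_sum_to_total(self, small_bulk):
        bulk, _ = small_bulk
        total = bulk["RJF"].to_numpy() + bulk["WL"].to_numpy()
        assert np.array_equal(total, bulk["total"].to_numpy())

    def test_null_design_mf_ratio_near_two(self, small_annotation):
        design = SimulationDesign(
            n_genes_per_chrom={"1": 900, "mu": 900, "Z": 150, "W": 5}, seed=21
        ).null()
        ann = synthdata.make_annotation(design)
        bulk, _ = synthdata.simulate_bulk_experiment(ann, design)
        sexes = bulk.unit_meta["sex"]
        males = sexes[sexes == "male"].index
        females = sexes[sexes == "female"].index
        z_genes = ann.loc[ann["chrom"] == "Z", "gene_id"]
        ratio = (
            bulk["total"].loc[z_genes, males].mean(axis=1)
            / bulk["total"].loc[z_genes, females].mean(axis=1)
        )
        assert 1.85 < ratio.median() < 2.15

    def test_female_single_z_upregulated_by_u(self):
        design = SimulationDesign(
            n_genes_per_chrom={"1": 300, "Z": 300, "W": 5}, seed=22
        ).null(u=1.5)
        ann = synthdata.make_annotation(design)
        bulk, truth = synthdata.simulate_bulk_experiment(ann, design)
        z_genes = ann.loc[ann["chrom"] == "Z", "gene_id"]
        exp = truth.extra["expected_counts"]
        # female single-Z expectation vs one male Z-allele expectation
        f_z = exp["ZW_1"].loc[z_genes, "WL"]
        m_z = exp["ZZ_1"].loc[z_genes, "WL"]
        # depth scaling differs slightly between samples; compare relative to
        # an autosomal anchor
        a_genes = ann.loc[ann["chrom"] == "1", "gene_id"]
        anchor = exp["ZW_1"].loc[a_genes].sum().sum() / exp["ZZ_1"].loc[a_genes].sum().sum()
        ratio = (f_z / m_z / anchor).median()
        assert ratio == pytest.approx(1.5, rel=0.05)

    def test_deterministic(self, small_design, small_annotation):
        b1, _ = synthdata.simulate_bulk_experiment(small_annotation, small_design)
        b2, _ = synthdata.simulate_bulk_experiment(small_annotation, small_design)
        assert b1.equals(b2)


class TestSimulateSc:
    def test_truth_covers_genes_by_alleles_present(self, small_sc, small_annotation):
        _, _, truth = small_sc
        chrom = small_annotation["chrom"]
        n_w = (chrom == "W").sum()
        n_z = (chrom == "Z").sum()
        n_auto = len(small_annotation) - n_w - n_z
        per_sample = truth.true_params.groupby("sample_id").size()
        # one truth row per (gene, distinct allele origin present)
        assert per_sample["ZZ_1"] == 2 * (n_auto + n_z)
        assert per_sample["ZW_1"] == 2 * n_auto + n_z + n_w
        assert per_sample["ZZW_1"] == 2 * (n_auto + n_z) + n_w

    def test_spike_and_endogenous_disjoint(self, small_sc):
        sc, spikes, _ = small_sc
        assert len(set(sc.genes) & set(spikes.index)) == 0

    def test_deterministic(self, small_design, small_annotation, small_sc):
        sc1, sp1, _ = small_sc
        sc2, sp2, _ = synthdata.simulate_sc_experiment(small_annotation, small_design)
        assert sc1.equals(sc2)
        pd.testing.assert_frame_equal(sp1, sp2)

    def test_too_few_cells_rejected(self, small_annotation, small_design):
        with pytest.raises(ValueError, match="50"):
            synthdata.simulate_sc_experiment(
                small_annotation, small_design.with_effects(n_cells=20)
            )


class TestSimulateRiboProtein:
    def test_protein_genes_subset_of_rna(self, small_design, small_annotation, small_bulk):
        bulk, truth = small_bulk
        ribo, protein, _ = synthdata.simulate_ribo_protein(small_annotation, small_design, truth)
        assert set(protein.index) <= set(ribo.index) == set(bulk.genes)

    def test_null_tau_gives_unit_te_ratio(self):
        design = SimulationDesign(
            n_genes_per_chrom={"1": 250, "mu": 250, "Z": 250, "W": 5}, seed=31
        ).null()
        ann = synthdata.make_annotation(design)
        bulk, truth = synthdata.simulate_bulk_experiment(ann, design)
        ribo, _, te_truth = synthdata.simulate_ribo_protein(ann, design, truth)
        z = ann.loc[ann["chrom"] == "Z", "gene_id"]
        assert np.allclose(
            te_truth.true_te.loc[z, "ZW_1"], te_truth.true_te.loc[z, "ZZ_1"]
        )

    def test_tau_boosts_w_bearing_z_te(self, small_design, small_annotation, small_bulk):
        _, truth = small_bulk
        _, _, te_truth = synthdata.simulate_ribo_protein(small_annotation, small_design, truth)
        z = small_annotation.loc[small_annotation["chrom"] == "Z", "gene_id"]
        ratio = te_truth.true_te.loc[z, "ZW_1"] / te_truth.true_te.loc[z, "ZZ_1"]
        assert np.allclose(ratio, small_design.tau)


@pytest.fixture(scope="module")
def variant_world():
    design = SimulationDesign(
        n_genes_per_chrom={"1": 60, "Z": 40}, seed=41, base_error=0.0
    )
    ann = synthdata.make_annotation(design)
    wl, rjf, truth = synthdata.simulate_variant_calls(ann, design)
    return design, ann, wl, rjf, truth


class TestSimulateReads:

    def test_noiseless_reads_match_truth_everywhere(self, variant_world):
        design, ann, wl, _, truth = variant_world
        reads, read_truth = synthdata.simulate_reads_at_variants(design, truth, wl, 3000)
        vt = wl.copy()
        vt["variant_key"] = (
            vt["chrom"].astype(str) + ":" + vt["pos"].astype(str) + ":" + vt["ref"] + ":" + vt["alt"]
        )
        expected = vt.set_index("variant_key")[["ref", "alt"]]
        merged = reads.join(read_truth.true_read_alleles, on="read_id")
        exp_base = np.where(
            merged["true_allele"] == "WL",
            expected.loc[merged["variant_key"], "alt"],
            expected.loc[merged["variant_key"], "ref"],
        )
        assert (merged["base"].to_numpy() == exp_base).all()

    def test_mismatch_rate_within_binomial_ci(self, variant_world):
        design, ann, wl, _, truth = variant_world
        noisy = design.with_effects(base_error=0.01, variants_per_read=(3, 3))
        reads, read_truth = synthdata.simulate_reads_at_variants(noisy, truth, wl, 20_000)
        vt = wl.copy()
        vt["variant_key"] = (
            vt["chrom"].astype(str) + ":" + vt["pos"].astype(str) + ":" + vt["ref"] + ":" + vt["alt"]
        )
        expected = vt.set_index("variant_key")[["ref", "alt"]]
        merged = reads.join(read_truth.true_read_alleles, on="read_id")
        exp_base = np.where(
            merged["true_allele"] == "WL",
            expected.loc[merged["variant_key"], "alt"],
            expected.loc[merged["variant_key"], "ref"],
        )
        merged["mismatch"] = merged["base"].to_numpy() != exp_base
        per_read = merged.groupby("read_id")["mismatch"].any()
        reads3 = per_read[merged.groupby("read_id").size() == 3]
        p_expected = 1 - 0.99**3
        n = len(reads3)
        lo, hi = binom.ppf([0.005, 0.995], n, p_expected) / n
        assert lo <= reads3.mean() <= hi

    def test_deterministic(self, variant_world):
        design, _, wl, _, truth = variant_world
        r1, t1 = synthdata.simulate_reads_at_variants(design, truth, wl, 500)
        r2, t2 = synthdata.simulate_reads_at_variants(design, truth, wl, 500)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_series_equal(t1.true_read_alleles, t2.true_read_alleles)


class TestNullFaithfulness:
    def test_chromosome_level_tests_calibrated_under_null(self):
        """With u=tau=beta=rho=1 the chromosome-level contrasts stay
        non-significant at alpha=0.01 in >= 90% of replicate seeds."""
        from zdose import dosage

        n_clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            design = SimulationDesign(
                n_genes_per_chrom={"1": 120, "mu": 120, "Z": 100, "W": 4},
                depth=3e5,
                seed=1000 + seed,
            ).null()
            ann = synthdata.make_annotation(design)
            bulk, truth = synthdata.simulate_bulk_experiment(ann, design)
            ribo, protein, _ = synthdata.simulate_ribo_protein(ann, design, truth)
            lengths = ann.set_index("gene_id")["exonic_length_bp"]
            f = dosage.fpkm(bulk["total"], lengths)
            mask = dosage.expressed_mask(f)
            mf = dosage.sex_ratio_per_gene(f, bulk.unit_meta["sex"], mask)
            ps = []
            ps.append(dosage.group_ratio_test(mf, ann, "mir_target", within_chrom="Z").p_value)
            te = dosage.translation_index(dosage.fpkm(ribo, lengths), f)
            ps.append(dosage.te_ratio_tests(te, bulk.unit_meta["sex"], ann)["F:M"]["p_value"])
            prot_mf = dosage.sex_ratio_per_gene(
                protein * 1e6, bulk.unit_meta["sex"].loc[protein.columns], pseudocount=1e-6
            )
            _, wtest = dosage.modality_summary({"RNA": mf, "protein": prot_mf}, ann, seed=seed)
            ps.append(wtest.p_value)
            if all(p > 0.01 for p in ps):
                n_clean += 1
        assert n_clean >= 0.9 * n_seeds
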