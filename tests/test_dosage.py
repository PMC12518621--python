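"""Dosage statistics: FPKM calculus, QC, ratios, resampling tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from zdose import dosage
from zdose.types import TestResult as ComparisonResult

from conftest import make_counts


class TestFpkm:
    def test_unit_arithmetic(self):
        counts = make_counts([[10]])
        lengths = pd.Series([1000], index=counts.index)
        lib = pd.Series([1_000_000], index=counts.columns)
        assert dosage.fpkm(counts, lengths, lib).iloc[0, 0] == pytest.approx(10.0)

    def test_within_unit_ratios_scale_invariant(self):
        rng = np.random.default_rng(1)
        counts = make_counts(rng.integers(1, 100, (20, 4)))
        lengths = pd.Series(rng.integers(500, 5000, 20), index=counts.index)
        f1 = dosage.fpkm(counts, lengths)
        f2 = dosage.fpkm(counts * 7, lengths)
        np.testing.assert_allclose(
            (f1 / f1.iloc[0]).to_numpy(), (f2 / f2.iloc[0]).to_numpy()
        )

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        counts = make_counts(rng.integers(0, 50, (10, 3)))
        lengths = pd.Series(rng.integers(300, 3000, 10), index=counts.index)
        f = dosage.fpkm(counts, lengths)
        lib = counts.sum(axis=0)
        for g, u in itertools.product(counts.index, counts.columns):
            expected = counts.loc[g, u] * 1e9 / (lengths[g] * lib[u])
            assert f.loc[g, u] == expected

    def test_zero_library_dropped(self):
        counts = make_counts([[5, 0], [5, 0]])
        lengths = pd.Series([1000, 1000], index=counts.index)
        f = dosage.fpkm(counts, lengths)
        assert list(f.columns) == ["u0"]


class TestExpressedMask:
    def test_exactly_threshold_excluded(self):
        f = make_counts([[1.0, 1.0], [1.5, 0.6], [0.2, 0.1]]).astype(float)
        mask = dosage.expressed_mask(f, threshold=1.0)
        assert list(mask) == [False, True, False]

    def test_zero_threshold_keeps_nonzero(self):
        f = make_counts([[0.0, 0.0], [0.1, 0.0]]).astype(float)
        mask = dosage.expressed_mask(f, threshold=0.0)
        assert list(mask) == [False, True]

    def test_per_group_scope(self):
        # gene passes globally but fails in tissue B: scoped mask drops it
        f = make_counts([[5.0, 0.5], [5.0, 5.0]]).astype(float)
        scope = pd.Series({"u0": "A", "u1": "B"})
        assert list(dosage.expressed_mask(f, scope=scope)) == [False, True]
        assert list(dosage.expressed_mask(f)) == [True, True]


class TestSpikeNormalisation:
    def test_unit_mean_scaling(self):
        spikes = make_counts([[100, 200, 300]])
        f = dosage.spike_size_factors(spikes)
        np.testing.assert_allclose(f.to_numpy(), [0.5, 1.0, 1.5])

    def test_equal_totals_identity(self):
        spikes = make_counts([[50, 50, 50], [10, 10, 10]])
        counts = make_counts(np.arange(12).reshape(4, 3))
        f = dosage.spike_size_factors(spikes)
        assert (f == 1).all()
        pd.testing.assert_frame_equal(
            dosage.normalize_by_spikes(counts, f), counts.astype(float)
        )

    def test_factor_mean_is_one(self):
        rng = np.random.default_rng(3)
        spikes = make_counts(rng.integers(1, 200, (5, 40)))
        f = dosage.spike_size_factors(spikes)
        assert f.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_spike_cell_rejected(self):
        spikes = make_counts([[10, 0]])
        with pytest.raises(ValueError, match="zero spike"):
            dosage.spike_size_factors(spikes)

    def test_normalisation_removes_capture_gradient(self):
        rng = np.random.default_rng(4)
        n_cells = 500
        capture = rng.lognormal(0, 0.3, n_cells)
        base = rng.integers(5, 50, 100).astype(float)
        counts = make_counts(rng.poisson(np.outer(base, capture)))
        spikes = make_counts(
            rng.poisson(np.outer(np.full(10, 40.0), capture)), units=list(counts.columns)
        )
        f = dosage.spike_size_factors(spikes)
        norm = dosage.normalize_by_spikes(counts, f)
        rho, _ = spearmanr(norm.mean(axis=0), capture)
        assert abs(rho) < 0.1
        rho_raw, _ = spearmanr(counts.mean(axis=0), capture)
        assert rho_raw > 0.8  # sanity: the gradient was there before


class TestCellQc:
    def test_high_spike_fraction_excluded(self):
        counts = make_counts(np.full((10, 3), 100))  # 1000 endo reads/cell
        spikes = make_counts([[50, 50, 140]])  # 4.8%, 4.8%, 12.3%
        kept, report = dosage.sc_cell_qc(counts, spikes)
        assert list(kept) == [True, True, False]
        assert bool(report["fail_spike_fraction"].iloc[2])

    def test_homogeneous_cells_no_outliers(self):
        rng = np.random.default_rng(5)
        counts = make_counts(rng.poisson(20, (50, 100)))
        spikes = make_counts(rng.poisson(20, (5, 100)), units=list(counts.columns))
        kept, report = dosage.sc_cell_qc(counts, spikes)
        assert not report["fail_gene_detection"].any()
        assert not report["fail_read_count"].any()

    def test_constructed_low_detection_cell_excluded(self):
        # one cell at median * 2^-4 gene detection but with enough reads to
        # clear the spike gate: the 3-MAD log gene-detection rule catches it
        rng = np.random.default_rng(6)
        lam = rng.uniform(0.3, 4.0, 200)  # variable detection across cells
        mat = rng.poisson(lam[:, None], (200, 60))
        mat[:, 0] = 0
        mat[: 200 // 16, 0] = 300  # ~median/16 genes detected, ample reads
        counts = make_counts(mat)
        spikes = make_counts(np.full((4, 60), 2), units=list(counts.columns))
        kept, report = dosage.sc_cell_qc(counts, spikes)
        assert not report["fail_spike_fraction"].iloc[0]
        assert bool(report["fail_gene_detection"].iloc[0])
        assert not kept.iloc[0]
        assert kept.iloc[1:].all()

    def test_all_cells_failing_raises(self):
        counts = make_counts(np.full((5, 3), 1))
        spikes = make_counts(np.full((2, 3), 500), units=list(counts.columns))
        with pytest.raises(ValueError, match="failed"):
            dosage.sc_cell_qc(counts, spikes)

    def test_overrepresented_spikes_dropped(self):
        spikes = make_counts(np.full((3, 4), 10))
        meta = pd.DataFrame(
            {"n_barcodes": [1, 8, 1], "n_sequences": [40, 40, 150]}, index=spikes.index
        )
        out = dosage.drop_overrepresented_spikes(spikes, meta)
        assert list(out.index) == ["g0"]


class TestSexRatios:
    SEXES = pd.Series({"m1": "male", "m2": "male", "f1": "female", "f2": "female"})

    def test_identical_expression_gives_unit_ratio(self):
        f = make_counts(np.tile([[4.0]], (6, 4)), units=list(self.SEXES.index))
        ratio = dosage.sex_ratio_per_gene(f, self.SEXES)
        assert np.allclose(ratio, 1.0)

    def test_label_swap_inverts_ratio(self):
        rng = np.random.default_rng(7)
        f = make_counts(rng.uniform(1, 50, (20, 4)), units=list(self.SEXES.index))
        r = dosage.sex_ratio_per_gene(f, self.SEXES, pseudocount=0)
        r_swapped = dosage.sex_ratio_per_gene(
            f, self.SEXES, numerator="female", denominator="male", pseudocount=0
        )
        np.testing.assert_allclose(r.to_numpy(), 1.0 / r_swapped.to_numpy())

    def test_per_unit_rescaling_invariance_through_fpkm(self):
        rng = np.random.default_rng(8)
        counts = make_counts(rng.integers(1, 1000, (30, 4)), units=list(self.SEXES.index))
        lengths = pd.Series(rng.integers(500, 5000, 30), index=counts.index)
        scaled = counts * pd.Series([1, 3, 5, 7], index=counts.columns)
        r1 = dosage.sex_ratio_per_gene(dosage.fpkm(counts, lengths), self.SEXES, pseudocount=0)
        r2 = dosage.sex_ratio_per_gene(dosage.fpkm(scaled, lengths), self.SEXES, pseudocount=0)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy())

    def test_empty_sex_group_rejected(self):
        f = make_counts([[1.0, 2.0]], units=["m1", "m2"])
        with pytest.raises(ValueError, match="female"):
            dosage.sex_ratio_per_gene(f, pd.Series({"m1": "male", "m2": "male"}))


class TestZToAutosome:
    def test_identical_distributions_near_unity(self):
        values = np.tile(np.linspace(1, 10, 60)[:, None], (2, 1))
        genes = [f"gA{i}" for i in range(60)] + [f"gZ{i}" for i in range(60)]
        f = pd.DataFrame(values, index=genes, columns=["u1"])
        ann = pd.DataFrame(
            {"gene_id": genes, "chrom": ["1"] * 60 + ["Z"] * 60}
        )
        ratio = dosage.z_to_autosome_ratio(f, ann)
        assert ratio["u1"] == pytest.approx(1.0)

    def test_insufficient_genes_skipped(self):
        genes = ["a", "z"]
        f = pd.DataFrame([[1.0], [1.0]], index=genes, columns=["u1"])
        ann = pd.DataFrame({"gene_id": genes, "chrom": ["1", "Z"]})
        assert dosage.z_to_autosome_ratio(f, ann).empty


class TestBootstrapMedianTest:
    def test_exhaustive_enumeration_oracle(self):
        # background {1,2,3,4}, k=2: subset medians {1.5, 2, 2.5, 2.5, 3, 3.5};
        # observed median 3, tail greater -> exhaustive p = 2/6
        background = np.array([1.0, 2.0, 3.0, 4.0])
        target = np.array([2.5, 3.5])  # median 3
        medians = [np.median(c) for c in itertools.combinations(background, 2)]
        p_exact = np.mean([m >= 3.0 for m in medians])
        assert p_exact == pytest.approx(2 / 6)
        res = dosage.bootstrap_median_test(
            target, background, n_draws=20_000, tail="greater", seed=0, min_target=2
        )
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.p_value - p_exact) < 3 * se

    def test_resampling_floor(self):
        background = np.arange(100, dtype=float)
        target = np.full(5, 1e9)
        res = dosage.bootstrap_median_test(target, background, n_draws=1000, tail="greater", seed=1)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_tail_must_be_declared(self):
        with pytest.raises(ValueError):
            dosage.bootstrap_median_test(np.ones(5), np.arange(10.0), tail="auto")

    def test_background_must_exceed_target(self):
        with pytest.raises(ValueError):
            dosage.bootstrap_median_test(np.ones(6), np.arange(5.0), tail="greater")

    def test_less_tail_symmetry(self):
        rng = np.random.default_rng(2)
        background = rng.normal(size=200)
        target = background[:20] - 3
        res = dosage.bootstrap_median_test(target, background, n_draws=5000, tail="less", seed=3)
        assert res.p_value < 0.01


class TestPercentileCi:
    def test_constant_vector_degenerate(self):
        lo, hi = dosage.percentile_ci(np.full(20, 3.3), seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_coverage_for_normal_median(self):
        rng = np.random.default_rng(4)
        covered = 0
        n_rep = 200
        for i in range(n_rep):
            x = rng.normal(size=1000)
            lo, hi = dosage.percentile_ci(x, n_boot=300, seed=i)
            covered += lo <= 0.0 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(5)
        small = rng.normal(size=20)
        big = rng.normal(size=2000)
        lo_s, hi_s = dosage.percentile_ci(small, seed=1)
        lo_b, hi_b = dosage.percentile_ci(big, seed=1)
        assert (hi_s - lo_s) > (hi_b - lo_b)


class TestTranslationIndex:
    def test_identical_layers_give_unit_te(self):
        f = make_counts(np.full((5, 3), 10.0))
        te = dosage.translation_index(f, f)
        assert np.allclose(te.to_numpy(), 1.0)

    def test_low_rna_gene_excluded(self):
        rpf = make_counts([[10.0, 10.0], [10.0, 10.0]])
        rna = make_counts([[10.0, 10.0], [0.5, 0.5]])
        te = dosage.translation_index(rpf, rna)
        assert list(te.index) == ["g0"]


class TestGroupRatioTest:
    ANN = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(40)],
            "chrom": ["Z"] * 20 + ["1"] * 20,
            "mir_target": ([True] * 5 + [False] * 15) * 2,
        }
    )

    def test_single_group_rejected(self):
        ratio = pd.Series(1.0, index=self.ANN["gene_id"])
        ann = self.ANN.assign(mir_target=True)
        with pytest.raises(ValueError, match="non-empty"):
            dosage.group_ratio_test(ratio, ann, "mir_target", within_chrom="Z")

    def test_detects_planted_difference(self):
        rng = np.random.default_rng(6)
        ratio = pd.Series(rng.lognormal(0, 0.05, 40), index=self.ANN["gene_id"])
        flagged_z = self.ANN.loc[(self.ANN["chrom"] == "Z") & self.ANN["mir_target"], "gene_id"]
        ratio[flagged_z] *= 0.5
        res = dosage.group_ratio_test(ratio, self.ANN, "mir_target", within_chrom="Z")
        assert res.p_value < 0.01
        assert res.extra["median_flagged"] < res.extra["median_unflagged"]
        null = dosage.group_ratio_test(ratio, self.ANN, "mir_target", within_chrom="autosome")
        assert null.p_value > 0.05

    def test_random_flags_are_calibrated(self):
        rng = np.random.default_rng(7)
        ratio = pd.Series(rng.lognormal(0, 0.3, 40), index=self.ANN["gene_id"])
        hits = 0
        for i in range(100):
            ann = self.ANN.copy()
            ann["mir_target"] = rng.permutation(ann["mir_target"].to_numpy())
            res = dosage.group_ratio_test(ratio, ann, "mir_target", within_chrom="Z")
            hits += res.p_value < 0.05
        assert hits <= 15


class TestPromoterAssociation:
    @staticmethod
    def fits(n, rng, tata_effect=1.0):
        tata = rng.random(n) < 0.3
        inr = rng.random(n) < 0.4
        k_syn = rng.lognormal(3, 0.4, n) * np.where(tata, tata_effect, 1.0)
        k_off = rng.lognormal(1, 0.3, n)
        k_on = rng.lognormal(0, 0.3, n)
        fits = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "allele": "RJF",
                "k_on": k_on, "k_off": k_off, "k_syn": k_syn,
                "burst_frequency": k_on,
                "burst_size": k_syn / k_off,
                "loglik": -1.0, "n_cells": 100, "status": "converged",
            }
        )
        ann = pd.DataFrame({"gene_id": fits["gene_id"], "chrom": "1", "tata": tata, "inr": inr})
        return fits, ann

    def test_independent_flag_near_zero(self):
        fits, ann = self.fits(2000, np.random.default_rng(8))
        table = dosage.promoter_kinetics_association(fits, ann)
        row = table[(table["flag"] == "tata") & (table["metric"] == "burst_size")].iloc[0]
        assert abs(row["rho"]) < 0.05

    def test_tata_doubling_detected(self):
        fits, ann = self.fits(2000, np.random.default_rng(9), tata_effect=2.0)
        table = dosage.promoter_kinetics_association(fits, ann)
        row = table[(table["flag"] == "tata") & (table["metric"] == "burst_size")].iloc[0]
        assert row["rho"] > 0 and row["p_value"] < 1e-4

    def test_rank_invariance_under_log_base(self):
        fits, ann = self.fits(500, np.random.default_rng(10), tata_effect=1.5)
        t1 = dosage.promoter_kinetics_association(fits, ann)
        fits2 = fits.copy()
        for col in ("burst_size", "burst_frequency"):
            fits2[col] = fits2[col] ** 2  # monotone transform
        t2 = dosage.promoter_kinetics_association(fits2, ann)
        np.testing.assert_allclose(t1["rho"].dropna(), t2["rho"].dropna(), atol=1e-12)


class TestOeEnrichment:
    def test_uniform_density_is_one(self):
        counts = pd.Series({"1": 50, "2": 100, "Z": 25})
        lengths = pd.Series({"1": 500, "2": 1000, "Z": 250})
        assert np.allclose(dosage.oe_enrichment(counts, lengths), 1.0)

    def test_worked_arithmetic(self):
        counts = pd.Series({"a": 10, "b": 30})
        lengths = pd.Series({"a": 100, "b": 100})
        oe = dosage.oe_enrichment(counts, lengths)
        np.testing.assert_allclose(oe.to_numpy(), [0.5, 1.5])

    def test_length_weighted_mean_is_one(self):
        rng = np.random.default_rng(11)
        counts = pd.Series(rng.integers(1, 100, 8), index=[str(i) for i in range(8)])
        lengths = pd.Series(rng.integers(100, 1000, 8), index=counts.index)
        oe = dosage.oe_enrichment(counts, lengths)
        weighted = (oe * lengths / lengths.sum()).sum()
        assert weighted == pytest.approx(1.0)

    def test_zero_length_excluded(self):
        counts = pd.Series({"a": 10, "bad": 5})
        lengths = pd.Series({"a": 100, "bad": 0})
        assert "bad" not in dosage.oe_enrichment(counts, lengths).index


class TestModalitySummary:
    ANN = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(30)], "chrom": ["Z"] * 15 + ["1"] * 15}
    )

    def test_identical_ratios_identical_rows(self):
        ratio = pd.Series(1.4, index=self.ANN["gene_id"])
        table, _ = dosage.modality_summary({"RNA": ratio, "Ribo": ratio.copy()}, self.ANN)
        assert table["chrZ_median"].nunique() == 1

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(12)
        tables = {
            m: pd.Series(rng.lognormal(0.3, 0.2, 30), index=self.ANN["gene_id"])
            for m in ("RNA", "Ribo", "protein")
        }
        table, _ = dosage.modality_summary(tables, self.ANN, seed=1)
        assert ((table["ci_low"] <= table["chrZ_median"]) & (table["chrZ_median"] <= table["ci_high"])).all()

    def test_protein_shift_detected_by_wilcoxon(self):
        rng = np.random.default_rng(13)
        rna = pd.Series(rng.lognormal(np.log(1.4), 0.05, 30), index=self.ANN["gene_id"])
        prot = rna * 0.8
        _, test = dosage.modality_summary({"RNA": rna, "protein": prot}, self.ANN, seed=2)
        assert isinstance(test, ComparisonResult)
        assert test.p_value < 0.01
        assert test.observed < test.extra["rna_chrZ_median"]
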