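"""Self-contained recovery experiments: simulate, analyse, summarise.

Each function wires generator output through the analysis modules at a
stated problem size and returns the recovered quantities, so that parameter
recovery, ratio calculus and test calibration can be checked (and reported)
from a single seed. These are the experiments behind the package's
headline checks; problem sizes are chosen to keep each run in the
seconds-to-minutes range on one core while leaving the estimators'
sampling error well inside the documented recovery bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allelic, dosage, kinetics, synthdata
from .types import Genotype, SimulationDesign, TelegraphParams


def _design(seed: int, **kw) -> SimulationDesign:
    return SimulationDesign(seed=seed, **kw)


# ---------------------------------------------------------------------------
# kinetics


def telegraph_recovery(
    seed: int, n_genes: int = 200, n_cells: int = 1000,
    kon_range=(0.2, 5.0), koff_range=(1.0, 20.0), ksyn_range=(10.0, 200.0),
) -> dict:
    """Fit genes simulated at log-uniform telegraph parameters.

    Returns the median |log2(k_on_hat / k_on)| over successful fits and the
    converged fraction.
    """
    rng = np.random.default_rng(seed)

    def lu(lohi, n):
        return np.exp(rng.uniform(np.log(lohi[0]), np.log(lohi[1]), n))

    kon, koff, ksyn = lu(kon_range, n_genes), lu(koff_range, n_genes), lu(ksyn_range, n_genes)
    errs, n_conv = [], 0
    for i in range(n_genes):
        counts = synthdata.sample_telegraph_counts(
            TelegraphParams(kon[i], koff[i], ksyn[i]), n_cells, rng
        )
        fit = kinetics.fit_telegraph(counts)
        if fit.status == "converged":
            n_conv += 1
        if fit.params is not None:
            errs.append(abs(np.log2(fit.params.k_on / kon[i])))
    return {
        "median_abs_log2_kon_error": float(np.median(errs)),
        "fraction_converged": n_conv / n_genes,
        "n_genes": n_genes,
        "n_cells": n_cells,
    }


def _sc_genotype_design(seed: int, karyotype: str, n_z: int, n_autosomal: int, n_cells: int,
                        **effects) -> SimulationDesign:
    geno = {
        "ZW": Genotype("ZW_1", "ZW", ("WL",), ("RJF",), ("RJF", "WL")),
        "ZZ": Genotype("ZZ_1", "ZZ", ("RJF", "WL"), (), ("RJF", "WL")),
        "ZZW": Genotype("ZZW_1", "ZZW", ("WL", "RJF"), ("WL",), ("WL", "RJF", "WL")),
    }[karyotype]
    half = n_autosomal // 2
    # spike budget ~5% of the expected endogenous UMIs so the 10% QC gate
    # stays meaningful at any panel size
    n_total = n_z + n_autosomal
    base = _design(
        seed,
        n_genes_per_chrom={"1": half, "2": n_autosomal - half, "Z": n_z},
        genotypes=(geno,),
        n_cells=n_cells,
        spike_mean_total=0.7 * n_total,
    )
    return base.null(**effects) if effects else base


def sc_kinetics_experiment(
    seed: int,
    karyotype: str = "ZW",
    n_z: int = 150,
    n_autosomal: int = 400,
    n_cells: int = 500,
    **effects,
) -> dict:
    """Single-genotype scRNA-seq run through QC, normalisation and fitting.

    Returns per-allele relative burst-frequency and burst-size contrasts
    (chrZ vs chrA medians, Mann-Whitney p) for alleles with single-haplotype
    layers; in ZZW only the RJF layer is fitted (the WL layer mixes two
    haplotypes).
    """
    design = _sc_genotype_design(seed, karyotype, n_z, n_autosomal, n_cells, **effects)
    ann = synthdata.make_annotation(design)
    sc, spikes, truth = synthdata.simulate_sc_experiment(ann, design)
    spikes = dosage.drop_overrepresented_spikes(spikes)
    qc_mask, _ = dosage.sc_cell_qc(sc["total"], spikes)
    factors = dosage.spike_size_factors(spikes, qc_mask)
    sub = sc.subset_units(factors.index)
    lengths = ann.set_index("gene_id")["exonic_length_bp"]
    norm_total = dosage.normalize_by_spikes(sub["total"], factors)
    mask = dosage.expressed_mask(dosage.fpkm(norm_total, lengths), threshold=1.0)
    alleles = ("RJF",) if karyotype == "ZZW" else ("RJF", "WL")
    fits = kinetics.fit_all(
        sub, ann, size_factors=factors,
        expressed_genes=mask[mask].index, alleles=alleles,
    )
    out = {"fits": fits, "truth": truth, "annotation": ann}
    for metric in ("burst_frequency", "burst_size"):
        out[metric] = kinetics.relative_kinetics_log2(fits, ann, metric=metric, seed=seed)
    return out


def z_allele_result(exp: dict, metric: str = "burst_frequency") -> dict:
    """The relative-kinetics contrast of the allele carrying Z fits."""
    results = exp[metric]
    with_z = [r for r in results.values() if r["n_z"] > 0]
    if not with_z:
        raise ValueError("no allele carries converged Z fits")
    return max(with_z, key=lambda r: r["n_z"])


# ---------------------------------------------------------------------------
# bulk ratios


def bulk_ratio_experiment(seed: int, u: float = 1.5, null_others: bool = True, **design_kw) -> dict:
    """Bulk run returning the chrZ M:F median and per-sample Z:AA ratios."""
    design = _design(seed, **design_kw)
    design = design.null(u=u) if null_others else design.with_effects(u=u)
    ann = synthdata.make_annotation(design)
    bulk, _ = synthdata.simulate_bulk_experiment(ann, design)
    lengths = ann.set_index("gene_id")["exonic_length_bp"]
    f = dosage.fpkm(bulk["total"], lengths)
    mask = dosage.expressed_mask(f)
    mf = dosage.sex_ratio_per_gene(f, bulk.unit_meta["sex"], mask)
    by_chrom = dosage.chromosome_medians(mf, ann)
    zaa = dosage.z_to_autosome_ratio(f, ann, mask)
    karyo = bulk.unit_meta["karyotype"]
    return {
        "mf_chrZ_median": float(by_chrom.at["Z", "median"]),
        "z_aa_zw": float(zaa[karyo[zaa.index] == "ZW"].mean()),
        "z_aa_zz": float(zaa[karyo[zaa.index] == "ZZ"].mean()),
        "z_aa": zaa,
        "mf": mf,
        "annotation": ann,
        "fpkm": f,
        "mask": mask,
        "sexes": bulk.unit_meta["sex"],
    }


def te_experiment(seed: int, tau: float = 1.2, null_others: bool = True, **design_kw) -> dict:
    """Matched RNA/footprint run returning F:M and I:M TE contrasts."""
    design = _design(seed, **design_kw)
    design = design.null(tau=tau) if null_others else design.with_effects(tau=tau)
    ann = synthdata.make_annotation(design)
    bulk, bulk_truth = synthdata.simulate_bulk_experiment(ann, design)
    ribo, protein, _ = synthdata.simulate_ribo_protein(ann, design, bulk_truth)
    lengths = ann.set_index("gene_id")["exonic_length_bp"]
    rna_fpkm = dosage.fpkm(bulk["total"], lengths)
    ribo_fpkm = dosage.fpkm(ribo, lengths)
    te = dosage.translation_index(ribo_fpkm, rna_fpkm)
    tests = dosage.te_ratio_tests(te, bulk.unit_meta["sex"], ann)
    return {"te": te, "tests": tests, "annotation": ann}


def multilayer_experiment(seed: int, **design_kw) -> dict:
    """Full dosage run at the design's default effects (u, tau, beta, rho).

    Returns RNA/footprint/protein chrZ M:F medians, the miR-target
    contrasts on Z and autosomes, the protein-vs-RNA Wilcoxon comparison and
    the underlying ratio tables.
    """
    design = _design(seed, **design_kw)
    ann = synthdata.make_annotation(design)
    bulk, bulk_truth = synthdata.simulate_bulk_experiment(ann, design)
    ribo, protein, _ = synthdata.simulate_ribo_protein(ann, design, bulk_truth)
    lengths = ann.set_index("gene_id")["exonic_length_bp"]
    sexes = bulk.unit_meta["sex"]
    rna_fpkm = dosage.fpkm(bulk["total"], lengths)
    mask = dosage.expressed_mask(rna_fpkm)
    mf = dosage.sex_ratio_per_gene(rna_fpkm, sexes, mask)
    ribo_fpkm = dosage.fpkm(ribo, lengths)
    ribo_mf = dosage.sex_ratio_per_gene(ribo_fpkm, sexes, mask)
    prot_mf = dosage.sex_ratio_per_gene(protein * 1e6, sexes.loc[protein.columns], pseudocount=1e-6)
    zaa = dosage.z_to_autosome_ratio(rna_fpkm, ann, mask)
    te = dosage.translation_index(ribo_fpkm, rna_fpkm)
    te_tests = dosage.te_ratio_tests(te, sexes, ann)
    summary, prot_test = dosage.modality_summary(
        {"RNA": mf, "Ribo": ribo_mf, "protein": prot_mf}, ann, seed=seed
    )
    mir_z = dosage.group_ratio_test(mf, ann, "mir_target", within_chrom="Z")
    mir_a = dosage.group_ratio_test(mf, ann, "mir_target", within_chrom="autosome")
    karyo = bulk.unit_meta["karyotype"]
    return {
        "annotation": ann,
        "summary": summary,
        "mf": mf,
        "mf_chrZ_median": float(summary.set_index("modality").at["RNA", "chrZ_median"]),
        "protein_chrZ_median": float(summary.set_index("modality").at["protein", "chrZ_median"]),
        "ribo_chrZ_median": float(summary.set_index("modality").at["Ribo", "chrZ_median"]),
        "z_aa_zw": float(zaa[karyo[zaa.index] == "ZW"].mean()),
        "z_aa_zz": float(zaa[karyo[zaa.index] == "ZZ"].mean()),
        "te_tests": te_tests,
        "protein_vs_rna": prot_test,
        "mir_z": mir_z,
        "mir_autosome": mir_a,
    }


# ---------------------------------------------------------------------------
# allelic assignment


def allelic_accuracy_experiment(seed: int, n_reads: int = 100_000, **design_kw) -> dict:
    """End-to-end assignment accuracy against the simulated truth."""
    design_kw.setdefault("n_genes_per_chrom", {"1": 150, "Z": 80})
    design = _design(seed, **design_kw)
    ann = synthdata.make_annotation(design)
    wl, rjf, var_truth = synthdata.simulate_variant_calls(ann, design)
    final = allelic.derive_final_variants(wl, rjf)
    gm = allelic.build_genotype_map(final)
    reads, read_truth = synthdata.simulate_reads_at_variants(design, var_truth, wl, n_reads)
    assigned = allelic.assign_reads(reads, gm)
    merged = assigned.merge(
        read_truth.true_read_alleles.rename("true_allele"), left_on="read_id", right_index=True
    )
    hit = merged[merged["allele"] != "unassigned"]
    return {
        "accuracy": float((hit["allele"] == hit["true_allele"]).mean()),
        "unassigned_fraction": float((merged["allele"] == "unassigned").mean()),
        "n_reads": int(len(merged)),
        "n_final_variants": int(len(final)),
    }
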