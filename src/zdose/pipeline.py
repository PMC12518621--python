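"""Pipeline orchestration: simulate -> allelic -> normalise/QC -> kinetics
-> dosage -> report, all randomness derived from one configured seed."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, dosage, io, kinetics, synthdata
from .types import SimulationDesign, Genotype, default_genotypes

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration; the seed is mandatory for every stochastic stage."""

    out_dir: str
    seed: int
    design: SimulationDesign
    expression_threshold: float = 1.0
    min_cells: int = 50
    bootstrap_draws: int = 10_000
    ci_boot: int = 1000
    n_reads: int = 50_000
    kinetics_samples: tuple = ()  # empty = all samples
    kinetics_max_genes: int = 0  # 0 = no cap; otherwise deterministic head per chromosome
    run_kinetics: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("refusing to run: a seed is mandatory")
        if not (0 < self.expression_threshold < 1e6):
            raise ValueError("expression threshold out of bounds")
        if self.min_cells < 10:
            raise ValueError("min_cells below any sensible bound")
        if self.bootstrap_draws < 100 or self.ci_boot < 100:
            raise ValueError("resampling sizes too small to be meaningful")
        if self.design.n_genes_per_chrom.get("Z", 0) < 1:
            raise ValueError("config requests no Z genes; pipeline meaningless")
        if self.run_kinetics and self.design.n_spikes == 0:
            raise ValueError(
                "kinetics stage requires spike normalisation but the design has no spike species"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        design_raw = dict(raw.pop("design", {}))
        if "genotypes" in design_raw:
            design_raw["genotypes"] = tuple(
                Genotype(
                    g["sample_id"], g["karyotype"],
                    tuple(g.get("z_origins", ())), tuple(g.get("w_origins", ())),
                    tuple(g.get("autosome_origins", ())),
                )
                for g in design_raw["genotypes"]
            )
        if "n_genes_per_chrom" in design_raw:
            design_raw["n_genes_per_chrom"] = {
                str(k): int(v) for k, v in design_raw["n_genes_per_chrom"].items()
            }
        seed = raw.pop("seed", None)
        if seed is None:
            raise ValueError("refusing to run: config lacks a seed")
        design = SimulationDesign(seed=int(design_raw.pop("seed", seed)), **design_raw)
        known = {f for f in cls.__dataclass_fields__ if f not in ("design",)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "kinetics_samples" in raw:
            raw["kinetics_samples"] = tuple(raw["kinetics_samples"])
        return cls(design=design, seed=int(seed), **raw)


@dataclass
class RunReport:
    stages: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int, elapsed: float, **params):
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
             "elapsed_s": round(elapsed, 3), "params": params}
        )
        log.info("stage %s: %d -> %d rows (%.1fs)", name, n_in, n_out, elapsed)

    def to_json(self, path):
        io.write_json({"stages": self.stages, "results": self.results}, path)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        import json

        with open(path) as fh:
            raw = json.load(fh)
        return cls(stages=raw["stages"], results=raw["results"])

    @property
    def digests(self) -> dict:
        return {k: v for k, v in self.results.get("files", {}).items()}


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(salt,)).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order; failures halt with a partial
    report on disk. Outputs are plain-text tables re-loadable by this
    package's readers, and byte-identical across runs at fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    files = {}
    report.results["files"] = files
    design = config.design
    try:
        _run_stages(config, out, report, files, design)
    finally:
        report.to_json(out / "run_report.json")
    return report


def _register(files: dict, *paths):
    for p in paths:
        files[Path(p).name] = io.file_digest(p)


def _run_stages(config, out, report, files, design):
    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    ann = synthdata.make_annotation(design)
    bulk, bulk_truth = synthdata.simulate_bulk_experiment(ann, design)
    sc, spikes, sc_truth = synthdata.simulate_sc_experiment(ann, design)
    ribo, protein, te_truth = synthdata.simulate_ribo_protein(ann, design, bulk_truth)
    wl_raw, rjf_raw, var_truth = synthdata.simulate_variant_calls(ann, design)
    panel = pd.DataFrame(
        {
            "unit_id": ["WL_M1", "WL_F1", "RJF_M1", "RJF_F1"],
            "breed": ["WL", "WL", "RJF", "RJF"],
            "sex": ["male", "female", "male", "female"],
        }
    )
    pure_reads, _ = synthdata.simulate_reads_at_variants(
        design, var_truth, wl_raw, n_reads=config.n_reads // 2, seed_salt=8, panel=panel
    )
    f1_reads, read_truth = synthdata.simulate_reads_at_variants(
        design, var_truth, wl_raw, n_reads=config.n_reads, seed_salt=9
    )
    io.write_annotation_tsv(ann, out / "annotation.tsv")
    io.write_gtf_lite(ann, out / "annotation.gtf")
    io.write_counts_tsv(bulk, out, prefix="bulk")
    io.write_table(ribo, out / "ribo_counts.tsv", index=True, index_label="gene_id")
    io.write_table(protein, out / "protein_abundance.tsv", index=True, index_label="gene_id")
    io.write_vcf_min(wl_raw, out / "wl_raw.vcf")
    io.write_vcf_min(rjf_raw, out / "rjf_raw.vcf")
    io.write_counts_mtx(sc, out, prefix="sc")
    io.write_table(spikes, out / "spike_umis.tsv", index=True, index_label="spike_id")
    synthdata.write_truth_bundle(sc_truth, out / "sc_truth.json")
    synthdata.write_truth_bundle(read_truth, out / "read_truth.json")
    _register(
        files, out / "annotation.tsv", out / "annotation.gtf", out / "bulk.total.tsv",
        out / "ribo_counts.tsv", out / "protein_abundance.tsv",
        out / "sc.total.mtx", out / "spike_umis.tsv",
    )
    report.add_stage("simulate", 0, len(ann), time.perf_counter() - t0, seed=design.seed)

    # --- allelic ------------------------------------------------------------
    t0 = time.perf_counter()
    conc = allelic.concordance_counts(
        pure_reads, allelic.informative_variant_sets(
            allelic.first_pass_variant_filter(wl_raw), allelic.first_pass_variant_filter(rjf_raw)
        )["unique_wl"],
        panel,
    )
    final_variants = allelic.derive_final_variants(
        wl_raw, rjf_raw, allelic_counts=conc,
        sample_sexes=panel.set_index("unit_id")["sex"].to_dict(),
    )
    gm = allelic.build_genotype_map(final_variants)
    assignments = allelic.assign_reads(f1_reads, gm)
    acm = allelic.aggregate_allelic_counts(assignments, ann)
    merged = assignments.merge(
        read_truth.true_read_alleles.rename("true_allele"), left_on="read_id", right_index=True
    )
    assigned = merged[merged["allele"] != "unassigned"]
    accuracy = float((assigned["allele"] == assigned["true_allele"]).mean()) if len(assigned) else np.nan
    io.write_vcf_min(final_variants, out / "final_variants.vcf")
    io.write_table(final_variants, out / "final_variants.tsv")
    io.write_counts_tsv(acm, out, prefix="allelic_reads")
    _register(files, out / "final_variants.tsv", out / "allelic_reads.total.tsv")
    report.results["allelic"] = {
        "n_final_variants": int(len(final_variants)),
        "assignment_accuracy": accuracy,
        "unassigned_fraction": float((merged["allele"] == "unassigned").mean()),
    }
    report.add_stage("allelic", len(wl_raw), len(final_variants), time.perf_counter() - t0)

    # --- normalise / QC -----------------------------------------------------
    t0 = time.perf_counter()
    spikes_clean = dosage.drop_overrepresented_spikes(spikes)
    qc_mask, qc_report = dosage.sc_cell_qc(sc["total"], spikes_clean)
    factors = dosage.spike_size_factors(spikes_clean, qc_mask)
    io.write_table(qc_report, out / "cell_qc.tsv", index=True, index_label="cell")
    io.write_table(factors.to_frame(), out / "size_factors.tsv", index=True, index_label="cell")
    _register(files, out / "cell_qc.tsv", out / "size_factors.tsv")
    report.results["qc"] = {"n_cells_kept": int(qc_mask.sum()), "n_cells": int(len(qc_mask))}
    report.add_stage("qc", len(qc_mask), int(qc_mask.sum()), time.perf_counter() - t0)

    # --- kinetics -----------------------------------------------------------
    lengths = ann.set_index("gene_id")["exonic_length_bp"]
    if config.run_kinetics:
        t0 = time.perf_counter()
        kin_samples = config.kinetics_samples or tuple(g.sample_id for g in design.genotypes)
        kin_genes = ann
        if config.kinetics_max_genes:
            kin_genes = ann.groupby("chrom", sort=False).head(config.kinetics_max_genes)
        all_fits, rel_results = [], {}
        for sample in kin_samples:
            cells = [c for c in sc.units if sc.unit_meta.at[c, "sample_id"] == sample and qc_mask.get(c, False)]
            sub = sc.subset_units(cells)
            sf = factors.loc[cells]
            norm_total = dosage.normalize_by_spikes(sub["total"], sf)
            expr_mask = dosage.expressed_mask(
                dosage.fpkm(norm_total, lengths), threshold=config.expression_threshold
            )
            karyotype = sc.unit_meta.loc[cells[0], "karyotype"]
            alleles = ("RJF",) if karyotype == "ZZW" else ("RJF", "WL")
            fits = kinetics.fit_all(
                sub, ann, size_factors=sf,
                expressed_genes=kin_genes.loc[kin_genes["gene_id"].isin(expr_mask[expr_mask].index), "gene_id"],
                min_cells=config.min_cells, alleles=alleles,
            )
            fits.insert(0, "sample_id", sample)
            all_fits.append(fits)
            rel = kinetics.relative_kinetics_log2(
                fits, ann, metric="burst_frequency", n_boot=config.ci_boot,
                seed=_sub_seed(config.seed, 20),
            )
            rel_results[sample] = {
                a: {k: v for k, v in r.items() if k not in ("rel", "chroms")} for a, r in rel.items()
            }
        fits_table = pd.concat(all_fits, ignore_index=True)
        kinetics.write_fits(fits_table, out / "telegraph_fits.tsv")
        _register(files, out / "telegraph_fits.tsv")
        report.results["kinetics"] = rel_results
        report.add_stage("kinetics", len(fits_table), int((fits_table["status"] == "converged").sum()),
                         time.perf_counter() - t0)

    # --- dosage -------------------------------------------------------------
    t0 = time.perf_counter()
    sexes = bulk.unit_meta["sex"]
    rna_fpkm = dosage.fpkm(bulk["total"], lengths)
    mask = dosage.expressed_mask(rna_fpkm, threshold=config.expression_threshold)
    mf = dosage.sex_ratio_per_gene(rna_fpkm, sexes, mask)
    mf_by_chrom = dosage.chromosome_medians(mf, ann)
    zaa = dosage.z_to_autosome_ratio(rna_fpkm, ann, mask)
    ribo_fpkm = dosage.fpkm(ribo, lengths)
    te = dosage.translation_index(ribo_fpkm, rna_fpkm)
    te_tests = dosage.te_ratio_tests(te, sexes, ann)
    mir_z = dosage.group_ratio_test(mf, ann, "mir_target", within_chrom="Z")
    mir_a = dosage.group_ratio_test(mf, ann, "mir_target", within_chrom="autosome")
    prot_genes = protein.index
    prot_mf = dosage.sex_ratio_per_gene(protein * 1e6, sexes.loc[protein.columns], pseudocount=1e-6)
    ribo_mf = dosage.sex_ratio_per_gene(ribo_fpkm, sexes, mask)
    summary, prot_test = dosage.modality_summary(
        {"RNA": mf, "Ribo": ribo_mf, "protein": prot_mf},
        ann, n_boot=config.ci_boot, seed=_sub_seed(config.seed, 30),
    )
    z_mask_expr = mask & ann.set_index("gene_id")["chrom"].eq("Z")
    boot = dosage.bootstrap_median_test(
        mf[mf.index.isin(z_mask_expr[z_mask_expr].index)],
        mf[mf.index.isin(mask[mask].index)],
        n_draws=config.bootstrap_draws, tail="less", seed=_sub_seed(config.seed, 31),
    )
    io.write_table(mf.rename("mf_ratio").to_frame(), out / "mf_ratio.tsv", index=True, index_label="gene_id")
    io.write_table(mf_by_chrom, out / "mf_ratio_by_chrom.tsv", index=True, index_label="chrom")
    io.write_table(zaa.to_frame(), out / "z_aa_ratio.tsv", index=True, index_label="unit")
    io.write_table(te, out / "translation_index.tsv", index=True, index_label="gene_id")
    io.write_table(summary, out / "modality_summary.tsv")
    _register(files, out / "mf_ratio.tsv", out / "mf_ratio_by_chrom.tsv", out / "z_aa_ratio.tsv",
              out / "translation_index.tsv", out / "modality_summary.tsv")
    report.results["dosage"] = {
        "mf_chrZ_median": float(mf_by_chrom.at["Z", "median"]) if "Z" in mf_by_chrom.index else np.nan,
        "z_aa": zaa.to_dict(),
        "te": {k: {kk: vv for kk, vv in v.items() if kk != "ratio"} for k, v in te_tests.items()},
        "mir_target_Z": mir_z.as_dict(),
        "mir_target_autosome": mir_a.as_dict(),
        "protein_vs_rna": prot_test.as_dict() if prot_test else None,
        "bootstrap_mf_z_vs_all": boot.as_dict(),
        "n_protein_genes": int(len(prot_genes)),
    }
    report.add_stage("dosage", int(mask.sum()), len(mf), time.perf_counter() - t0)
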