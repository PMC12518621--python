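# zdose

Allele-resolved analysis of avian Z-chromosome dosage compensation.

Birds have ZZ males and ZW females, so a female cell carries one Z
chromosome against a diploid autosomal background. `zdose` implements the
analysis layers needed to ask how (and how far) that imbalance is
compensated, for researchers working with allele-resolved bulk and
single-cell RNA-seq, ribosome profiling and proteomics from F1-hybrid
birds:

* **allelic** — derivation of allele-informative variants from two breed
  callsets (strict first-pass filters, set algebra, a per-sex concordance
  second pass, hemizygous-Z phasing) and assignment of reads to parental
  alleles by the strict >0.66 basecall-match rule.
* **kinetics** — maximum-likelihood inference of two-state telegraph-model
  burst kinetics per gene and allele from spike-in-normalised single-cell
  UMI counts. At stationarity counts follow the beta-Poisson law
  P(n) = ∫₀¹ Pois(n; k_syn·x)·Beta(x; k_on, k_off) dx with burst frequency
  k_on and burst size k_syn/k_off (time in units of mRNA decay). The
  likelihood uses Gauss–Jacobi quadrature with the Beta weight; fits start
  from a closed-form moment estimator with deterministic fallbacks.
* **dosage** — FPKM and expressed-gene masks, spike-in size factors and
  cell QC, per-gene M:F ratios and per-sample Z:AA ratios, a
  gene-subsampling bootstrap median test, bootstrap percentile CIs,
  translation-efficiency (RPF-FPKM/RNA-FPKM) comparisons, miR-2954
  target-group contrasts, promoter-element/kinetics association, motif
  O/E enrichment, and a cross-modality chromosome summary.
* **synthdata** — a generator producing every input (annotation, breed
  VCFs, abstract reads, bulk/single-cell/footprint/protein matrices) with
  known ground truth, emulating ZZ/ZW/ZZW genotypes: female-specific
  Z-upregulation via burst frequency (`u`), triploid autosomal buffering
  (`beta`), elevated Z translation in W-bearing genotypes (`tau`), and
  male-biased miR-2954 repression (`rho`).
* **io / pipeline / cli** — GTF-lite, minimal-VCF and TSV/MatrixMarket
  readers and writers, end-to-end orchestration, and the `zdose` command
  (`simulate | allelic | kinetics | dosage | report | run`).

## Worked example

```python
from zdose import validation
from zdose.validation import z_allele_result

# a ZW female line: 150 Z + 400 autosomal genes, 500 cells, u = 1.5
exp = validation.sc_kinetics_experiment(
    seed=1, karyotype="ZW", n_z=150, n_autosomal=400, n_cells=500
)
bf = z_allele_result(exp, "burst_frequency")
bs = z_allele_result(exp, "burst_size")
print(f"Z:A burst frequency ratio {2**bf['median_z']:.3f}  (p = {bf['p_value']:.3g})")
print(f"Z:A burst size ratio      {2**bs['median_z']:.3f}  (p = {bs['p_value']:.3g})")
```

prints

```
Z:A burst frequency ratio 1.514  (p = 4.56e-29)
Z:A burst size ratio      1.069  (p = 0.855)
```

i.e. the single female Z's simulated 1.5-fold k_on elevation is recovered
as a burst-*frequency* shift (ratio ≈ 1.5, strongly significant) while
burst *size* stays at autosomal levels — the kinetic signature of
Z-upregulation. Bulk calculus behaves the same way:

```python
res = validation.bulk_ratio_experiment(seed=1, u=1.27)
print(res["mf_chrZ_median"], res["z_aa_zw"])   # 1.521  0.607
```

against the no-compensation expectations 2/1.27 ≈ 1.57 and 1.27/2 ≈ 0.635
(the few-percent shortfall is the FPKM composition effect of the sexes'
different Z content, as in real data).

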