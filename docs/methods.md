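# Methods

`zdose` analyses dosage compensation of the avian Z chromosome from
allele-resolved expression data: birds are ZZ (male) / ZW (female), so
without compensation a female expresses Z-linked genes at half the male
level and at half the diploid autosomal level. The package implements the
three analysis layers — allele-informative variant derivation with
read-to-allele assignment, transcriptional burst-kinetics inference, and
dosage statistics across RNA, ribosome-footprint and protein layers —
together with a synthetic-data generator that produces every input with
known ground truth.

## The telegraph model and its likelihood

A gene switches between OFF and ON states at rates `k_on` and `k_off`,
synthesises mRNA at rate `k_syn` while ON, and transcripts decay at rate
`k_deg`. Time is measured in units of the decay rate (`k_deg ≡ 1`), the
standard convention when only snapshot counts are observed, so all rates
are unitless. At stationarity the mRNA copy number follows the
beta-Poisson mixture

    P(n) = ∫₀¹ Pois(n; k_syn·x) · Beta(x; k_on, k_off) dx,

with burst frequency `k_on` (bursts per mRNA lifetime) and mean burst size
`k_syn / k_off` (molecules per burst). The mean is
`k_syn · k_on / (k_on + k_off)`.

Numerics:

* The integral is evaluated by 64-node Gauss–Jacobi quadrature with the
  Beta(k_on, k_off) weight, accumulated in log space. Against adaptive
  quadrature the worst absolute error over k_on, k_off ∈ {0.1, 1, 10},
  k_syn ∈ {1, 200} and n ≤ 200 is ~2×10⁻¹¹; the order is configurable.
  The Jacobi weight handles the integrable endpoint singularities that
  appear whenever `k_on < 1` or `k_off < 1`, where ordinary
  Gauss–Legendre rules lose accuracy.
* `k_syn = 0` is treated as a point mass at zero.

## Maximum-likelihood fitting

Per gene-allele count vector (minimum 50 cells by default):

1. **Initialisation.** The closed-form method-of-moments solution from the
   first three factorial moments (the ratios
   `r_k = f_k / f_{k-1}` invert to the three rates). The estimator refuses
   to return values when moments are inconsistent with the model: empty or
   constant input, non-positive factorial moments, or a dispersion index
   within three standard errors of 1 (data indistinguishable from Poisson
   cannot pin down `k_on`/`k_off`).
2. **Optimisation.** Bounded L-BFGS-B on log10 parameters,
   `k_on, k_off ∈ [10⁻³, 10³]`, `k_syn ∈ [10⁻², 10⁴]`. The moment start is
   optimised first; three deterministic grid starts (spanning bursty to
   frequent regimes, scaled by the sample mean) are added only when the
   moment start is unavailable or does not converge cleanly, and the best
   optimum is kept. Running the fallbacks lazily rather than
   unconditionally cuts the cost of large fit batches roughly fourfold and
   is deterministic given the data. The returned log-likelihood never falls
   below the start point's (the optimiser result is discarded if worse).
3. **Status.** `boundary` when a parameter ends within 1% of a box bound
   *or* when the fitted likelihood exceeds the best single-parameter
   Poisson fit by less than 2 log-units — in that corner
   (`k_on, k_off → ∞`) the rates are unidentifiable and precise estimates
   would be spurious. `failed` for flat likelihoods (all-zero or constant
   counts) or optimiser failure; `insufficient_cells` below the cell
   minimum. In triploid ZZW lines only the RJF layer is fitted: the WL
   layer sums two haplotypes and is not a single-allele observation.

Relative kinetics: per allele, `rel(g) = log2(metric_g / median autosomal
metric)`; the chrZ-vs-chrA contrast is a two-tailed Mann–Whitney U test
with bootstrap percentile CIs on the group medians. "Z elevation" is
called when the two-tailed p is below 0.05 *and* the Z median lies above
the autosomal one; requiring the direction keeps the per-test false-call
rate at α/2.

## Allelic procedure

Breed variant callsets (White Leghorn vs Red Junglefowl) pass a strict
first-pass filter (depth > 5, alternate-allele frequency > 0.5,
QUAL > 10); WL-unique and RJF-common sets follow by set algebra on the
(chrom, pos, ref, alt) key. The second pass excludes variants whose
allele-informative reads agree with the expected breed allele in fewer
than half of the male samples or fewer than half of the female samples;
"agreement" per sample is operationalised as a majority of covering reads
(the per-sample statistic is configurable; zero-coverage samples are not
evaluable and drop out of the fraction). Hemizygous-Z records are phased
against female genotypes: when the single allele a ZW female carries is
the one labelled opposite to the expected breed, REF/ALT labels are
swapped; conflicting females drop the variant. Reads are assigned to the
breed whose allele matches strictly more than 0.66 of their basecalls at
final informative positions (unknown positions are ignored in the
denominator); exactly 0.66 stays unassigned, and with two breeds the rule
cannot tie. N-masking is upstream of this package and is represented only
as bookkeeping on variant positions. On-disk interval formats are 1-based
inclusive; in-memory intervals 0-based half-open.

## Dosage statistics

* `FPKM(g,u) = counts·10⁹ / (exonic_length_bp · library_size)` with the
  library size the per-unit sum of gene counts. Expressed-gene masks use
  mean FPKM strictly above 1.
* Spike-in size factors: per-cell total spike UMIs scaled to unit mean
  over QC-passing cells, after dropping overrepresented spike species
  (>5 barcodes or >100 sequences — thresholds configurable since the units
  of the published criterion are ambiguous). Cell QC keeps cells with
  spike fraction < 10%, then removes low-tail MAD outliers (log gene
  detection > 3 MADs, log read count > 5 MADs below the median;
  normal-consistent MAD, one-sided because the criteria target *low*
  quality).
* Sex ratios are mean-based per gene with an ε = 0.01 FPKM pseudocount
  (chromosome summaries report medians, matching how such analyses are
  usually displayed); Z:AA is the within-sample median FPKM of Z genes
  over the autosomal median (≥50 expressed genes each).
* The bootstrap median test subsamples |target| genes from the background
  without replacement (with-replacement available),
  `p = (1 + #extreme) / (B + 1)` with ties counting as extreme; the tail
  must be declared by the caller. Because the null is a *subsample* of the
  background, calibration experiments use a subsample fraction ≤ a few
  percent — at large fractions the finite-population correction makes an
  independent target look anti-conservative.
* Percentile CIs: 1000 bootstrap resamples, 2.5/97.5 percentiles.
* Translation efficiency `TE = RPF-FPKM / RNA-FPKM` on genes with mean
  RPF FPKM > 1 and RNA FPKM > 1; Female:Male and Intersex:Male ratios from
  sex-group means, chrZ-vs-chrA two-tailed Mann–Whitney.
* Promoter–kinetics association: Spearman rank correlation of TATA/Inr
  flags with log burst size and log burst frequency, group medians with
  Mann–Whitney p, and the TATA+Inr vs TATA-only additive contrast.
* Motif O/E enrichment per chromosome relative to the genome-wide density
  over non-N-masked bases; the length-weighted mean is 1 by construction.
* The modality summary reports the chrZ median M:F ratio with percentile
  CI per layer (RNA, footprints, protein) and a one-sample Wilcoxon of
  per-gene protein ratios against the RNA-level chrZ median.
* Chromosome-level tests are few and reported raw; gene-level screens use
  Benjamini–Hochberg at 0.05.

## The synthetic-data generator

The generator emulates the study design: five embryonic-fibroblast-like
lines (2 ZW, 2 ZZ, 1 triploid ZZW with Z(WL) Z(RJF) W(WL) and autosomal
sets WL/RJF/WL) from reciprocal crosses of two breeds, each measured in
bulk RNA (3 technical replicates summed — negative-binomial with tripled
mean and dispersion/3, which is exact for summed i.i.d. NB), single-cell
UMIs with spike-ins, ribosome footprints and protein abundances. The four
dosage effects and their defaults:

| parameter | meaning | default |
|---|---|---|
| `u` | k_on (and bulk output) multiplier of the single Z in ZW | 1.5 |
| `tau` | translation-efficiency boost of Z genes in W-bearing genotypes | 1.2 |
| `beta` | per-copy autosomal output multiplier in ZZW (buffering); no published magnitude exists for "less than linearly additive", so 0.8 is a free choice | 0.8 |
| `rho` | miR-2954 repression of target-Z RNA in ZZ; √rho in ZZW (intermediate miR level) | 0.7 |

Noise model: negative binomial (dispersion 0.1) for bulk and footprints,
Poisson spike UMIs, lognormal protein noise (σ = 0.25) on a detectable
subset (top 50% by abundance). Single cells draw true molecule counts per
chromosome copy from the telegraph model, thin them binomially by a
per-cell capture efficiency (lognormal, mean 0.7), and spike UMIs share
the capture factor — so spike normalisation removes capture variation but
leaves a global scale on `k_syn` that cancels in all relative metrics. In
ZZW, `beta` multiplies `k_syn` (an exact output multiplier leaving burst
frequency untouched); `u` multiplies `k_on`, the designed kinetic mode.

Deliberate scale choices (the package's own study conditions):

* **Genome**: 14,000 autosomal + 1,000 Z + 30 W genes, so chrZ holds a
  realistically small (~6–7%) share of each library. This matters:
  FPKM's total-count normalisation couples the sexes' Z copy numbers to
  every gene's FPKM, and an inflated Z share would depress the null M:F
  ratio visibly below 2. It also keeps the gene-sampling noise of Z-set
  medians (~1.25σ/√n) near 0.02 log.
* **Baseline expression**: lognormal per gene, σ_ln = 0.5. Narrower than
  real FPKM distributions; chosen so chromosome-median statistics at these
  panel sizes estimate their targets to ~2%, which is what the recovery
  experiments assert. Real data would need the bootstrap machinery (also
  provided) rather than raw medians.
* **Kinetic parameters**: lognormal with medians (k_on, k_off, k_syn) =
  (1, 6, 50) and log2 SDs (0.5, 0.4, 0.5), identical in law across
  chromosomes. Wide log-uniform parameter boxes are reserved for the pure
  recovery experiment; with them, the Z-vs-autosome *median* difference
  over a few hundred genes would be dominated by gene sampling (SD ≈ 0.19
  log2), not by biology or the estimator.
* **Reads**: abstract variant-overlap observations (2–4 informative
  variants per read, per-base error 0.005), not FASTQ/BAM; alignment is
  out of scope.

What passing tests do and do not show: the generator's noise is
well-specified (NB/beta-Poisson/lognormal, no batch effects, no
mapping bias, no gene-length bias beyond the FPKM model, no doublets or
ambient RNA), so recovery here demonstrates correctness of the estimators
and the pipeline plumbing — not robustness to real-data artefacts.

## Validation experiments and problem sizes

`zdose.validation` packages the recovery experiments the tests and
`scripts/acceptance.py` run: telegraph recovery (200 genes × 1000 cells,
log-uniform truth), the ZW kinetic-mode experiment (150 Z + 400 autosomal
genes, 500 cells, through QC/normalisation/fitting), 20-seed ZZ and ZZW
null arms at 30 Z + 80 autosomal genes × 300 cells (a Mann–Whitney null is
size-valid at any n; the smaller arms keep 20 replicates affordable),
bulk ratio calibrations at u ∈ {1, 1.27}, the τ = 1.2 translation-
efficiency recovery, the full multi-layer run, and the 100k-read
assignment-accuracy experiment. Sizes are stated in each function's
signature and were fixed from the power arithmetic above.

## Known limitations

* Kinetic inference assumes steady state and one telegraph per allele; no
  extrinsic noise, cell-cycle, or multi-state extensions.
* The second-pass "agreement" statistic and the bootstrap subsample size
  are under-specified in the published descriptions; the choices here
  (majority-of-reads; |target| without replacement) are documented and
  configurable, not asserted as the original computation.
* FPKM-based ratios inherit composition effects; the generator makes them
  small but they are not removed.
* The W chromosome is carried through annotation and counts but excluded
  from all Z-vs-autosome statistics.
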