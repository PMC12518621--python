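"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline touches — gene annotation, breed variant
callsets, abstract read observations at variant positions, bulk allelic
count matrices, allele-resolved single-cell UMI matrices with spike-ins,
ribosome-footprint counts and protein abundances — together with ground
truth for recovery tests. The dosage effects emulated are:

* female ZW cells upregulate their single Z allele (factor ``u`` on k_on,
  and on bulk output),
* triploid ZZW intersex shows autosomal buffering (per-copy multiplier
  ``beta``) but no Z-upregulation,
* Z genes in W-bearing genotypes translate more efficiently (factor ``tau``),
* miR-2954 represses RNA of target Z genes in ZZ males (factor ``rho``;
  sqrt(rho) in ZZW, matching the intermediate miR-2954 level there).

Counts are negative-binomial around their expectations for bulk-type
libraries and telegraph-model draws (with binomial capture and Poisson
spike-ins) for single cells. Identical (design, seed) pairs produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ALLELES, MICRO, AllelicCountMatrix, SimulationDesign, TelegraphParams

log = logging.getLogger(__name__)

LENGTH_RANGE_BP = (300, 30_000)
BASES = np.array(list("ACGT"))


@dataclass
class TruthBundle:
    """Ground truth threaded through the simulators for recovery tests."""

    true_params: pd.DataFrame | None = None
    true_read_alleles: pd.Series | None = None
    true_informative_variants: pd.Index | None = None
    true_te: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def write_truth_bundle(truth: TruthBundle, path) -> None:
    """Serialise the ground-truth bundle as JSON (tables as record lists)."""
    from .io import write_json

    payload = {}
    if truth.true_params is not None:
        payload["true_params"] = truth.true_params.to_dict(orient="records")
    if truth.true_read_alleles is not None:
        payload["true_read_alleles"] = truth.true_read_alleles.to_dict()
    if truth.true_informative_variants is not None:
        payload["true_informative_variants"] = list(truth.true_informative_variants)
    if truth.true_te is not None:
        payload["true_te"] = {c: truth.true_te[c].to_dict() for c in truth.true_te.columns}
    write_json(payload, path)


def _rng(design: SimulationDesign, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=design.seed, spawn_key=(salt,)))


# ---------------------------------------------------------------------------
# annotation


def make_annotation(design: SimulationDesign) -> pd.DataFrame:
    """Gene table: id, chromosome, coordinates, exonic length and flags.

    Lengths are log-uniform in [0.3 kb, 30 kb]; genes are laid out along each
    chromosome with fixed intergenic gaps. Flags (TATA box, initiator
    element, miR-2954 target, ancient paralog) are Bernoulli at the design
    rates, with the miR-target rate differing between Z and autosomes.
    """
    if design.n_genes_per_chrom.get("Z", 0) < 1:
        raise ValueError("a design without Z genes is meaningless for this pipeline")
    rng = _rng(design, 0)
    frames = []
    lo, hi = np.log(LENGTH_RANGE_BP[0]), np.log(LENGTH_RANGE_BP[1])
    for chrom in sorted(design.n_genes_per_chrom):
        n = design.n_genes_per_chrom[chrom]
        lengths = np.exp(rng.uniform(lo, hi, n)).astype(np.int64)
        mir_rate = design.mir_target_rate_z if chrom == "Z" else design.mir_target_rate_autosome
        # genes laid end to end with 1 kb intergenic gaps, 1-based inclusive
        ends = np.cumsum(lengths + 1000)
        starts = ends - lengths - 999
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": [f"g{chrom}_{i:04d}" for i in range(n)],
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + lengths - 1,
                    "exonic_length_bp": lengths,
                    "tata": rng.random(n) < design.tata_rate,
                    "inr": rng.random(n) < design.inr_rate,
                    "mir_target": rng.random(n) < mir_rate,
                    "ancient_paralog": rng.random(n) < design.ancient_paralog_rate,
                }
            )
        )
    ann = pd.concat(frames, ignore_index=True)
    if ann["gene_id"].duplicated().any():
        raise AssertionError("gene ids must be unique")
    return ann


def _is_autosome(chrom: pd.Series) -> pd.Series:
    return ~chrom.isin(("Z", "W"))


# ---------------------------------------------------------------------------
# telegraph sampling


def sample_telegraph_counts(params: TelegraphParams, n_cells: int, seed) -> np.ndarray:
    """Stationary telegraph-model counts: p ~ Beta(k_on, k_off), n ~ Pois(k_syn p).

    ``seed`` may be an integer or a ``numpy.random.Generator``. The
    k_syn = 0 boundary yields the all-zero vector.
    """
    k_on, k_off, k_syn = params
    if not np.all(np.isfinite([k_on, k_off, k_syn])):
        raise ValueError(f"non-finite telegraph parameters: {params}")
    if k_on <= 0 or k_off <= 0 or k_syn < 0:
        raise ValueError(f"rates must be positive (k_syn may be 0): {params}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k_syn == 0:
        return np.zeros(n_cells, dtype=np.int64)
    p = rng.beta(k_on, k_off, n_cells)
    return rng.poisson(k_syn * p).astype(np.int64)


# ---------------------------------------------------------------------------
# bulk RNA


def _copy_modifier(design: SimulationDesign, karyotype: str, chrom: str, mir_target, n_z: int) -> np.ndarray:
    """Per-copy expectation multiplier for one (genotype, chromosome) pair."""
    mod = np.ones(len(mir_target))
    if chrom == "Z":
        if karyotype == "ZW" and n_z == 1:
            mod *= design.u
        if karyotype == "ZZ":
            mod = np.where(mir_target, design.rho, 1.0) * mod
        if karyotype == "ZZW":
            mod = np.where(mir_target, np.sqrt(design.rho), 1.0) * mod
    elif chrom != "W" and karyotype == "ZZW":
        mod *= design.beta
    return mod


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam).astype(np.int64)


def baseline_rates(annotation: pd.DataFrame, design: SimulationDesign) -> pd.Series:
    """Per-copy expression rate per gene (lognormal across genes)."""
    rng = _rng(design, 1)
    return pd.Series(
        np.exp(rng.normal(0.0, design.baseline_log_sd, len(annotation))),
        index=annotation["gene_id"].to_numpy(),
        name="baseline",
    )


def simulate_bulk_experiment(
    annotation: pd.DataFrame, design: SimulationDesign
) -> tuple[AllelicCountMatrix, TruthBundle]:
    """Bulk allelic count matrix across the design's genotype panel.

    Per sample, gene and chromosome copy the expected output is
    baseline x (u if single-Z ZW) x (beta per ZZW autosomal copy) x
    (rho if miR-target Z gene in ZZ; sqrt(rho) in ZZW); counts are
    negative-binomial scaled to sequencing depth and exonic length, with
    technical replicates summed into each library. Allelic layers sum to the
    total layer exactly.
    """
    rng = _rng(design, 2)
    base = baseline_rates(annotation, design)
    genes = annotation["gene_id"].to_numpy()
    lengths = annotation["exonic_length_bp"].to_numpy(dtype=float)
    chroms = annotation["chrom"].to_numpy()
    mir = annotation["mir_target"].to_numpy()
    has_w_genes = (chroms == "W").any()

    layers = {k: pd.DataFrame(0, index=genes, columns=[g.sample_id for g in design.genotypes], dtype=np.int64)
              for k in ("total", "RJF", "WL", "unassigned")}
    meta_rows = []
    expected = {}
    disp = design.nb_dispersion / design.n_tech_reps
    for geno in design.genotypes:
        mu = np.zeros((len(genes), len(ALLELES)))  # per-origin expectation
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            if chrom == "Z":
                origins = geno.z_origins
            elif chrom == "W":
                origins = geno.w_origins
                if origins and not has_w_genes:
                    log.warning("%s carries W but annotation has no W genes; W layer dropped", geno.sample_id)
                    continue
            else:
                origins = geno.autosome_origins
            if not origins:
                continue
            mod = _copy_modifier(design, geno.karyotype, chrom, mir[sel], len(geno.z_origins))
            per_copy = base.to_numpy()[sel] * mod
            for origin in origins:
                mu[sel, ALLELES.index(origin)] += per_copy
        rate = mu * lengths[:, None]
        scale = design.depth * design.n_tech_reps / rate.sum()
        counts = _nb_draw(rng, rate * scale, disp)
        layers["RJF"][geno.sample_id] = counts[:, 0]
        layers["WL"][geno.sample_id] = counts[:, 1]
        layers["total"][geno.sample_id] = counts.sum(axis=1)
        expected[geno.sample_id] = pd.DataFrame(
            rate * scale, index=genes, columns=list(ALLELES)
        )
        meta_rows.append(
            {"unit": geno.sample_id, "sample_id": geno.sample_id,
             "karyotype": geno.karyotype, "sex": geno.sex}
        )
    meta = pd.DataFrame(meta_rows).set_index("unit")
    matrix = AllelicCountMatrix(layers, meta)
    truth = TruthBundle(extra={"expected_counts": expected, "baseline": base})
    return matrix, truth


# ---------------------------------------------------------------------------
# single-cell with spike-ins


def _kinetic_table(annotation: pd.DataFrame, design: SimulationDesign) -> pd.DataFrame:
    """Gene-level telegraph parameters, lognormal around the design medians.

    The log2 spreads are moderate so that chromosome-level medians over a
    few hundred genes are stable; every chromosome draws from the same law,
    making Z-vs-autosome contrasts null except for the designed effects.
    """
    rng = _rng(design, 3)
    n = len(annotation)
    ln2 = np.log(2.0)

    def ln(median, log2_sd):
        return np.exp(rng.normal(np.log(median), log2_sd * ln2, n))

    meds, sds = design.kinetic_medians, design.kinetic_log2_sds
    return pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "chrom": annotation["chrom"].to_numpy(),
            "mir_target": annotation["mir_target"].to_numpy(),
            "k_on": ln(meds[0], sds[0]),
            "k_off": ln(meds[1], sds[1]),
            "k_syn": ln(meds[2], sds[2]),
        }
    )


def _effective_params(
    kin: pd.DataFrame, design: SimulationDesign, karyotype: str, chrom_mask: dict
) -> dict:
    """Per-copy effective (k_on, k_syn) modifiers for one genotype."""
    k_on = kin["k_on"].to_numpy().copy()
    k_syn = kin["k_syn"].to_numpy().copy()
    z = chrom_mask["Z"]
    auto = chrom_mask["autosome"]
    mir = kin["mir_target"].to_numpy()
    if karyotype == "ZW":
        k_on = np.where(z, k_on * design.u, k_on)
    if karyotype == "ZZ":
        k_syn = np.where(z & mir, k_syn * design.rho, k_syn)
    if karyotype == "ZZW":
        k_syn = np.where(z & mir, k_syn * np.sqrt(design.rho), k_syn)
        k_syn = np.where(auto, k_syn * design.beta, k_syn)
    return {"k_on": k_on, "k_syn": k_syn}


def simulate_sc_experiment(
    annotation: pd.DataFrame, design: SimulationDesign
) -> tuple[AllelicCountMatrix, pd.DataFrame, TruthBundle]:
    """Allele-resolved single-cell UMI counts plus spike-in UMIs.

    Every chromosome copy bursts independently under its telegraph
    parameters (ZW single-Z k_on multiplied by ``u``); true molecule counts
    are thinned binomially by a per-cell capture efficiency, spike UMIs are
    Poisson with the same capture factor, and a configurable fraction of
    cells is rendered QC-failing (strongly reduced endogenous capture, hence
    low gene detection and high spike fraction).

    Returns the cell matrix, a spikes x cells count table (with per-spike
    barcode/sequence metadata attached via ``attrs['spike_meta']``), and the
    truth bundle holding the per-sample effective kinetic parameters.
    """
    if design.n_cells < 50:
        raise ValueError("need >= 50 cells per sample for kinetics downstream")
    rng = _rng(design, 4)
    kin = _kinetic_table(annotation, design)
    genes = kin["gene_id"].to_numpy()
    chroms = kin["chrom"].to_numpy()
    mask = {"Z": chroms == "Z", "W": chroms == "W", "autosome": ~np.isin(chroms, ("Z", "W"))}

    spike_mu = np.exp(rng.normal(0.0, 1.0, design.n_spikes))
    spike_mu *= design.spike_mean_total / spike_mu.sum() if design.n_spikes else 1.0
    spike_ids = [f"spike_{i:03d}" for i in range(design.n_spikes)]
    # a couple of overrepresented spike species (to be dropped by QC downstream)
    n_bad = min(2, design.n_spikes // 10)
    spike_meta = pd.DataFrame(
        {
            "spike_id": spike_ids,
            "n_barcodes": [8 if i < n_bad else 1 for i in range(design.n_spikes)],
            "n_sequences": [150 if i < n_bad else 40 for i in range(design.n_spikes)],
        }
    ).set_index("spike_id")

    cell_cols, meta_rows = [], []
    layer_arrays = {k: [] for k in ("total", "RJF", "WL", "unassigned")}
    spike_arrays = []
    truth_rows = []
    mu_cap = np.log(design.capture_mean) - design.capture_log_sd**2 / 2
    for geno in design.genotypes:
        eff = _effective_params(kin, design, geno.karyotype, mask)
        n_c = design.n_cells
        capture = np.clip(rng.lognormal(mu_cap, design.capture_log_sd, n_c), 0.02, 1.0)
        fail = rng.random(n_c) < design.qc_fail_frac
        endo_capture = np.where(fail, capture * 0.03, capture)

        per_origin = {a: np.zeros((len(genes), n_c), dtype=np.int64) for a in ALLELES}
        copies = []
        for chrom_kind, origins in (("Z", geno.z_origins), ("W", geno.w_origins), ("autosome", geno.autosome_origins)):
            for origin in origins:
                copies.append((chrom_kind, origin))
        for chrom_kind, origin in copies:
            sel = mask[chrom_kind]
            if not sel.any():
                continue
            k_on = eff["k_on"][sel][:, None]
            k_off = kin["k_off"].to_numpy()[sel][:, None]
            k_syn = eff["k_syn"][sel][:, None]
            p = rng.beta(np.broadcast_to(k_on, (sel.sum(), n_c)), np.broadcast_to(k_off, (sel.sum(), n_c)))
            true_mol = rng.poisson(k_syn * p)
            obs = rng.binomial(true_mol, endo_capture[None, :])
            per_origin[origin][sel] += obs
        for a in ALLELES:
            layer_arrays[a].append(per_origin[a])
        total = per_origin["RJF"] + per_origin["WL"]
        layer_arrays["total"].append(total)
        layer_arrays["unassigned"].append(np.zeros_like(total))
        spike_arrays.append(rng.poisson(spike_mu[:, None] * capture[None, :]))

        cols = [f"{geno.sample_id}:c{i:04d}" for i in range(n_c)]
        cell_cols.extend(cols)
        for i, col in enumerate(cols):
            meta_rows.append(
                {"unit": col, "sample_id": geno.sample_id, "karyotype": geno.karyotype,
                 "sex": geno.sex, "capture": capture[i], "qc_fail_truth": bool(fail[i])}
            )
        seen = set()
        for chrom_kind, origin in copies:
            if (chrom_kind, origin) in seen:
                continue
            seen.add((chrom_kind, origin))
            sel = mask[chrom_kind]
            for j in np.flatnonzero(sel):
                truth_rows.append(
                    {
                        "sample_id": geno.sample_id,
                        "gene_id": genes[j],
                        "allele": origin,
                        "k_on": eff["k_on"][j],
                        "k_off": kin["k_off"].to_numpy()[j],
                        "k_syn": eff["k_syn"][j],
                        "n_copies": sum(1 for c in copies if c == (chrom_kind, origin)),
                    }
                )

    layers = {
        k: pd.DataFrame(np.concatenate(v, axis=1), index=genes, columns=cell_cols, dtype=np.int64)
        for k, v in layer_arrays.items()
    }
    meta = pd.DataFrame(meta_rows).set_index("unit")
    matrix = AllelicCountMatrix(layers, meta)
    spikes = pd.DataFrame(
        np.concatenate(spike_arrays, axis=1) if spike_arrays else np.zeros((0, len(cell_cols))),
        index=spike_ids, columns=cell_cols, dtype=np.int64,
    )
    spikes.attrs["spike_meta"] = spike_meta
    truth = TruthBundle(true_params=pd.DataFrame(truth_rows), extra={"kinetics": kin})
    return matrix, spikes, truth


# ---------------------------------------------------------------------------
# ribosome footprints and protein


def simulate_ribo_protein(
    annotation: pd.DataFrame,
    design: SimulationDesign,
    bulk_truth: TruthBundle,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Ribosome-footprint CDS counts and protein abundances matched to bulk RNA.

    The footprint expectation is the RNA expectation times a gene-level base
    translation efficiency, boosted by ``tau`` for Z genes in W-bearing
    genotypes, with negative-binomial noise; protein abundance is RNA x TE
    with lognormal noise, restricted to a detectable subset of genes.
    """
    if "expected_counts" not in bulk_truth.extra:
        raise ValueError("bulk truth bundle with expected counts required")
    rng = _rng(design, 5)
    genes = annotation["gene_id"].to_numpy()
    z_mask = (annotation["chrom"] == "Z").to_numpy()
    base_te = np.exp(rng.normal(0.0, design.base_te_log_sd, len(genes)))
    disp = design.nb_dispersion / design.n_tech_reps

    samples = [g.sample_id for g in design.genotypes]
    karyo = {g.sample_id: g.karyotype for g in design.genotypes}
    ribo = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    prot = pd.DataFrame(0.0, index=genes, columns=samples)
    true_te = pd.DataFrame(0.0, index=genes, columns=samples)
    for s in samples:
        rna_mean = bulk_truth.extra["expected_counts"][s].sum(axis=1).to_numpy()
        te = base_te.copy()
        if karyo[s] in ("ZW", "ZZW"):
            te = np.where(z_mask, te * design.tau, te)
        true_te[s] = te
        ribo_mean = rna_mean * te
        ribo_mean *= rna_mean.sum() / ribo_mean.sum()  # equal footprint depth
        ribo[s] = _nb_draw(rng, ribo_mean, disp)
        abundance = rna_mean * te * rng.lognormal(0.0, design.protein_noise_log_sd, len(genes))
        prot[s] = abundance / abundance.sum()
    # detectable set: most abundant fraction on average
    mean_ab = prot.mean(axis=1)
    cutoff = mean_ab.quantile(1.0 - design.protein_detect_frac)
    detected = mean_ab[mean_ab > cutoff].index
    prot = prot.loc[detected]
    truth = TruthBundle(true_te=true_te, extra={"base_te": pd.Series(base_te, index=genes)})
    return ribo, prot, truth


# ---------------------------------------------------------------------------
# variants and abstract reads


def simulate_variant_calls(
    annotation: pd.DataFrame, design: SimulationDesign
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Breed callsets (WL and RJF) whose set relations define the informative set.

    Informative variants are unique to WL (WL carries the alternate base);
    common variants appear in both callsets; each callset also carries
    records that fail the first-pass filter (low depth / allele frequency /
    quality) so filtering has something to do.
    """
    rng = _rng(design, 6)
    rows_wl, rows_rjf = [], []
    truth_keys = []
    for _, g in annotation.iterrows():
        n_var = rng.poisson(design.variant_density * g.exonic_length_bp / 1000.0)
        if n_var == 0:
            continue
        pos = np.sort(rng.choice(np.arange(g.start, g.end + 1), size=min(n_var, g.exonic_length_bp), replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt = BASES[ref], BASES[alt]
            kind = rng.random()
            good = rng.random() > 0.1  # 10% of candidate records fail first pass
            depth = int(6 + rng.poisson(20)) if good else int(rng.integers(0, 6))
            af = float(rng.uniform(0.75, 1.0)) if good else float(rng.uniform(0.05, 0.5))
            qual = float(rng.uniform(15, 60)) if good else float(rng.uniform(0, 10))
            rec = {"chrom": g.chrom, "pos": int(p), "ref": ref, "alt": alt,
                   "qual": qual, "depth": depth, "af": af, "gene_id": g.gene_id}
            if kind < 0.6:  # unique WL
                rows_wl.append({**rec, "source": "WL"})
                if good:
                    truth_keys.append(f"{g.chrom}:{p}:{ref}:{alt}")
            elif kind < 0.85:  # common to both breeds
                rows_wl.append({**rec, "source": "WL"})
                rows_rjf.append({**rec, "source": "RJF"})
            else:  # RJF-private
                rows_rjf.append({**rec, "source": "RJF"})
    wl = pd.DataFrame(rows_wl)
    rjf = pd.DataFrame(rows_rjf)
    truth = TruthBundle(true_informative_variants=pd.Index(truth_keys, name="variant_key"))
    return wl, rjf, truth


def simulate_reads_at_variants(
    design: SimulationDesign,
    truth: TruthBundle,
    variant_table: pd.DataFrame,
    n_reads: int,
    seed_salt: int = 7,
    panel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Abstract reads with basecalls at informative variant positions.

    Each read originates from one allele of one gene and covers 1..k
    informative variants of that gene; a basecall matches the generating
    allele with probability 1 - base_error and otherwise shows the other
    allele's base. Returned in tidy (one row per basecall) form with columns
    read_id, gene_id, unit_id, variant_key, base.

    By default reads are F1-hybrid (units are the design's genotypes, the
    generating allele a fair coin). A ``panel`` table with columns
    unit_id / breed [/ sex] instead emulates pure-breed samples whose reads
    all originate from the panel breed, as used by the second-pass
    concordance quantification.
    """
    rng = _rng(design, seed_salt)
    informative = truth.true_informative_variants
    vt = variant_table.copy()
    vt["variant_key"] = (
        vt["chrom"].astype(str) + ":" + vt["pos"].astype(str) + ":" + vt["ref"] + ":" + vt["alt"]
    )
    vt = vt[vt["variant_key"].isin(informative)]
    by_gene = {
        g: (sub["variant_key"].to_numpy(), sub["ref"].to_numpy(), sub["alt"].to_numpy())
        for g, sub in vt.groupby("gene_id")
        if len(sub) > 0
    }
    genes = sorted(by_gene)
    if not genes:
        raise ValueError("no genes carry informative variants at this density")
    if panel is not None:
        units = list(panel["unit_id"])
        unit_breed = list(panel["breed"])
    else:
        units = [g.sample_id for g in design.genotypes] or ["sample_0"]
        unit_breed = None
    lo, hi = design.variants_per_read

    gene_pick = rng.choice(len(genes), size=n_reads)
    unit_pick = rng.choice(len(units), size=n_reads)
    if unit_breed is None:
        allele_pick = rng.choice(len(ALLELES), size=n_reads)
    else:
        allele_pick = np.array([ALLELES.index(unit_breed[u]) for u in unit_pick])
    k_pick = rng.integers(lo, hi + 1, size=n_reads)
    col_read, col_gene, col_unit, col_key, col_base = [], [], [], [], []
    truth_alleles = np.empty(n_reads, dtype=object)
    read_ids = np.array([f"r{i:07d}" for i in range(n_reads)])
    for i in range(n_reads):
        g = genes[gene_pick[i]]
        keys, refs, alts = by_gene[g]
        k = min(int(k_pick[i]), len(keys))
        idx = rng.choice(len(keys), size=k, replace=False)
        allele = ALLELES[allele_pick[i]]
        truth_alleles[i] = allele
        own, other = (alts, refs) if allele == "WL" else (refs, alts)
        flip = rng.random(k) < design.base_error
        bases = np.where(flip, other[idx], own[idx])
        col_read.extend([read_ids[i]] * k)
        col_gene.extend([g] * k)
        col_unit.extend([units[unit_pick[i]]] * k)
        col_key.extend(keys[idx])
        col_base.extend(bases)
    reads = pd.DataFrame(
        {"read_id": col_read, "gene_id": col_gene, "unit_id": col_unit,
         "variant_key": col_key, "base": col_base}
    )
    truth_out = TruthBundle(
        true_read_alleles=pd.Series(truth_alleles, index=pd.Index(read_ids, name="read_id"), name="true_allele"),
        true_informative_variants=informative,
    )
    return reads, truth_out
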