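"""Dosage-compensation statistics.

FPKM and expression masks, spike-in size-factor normalisation with cell QC,
per-gene Male:Female ratios and per-sample Z:autosome ratios, the
gene-subsampling bootstrap median test, bootstrap percentile CIs, the
translation-efficiency index (footprint FPKM / RNA FPKM), grouped-ratio
contrasts (miR-2954 targets, promoter elements), observed/expected motif
enrichment, and the cross-modality chromosome summary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, median_abs_deviation, spearmanr, wilcoxon

from .types import TestResult

log = logging.getLogger(__name__)

PSEUDOCOUNT_FPKM = 0.01


# ---------------------------------------------------------------------------
# normalisation layers


def fpkm(counts: pd.DataFrame, exonic_length_bp: pd.Series, library_size: pd.Series | None = None) -> pd.DataFrame:
    """FPKM(g, u) = counts * 1e9 / (length_bp * library_size).

    Library size defaults to the per-unit sum of gene counts; units with a
    zero library are dropped with a log line.
    """
    lengths = exonic_length_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exonic length")
    if library_size is None:
        library_size = counts.sum(axis=0)
    zero = library_size <= 0
    if zero.any():
        log.warning("dropping %d units with zero library size", int(zero.sum()))
        counts = counts.loc[:, ~zero]
        library_size = library_size[~zero]
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_size.to_numpy())


def expressed_mask(
    fpkm_layer: pd.DataFrame,
    threshold: float = 1.0,
    scope: pd.Series | None = None,
) -> pd.Series:
    """Genes with mean FPKM strictly above ``threshold``.

    ``scope`` may map units to groups (e.g. tissues); the gene is then kept
    when its within-group average exceeds the threshold in every group.
    """
    if scope is None:
        return fpkm_layer.mean(axis=1) > threshold
    groups = fpkm_layer.T.groupby(pd.Series(scope)).mean().T
    return (groups > threshold).all(axis=1)


def drop_overrepresented_spikes(
    spikes: pd.DataFrame,
    spike_meta: pd.DataFrame | None = None,
    max_barcodes: int = 5,
    max_sequences: int = 100,
) -> pd.DataFrame:
    """Remove spike species flagged overrepresented (>5 barcodes or >100 sequences)."""
    if spike_meta is None:
        spike_meta = spikes.attrs.get("spike_meta")
    if spike_meta is None:
        return spikes
    meta = spike_meta.reindex(spikes.index)
    bad = (meta["n_barcodes"] > max_barcodes) | (meta["n_sequences"] > max_sequences)
    if bad.any():
        log.info("dropping %d overrepresented spike species", int(bad.sum()))
    out = spikes.loc[~bad.fillna(False)]
    out.attrs["spike_meta"] = spike_meta
    return out


def sc_cell_qc(
    counts: pd.DataFrame,
    spikes: pd.DataFrame,
    max_spike_fraction: float = 0.10,
    gene_mads: float = 3.0,
    count_mads: float = 5.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cell mask: spike fraction < 10%, then low-tail MAD outlier removal.

    Cells are kept when spike reads are under 10% of the total, then
    excluded when log gene detection falls more than 3 MADs, or log read
    count more than 5 MADs, below the respective median (one-sided, low
    tail, normal-consistent MAD). Returns (kept mask, per-cell QC report).
    """
    if not counts.columns.equals(spikes.columns):
        raise ValueError("endogenous and spike matrices must share cells")
    endo_total = counts.sum(axis=0)
    spike_total = spikes.sum(axis=0)
    spike_frac = spike_total / (spike_total + endo_total).replace(0, np.nan)
    keep = spike_frac.fillna(1.0) < max_spike_fraction

    report = pd.DataFrame(
        {"n_genes": (counts > 0).sum(axis=0), "n_reads": endo_total, "spike_fraction": spike_frac}
    )
    report["fail_spike_fraction"] = ~keep
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} cells failed the spike-fraction gate "
            f"(median spike fraction {float(spike_frac.median()):.3f})"
        )

    def low_outlier(values: pd.Series, n_mads: float) -> pd.Series:
        x = np.log1p(values[keep].astype(float))
        med = x.median()
        mad = median_abs_deviation(x, scale="normal")
        if mad == 0:
            return pd.Series(False, index=values.index)
        return pd.Series(np.log1p(values.astype(float)) < med - n_mads * mad, index=values.index)

    report["fail_gene_detection"] = low_outlier(report["n_genes"], gene_mads) & keep
    report["fail_read_count"] = low_outlier(report["n_reads"], count_mads) & keep
    kept = keep & ~report["fail_gene_detection"] & ~report["fail_read_count"]
    report["kept"] = kept
    if not kept.any():
        raise ValueError(f"all {len(kept)} cells failed QC:\n{report.sum(numeric_only=True)}")
    log.info("cell QC: %d/%d cells kept", int(kept.sum()), len(kept))
    return kept, report


def spike_size_factors(
    spikes: pd.DataFrame, qc_mask: pd.Series | None = None
) -> pd.Series:
    """Per-cell size factor: total spike UMIs scaled to unit mean over kept cells."""
    if qc_mask is not None:
        spikes = spikes.loc[:, qc_mask[qc_mask].index]
    totals = spikes.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"kept cells with zero spike UMIs (QC should have removed them): {bad[:5]}")
    factors = totals / totals.mean()
    factors.name = "size_factor"
    return factors


def normalize_by_spikes(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """counts(g, c) / factor(c) over the cells covered by the factors."""
    return counts.loc[:, factors.index] / factors


# ---------------------------------------------------------------------------
# ratio tables


def sex_ratio_per_gene(
    expr: pd.DataFrame,
    sex_labels: pd.Series,
    mask: pd.Series | None = None,
    numerator: str = "male",
    denominator: str = "female",
    pseudocount: float = PSEUDOCOUNT_FPKM,
) -> pd.Series:
    """Per-gene expression ratio between sex groups (means + pseudocount)."""
    sexes = sex_labels.reindex(expr.columns)
    for grp in (numerator, denominator):
        if not (sexes == grp).any():
            raise ValueError(f"no units labelled {grp!r}")
    num = expr.loc[:, sexes[sexes == numerator].index].mean(axis=1)
    den = expr.loc[:, sexes[sexes == denominator].index].mean(axis=1)
    ratio = (num + pseudocount) / (den + pseudocount)
    if mask is not None:
        ratio = ratio[mask.reindex(ratio.index).fillna(False)]
    ratio.name = f"{numerator}:{denominator}"
    return ratio


def chromosome_medians(ratio: pd.Series, annotation: pd.DataFrame) -> pd.DataFrame:
    chrom = annotation.set_index("gene_id")["chrom"].reindex(ratio.index)
    out = ratio.groupby(chrom).agg(["median", "size"])
    out.columns = ["median", "n_genes"]
    return out


def z_to_autosome_ratio(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    mask: pd.Series | None = None,
    min_genes: int = 50,
) -> pd.Series:
    """Per-unit Z:AA value: median FPKM of Z genes over median of autosomal genes."""
    chrom = annotation.set_index("gene_id")["chrom"].reindex(expr.index)
    sub = expr if mask is None else expr.loc[mask.reindex(expr.index).fillna(False)]
    chrom = chrom.reindex(sub.index)
    z = sub[chrom == "Z"]
    auto = sub[~chrom.isin(("Z", "W"))]
    out = {}
    for unit in sub.columns:
        if len(z) < min_genes or len(auto) < min_genes:
            log.warning("unit %s skipped: <%d expressed genes on Z or autosomes", unit, min_genes)
            continue
        out[unit] = float(z[unit].median() / auto[unit].median())
    return pd.Series(out, name="Z:AA")


# ---------------------------------------------------------------------------
# resampling


def bootstrap_median_test(
    target_values,
    background_values,
    n_draws: int = 100_000,
    tail: str = "greater",
    seed: int = 0,
    replacement: bool = False,
    min_target: int = 5,
) -> TestResult:
    """One-tailed subsampling test of a gene-set median against a background.

    Draws |target| genes from the background ``n_draws`` times (without
    replacement by default) and compares null medians against the observed
    target median; p = (1 + #extreme) / (n_draws + 1), ties counting as
    extreme. The caller must declare the tail; it is never inferred.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    target = np.asarray(target_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    k, n = target.size, background.size
    if k < min_target:
        raise ValueError(f"need at least {min_target} target values")
    if n <= k and not replacement:
        raise ValueError("background must be larger than the target set")
    observed = float(np.median(target))
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_draws)
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        if replacement:
            idx = rng.integers(0, n, size=(b, k))
            nulls[done : done + b] = np.median(background[idx], axis=1)
        else:
            keys = rng.random((b, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            nulls[done : done + b] = np.median(background[idx], axis=1)
        done += b
    extreme = int((nulls >= observed).sum() if tail == "greater" else (nulls <= observed).sum())
    p = (1 + extreme) / (n_draws + 1)
    return TestResult(
        name="bootstrap_median",
        observed=observed,
        p_value=p,
        method="bootstrap_median",
        ci_low=float(np.percentile(nulls, 2.5)),
        ci_high=float(np.percentile(nulls, 97.5)),
        null_size=n_draws,
        null_mean=float(nulls.mean()),
        tail_count=extreme,
        extra={"tail": tail, "target_size": k},
    )


def percentile_ci(
    values, statistic=np.median, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Bootstrap percentile CI of a statistic (resampling with replacement)."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    stats = np.asarray([statistic(x[row]) for row in idx])
    alpha = 100 * (1 - level) / 2
    return float(np.percentile(stats, alpha)), float(np.percentile(stats, 100 - alpha))


# ---------------------------------------------------------------------------
# translation efficiency


def translation_index(
    rpf_fpkm: pd.DataFrame,
    rna_fpkm: pd.DataFrame,
    rpf_threshold: float = 1.0,
    rna_threshold: float = 1.0,
) -> pd.DataFrame:
    """TE(g, u) = RPF FPKM / RNA FPKM for expressed genes.

    Genes must pass mean RPF FPKM > 1 AND mean RNA FPKM > 1 (strict) on the
    shared gene x sample grid.
    """
    genes = rpf_fpkm.index.intersection(rna_fpkm.index)
    samples = rpf_fpkm.columns.intersection(rna_fpkm.columns)
    rpf = rpf_fpkm.loc[genes, samples]
    rna = rna_fpkm.loc[genes, samples]
    keep = (rpf.mean(axis=1) > rpf_threshold) & (rna.mean(axis=1) > rna_threshold)
    return rpf.loc[keep] / rna.loc[keep]


def te_ratio_tests(
    te: pd.DataFrame,
    sex_labels: pd.Series,
    annotation: pd.DataFrame,
    pseudocount: float = 0.0,
) -> dict:
    """Female:Male (and Intersex:Male when present) per-gene TE ratios with
    a two-tailed chrZ-vs-chrA Mann-Whitney per contrast."""
    sexes = sex_labels.reindex(te.columns)
    chrom = annotation.set_index("gene_id")["chrom"].reindex(te.index)
    males = sexes[sexes == "male"].index
    if len(males) == 0:
        raise ValueError("no male samples for TE ratios")
    out = {}
    for label, group in (("F:M", "female"), ("I:M", "intersex")):
        units = sexes[sexes == group].index
        if len(units) == 0:
            log.info("no %s samples; %s TE comparison skipped", group, label)
            continue
        ratio = (te[units].mean(axis=1) + pseudocount) / (te[males].mean(axis=1) + pseudocount)
        rz = ratio[chrom == "Z"].dropna()
        ra = ratio[~chrom.isin(("Z", "W"))].dropna()
        mw = mannwhitneyu(rz, ra, alternative="two-sided")
        out[label] = {
            "ratio": ratio,
            "median_z": float(rz.median()),
            "median_autosome": float(ra.median()),
            "p_value": float(mw.pvalue),
            "n_z": int(len(rz)),
            "n_autosome": int(len(ra)),
        }
    return out


# ---------------------------------------------------------------------------
# grouped contrasts


def group_ratio_test(
    ratio: pd.Series,
    annotation: pd.DataFrame,
    flag: str,
    within_chrom: str | None = None,
) -> TestResult:
    """Two-sided Mann-Whitney of ratios between flagged and unflagged genes.

    ``flag`` is one of the annotation's boolean columns (mir_target, tata,
    inr, ancient_paralog); ``within_chrom`` restricts the scope ("Z",
    "autosome" or a chromosome label).
    """
    ann = annotation.set_index("gene_id")
    genes = ratio.index.intersection(ann.index)
    r = ratio.loc[genes]
    sub = ann.loc[genes]
    if within_chrom == "autosome":
        sel = ~sub["chrom"].isin(("Z", "W"))
    elif within_chrom is not None:
        sel = sub["chrom"] == within_chrom
    else:
        sel = pd.Series(True, index=sub.index)
    r = r[sel]
    flags = sub.loc[sel, flag].astype(bool)
    a, b = r[flags], r[~flags]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"both {flag} groups must be non-empty within scope {within_chrom!r}")
    mw = mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        name=f"{flag}_ratio_{within_chrom or 'all'}",
        observed=float(a.median()),
        p_value=float(mw.pvalue),
        method="mann_whitney",
        extra={
            "median_flagged": float(a.median()),
            "median_unflagged": float(b.median()),
            "n_flagged": int(len(a)),
            "n_unflagged": int(len(b)),
        },
    )


def promoter_kinetics_association(
    fits: pd.DataFrame, annotation: pd.DataFrame, min_fits: int = 100
) -> pd.DataFrame:
    """Association of core-promoter elements with burst kinetics.

    For each element flag (TATA, Inr) x metric (log burst size, log burst
    frequency): Spearman rank correlation of the binary flag with the metric,
    group medians and a Mann-Whitney p; plus the TATA+Inr vs TATA-only
    additive contrast on each metric. Constant flags are reported as missing.
    """
    conv = fits[fits["status"] == "converged"]
    if len(conv) < min_fits:
        raise ValueError(f"need >= {min_fits} converged fits, have {len(conv)}")
    ann = annotation.set_index("gene_id")
    merged = conv.join(ann[["tata", "inr"]], on="gene_id").dropna(subset=["tata", "inr"])
    rows = []
    for flag in ("tata", "inr"):
        f = merged[flag].astype(bool)
        for metric in ("burst_size", "burst_frequency"):
            x = np.log(merged[metric].to_numpy())
            if f.nunique() < 2:
                rows.append({"flag": flag, "metric": metric, "rho": np.nan, "p_value": np.nan,
                             "median_flagged": np.nan, "median_unflagged": np.nan, "note": "constant flag"})
                continue
            rho, p_s = spearmanr(f.to_numpy().astype(int), x)
            mw = mannwhitneyu(x[f], x[~f], alternative="two-sided")
            rows.append(
                {"flag": flag, "metric": metric, "rho": float(rho), "p_value": float(mw.pvalue),
                 "median_flagged": float(np.median(x[f])), "median_unflagged": float(np.median(x[~f])),
                 "note": ""}
            )
    both = merged["tata"].astype(bool) & merged["inr"].astype(bool)
    tata_only = merged["tata"].astype(bool) & ~merged["inr"].astype(bool)
    for metric in ("burst_size", "burst_frequency"):
        x = np.log(merged[metric].to_numpy())
        if both.sum() >= 5 and tata_only.sum() >= 5:
            mw = mannwhitneyu(x[both], x[tata_only], alternative="two-sided")
            rows.append(
                {"flag": "tata+inr_vs_tata", "metric": metric, "rho": np.nan,
                 "p_value": float(mw.pvalue),
                 "median_flagged": float(np.median(x[both])),
                 "median_unflagged": float(np.median(x[tata_only])), "note": "additive contrast"}
            )
    return pd.DataFrame(rows)


def oe_enrichment(motif_counts: pd.Series, effective_lengths: pd.Series) -> pd.Series:
    """Observed/expected motif density per chromosome.

    O/E(chrom) = (count/length) / (sum(counts)/sum(lengths)), over
    non-N-masked base counts; zero-length chromosomes are excluded.
    """
    lengths = effective_lengths.reindex(motif_counts.index)
    ok = lengths > 0
    if (~ok).any():
        log.warning("excluding %d zero-length chromosomes from O/E", int((~ok).sum()))
    counts, lengths = motif_counts[ok], lengths[ok]
    genome_rate = counts.sum() / lengths.sum()
    out = (counts / lengths) / genome_rate
    out.name = "oe"
    return out


def modality_summary(
    ratio_tables: dict,
    annotation: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    rna_key: str = "RNA",
    protein_key: str = "protein",
) -> tuple[pd.DataFrame, TestResult | None]:
    """Chromosome-Z median M:F ratio with percentile CI per modality.

    ``ratio_tables`` maps modality name (ATAC, RNA, Ribo, protein) to a
    per-gene M:F ratio Series. When RNA and protein are both present, the
    per-gene protein ratios are additionally compared against the RNA-level
    chrZ median with a one-sample Wilcoxon test.
    """
    chrom = annotation.set_index("gene_id")["chrom"]
    rows = []
    rng = np.random.default_rng(seed)
    z_values = {}
    for modality in sorted(ratio_tables):
        ratio = ratio_tables[modality]
        z = ratio[chrom.reindex(ratio.index) == "Z"].dropna()
        z_values[modality] = z
        lo, hi = percentile_ci(z, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)))
        rows.append(
            {"modality": modality, "chrZ_median": float(z.median()),
             "ci_low": lo, "ci_high": hi, "n_genes": int(len(z))}
        )
    table = pd.DataFrame(rows)
    test = None
    if rna_key in z_values and protein_key in z_values and len(z_values[protein_key]) >= 5:
        rna_median = float(z_values[rna_key].median())
        diffs = z_values[protein_key] - rna_median
        w = wilcoxon(diffs[diffs != 0])
        test = TestResult(
            name="protein_vs_rna_chrZ",
            observed=float(z_values[protein_key].median()),
            p_value=float(w.pvalue),
            method="wilcoxon_1sample",
            extra={"rna_chrZ_median": rna_median, "n": int(len(diffs))},
        )
    return table, test


def bh_adjust(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values for gene-level screens."""
    from scipy.stats import false_discovery_control

    out = pd.Series(false_discovery_control(p_values.to_numpy(), method="bh"), index=p_values.index)
    out.name = "q_value"
    return out
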