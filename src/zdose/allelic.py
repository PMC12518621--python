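"""Allele-informative variant derivation and read-to-allele assignment.

The two-pass procedure: breed callsets are filtered on strict depth /
allele-frequency / quality cutoffs, WL-unique and RJF-common sets are
derived by set algebra on (chrom, pos, ref, alt) keys, a second pass drops
variants whose reads disagree with the expected breed allele in fewer than
half of the males or females, and hemizygous-Z records are phased against
female genotypes (REF/ALT flipped when the single female allele is the one
labelled opposite to the expected breed). Reads are then assigned to the
breed whose allele matches more than 0.66 of their basecalls — the
inequalities are strict everywhere (depth = 5 fails, agreement = 0.5 is
kept, a 0.66 match fraction stays unassigned).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ALLELES, AllelicCountMatrix

log = logging.getLogger(__name__)

KEY_COLS = ("chrom", "pos", "ref", "alt")
MATCH_THRESHOLD = 0.66
REQUIRED_FIELDS = ("depth", "af", "qual")


def variant_key(df: pd.DataFrame) -> pd.Series:
    """Canonical '<chrom>:<pos>:<ref>:<alt>' key for a variant table."""
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
    )


def first_pass_variant_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep records with depth > 5 AND af > 0.5 AND qual > 10 (all strict).

    Records missing any of the three fields are rejected with a logged count.
    Idempotent: a second application changes nothing.
    """
    if variants.empty:
        return variants.copy()
    missing = variants[list(REQUIRED_FIELDS)].isna().any(axis=1)
    if missing.any():
        log.info("first-pass filter: %d records rejected for missing fields", int(missing.sum()))
    v = variants[~missing]
    keep = (v["depth"] > 5) & (v["af"] > 0.5) & (v["qual"] > 10)
    out = v[keep].copy()
    log.info("first-pass filter: %d -> %d records", len(variants), len(out))
    return out


def _dedup(df: pd.DataFrame, label: str) -> pd.DataFrame:
    if df.empty:
        return df
    keys = variant_key(df)
    dup = keys.duplicated()
    if dup.any():
        log.warning("%s callset: %d duplicate variant keys removed", label, int(dup.sum()))
    return df[~dup]


def informative_variant_sets(wl: pd.DataFrame, rjf: pd.DataFrame) -> dict:
    """Partition the WL callset into WL-unique and RJF-common variants.

    unique_wl = wl \\ rjf and common_rjf = wl intersect rjf on the
    (chrom, pos, ref, alt) key; the two sets are disjoint and cover wl.
    """
    wl = _dedup(wl, "WL")
    rjf = _dedup(rjf, "RJF")
    if wl.empty:
        return {"unique_wl": wl.copy(), "common_rjf": wl.copy()}
    rjf_keys = set(variant_key(rjf)) if not rjf.empty else set()
    in_rjf = variant_key(wl).isin(rjf_keys)
    return {"unique_wl": wl[~in_rjf].copy(), "common_rjf": wl[in_rjf].copy()}


def second_pass_concordance_filter(
    allelic_counts: pd.DataFrame, sample_sexes: dict | pd.Series
) -> pd.Index:
    """Final variant keys after the per-sex concordance exclusion.

    ``allelic_counts`` has one row per (variant_key, sample_id) with
    ``n_match`` / ``n_mismatch`` read counts against the expected breed
    allele. A sample agrees when the majority of its allele-informative
    reads match; a variant is excluded when the fraction of agreeing samples
    is < 0.5 (strict) within the male group OR within the female group.
    Samples with zero covering reads are not evaluable and do not enter the
    fraction; a variant unevaluable in one sex is judged on the other alone.
    """
    sexes = pd.Series(sample_sexes)
    df = allelic_counts.copy()
    df["sex"] = df["sample_id"].map(sexes)
    if df["sex"].isna().any():
        raise ValueError("allelic counts contain samples with unknown sex")
    covered = df[(df["n_match"] + df["n_mismatch"]) > 0].copy()
    covered["agrees"] = covered["n_match"] > covered["n_mismatch"]
    frac = (
        covered.groupby(["variant_key", "sex"])["agrees"].mean().unstack("sex")
    )
    all_keys = pd.Index(allelic_counts["variant_key"].unique(), name="variant_key")
    frac = frac.reindex(all_keys)
    n_unevaluable = int(frac.isna().any(axis=1).sum())
    if n_unevaluable:
        log.info("second pass: %d variants unevaluable in at least one sex group", n_unevaluable)
    fails = pd.Series(False, index=all_keys)
    for sex in frac.columns:
        fails |= frac[sex] < 0.5  # NaN (unevaluable) never fails
    kept = all_keys[~fails]
    log.info("second pass: %d -> %d variants", len(all_keys), len(kept))
    return kept


def concordance_counts(
    reads: pd.DataFrame, unique_wl: pd.DataFrame, panel: pd.DataFrame
) -> pd.DataFrame:
    """Per-(variant, sample) agreement counts for the second-pass filter.

    ``reads`` is a tidy basecall table from pure-breed samples; ``panel``
    maps unit_id to breed and sex. For a WL-unique variant the expected base
    is ALT in WL samples and REF in RJF samples; ``n_match``/``n_mismatch``
    count basecalls agreeing/disagreeing with that expectation.
    """
    vk = unique_wl.copy()
    vk["variant_key"] = variant_key(vk)
    expected = vk.set_index("variant_key")[["ref", "alt"]]
    sub = reads[reads["variant_key"].isin(expected.index)].copy()
    breed = panel.set_index("unit_id")["breed"]
    sub["breed"] = sub["unit_id"].map(breed)
    exp = expected.loc[sub["variant_key"]]
    expected_base = np.where(sub["breed"].to_numpy() == "WL", exp["alt"].to_numpy(), exp["ref"].to_numpy())
    sub["match"] = sub["base"].to_numpy() == expected_base
    agg = (
        sub.groupby(["variant_key", "unit_id"])["match"]
        .agg(n_match="sum", n_total="count")
        .reset_index()
    )
    agg["n_mismatch"] = agg["n_total"] - agg["n_match"]
    agg = agg.rename(columns={"unit_id": "sample_id"})
    return agg[["variant_key", "sample_id", "n_match", "n_mismatch"]]


def phase_hemizygous_z(variants: pd.DataFrame, female_genotypes: pd.DataFrame) -> pd.DataFrame:
    """Flip REF/ALT of chrZ records whose hemizygous female allele is mislabelled.

    ``female_genotypes`` has one row per (variant_key, sample_id) with an
    ``allele`` column in {ref, alt}: the single allele each ZW female carries
    at the Z-linked site. The expected breed allele in a WL-informative set
    is ALT; Z variants where females carry REF get their labels swapped.
    Variants with conflicting calls across females are dropped (logged);
    autosomal records and variants without female calls pass unchanged.
    """
    out = variants.copy()
    out["variant_key"] = variant_key(out)
    if female_genotypes.empty:
        return out.drop(columns="variant_key")
    on_z = out["chrom"].astype(str) == "Z"
    calls = female_genotypes.groupby("variant_key")["allele"].agg(["nunique", "first"])
    conflicted = set(calls.index[calls["nunique"] > 1])
    flip_keys = set(calls.index[(calls["nunique"] == 1) & (calls["first"] == "ref")])

    drop = on_z & out["variant_key"].isin(conflicted)
    if drop.any():
        log.warning("phasing: %d chrZ variants dropped for conflicting female genotypes", int(drop.sum()))
    flip = on_z & out["variant_key"].isin(flip_keys) & ~drop
    ref, alt = out.loc[flip, "ref"].copy(), out.loc[flip, "alt"].copy()
    out.loc[flip, "ref"], out.loc[flip, "alt"] = alt.to_numpy(), ref.to_numpy()
    return out[~drop].drop(columns="variant_key").reset_index(drop=True)


def build_genotype_map(final_variants: pd.DataFrame) -> pd.DataFrame:
    """variant_key -> expected base per breed (WL carries ALT, RJF carries REF)."""
    gm = pd.DataFrame(
        {"WL": final_variants["alt"].to_numpy(), "RJF": final_variants["ref"].to_numpy()},
        index=pd.Index(variant_key(final_variants), name="variant_key"),
    )
    return gm[~gm.index.duplicated()]


def assign_read_to_allele(basecalls, genotype_map: pd.DataFrame) -> str:
    """Assign one read from its [(variant_key, base), ...] observations.

    The match fraction against each breed counts only basecalls at positions
    present in the genotype map (unknown positions are ignored, logged);
    a breed is assigned iff its fraction exceeds 0.66 strictly.
    """
    known = [(k, b) for k, b in basecalls if k in genotype_map.index]
    skipped = len(basecalls) - len(known)
    if skipped:
        log.debug("read assignment: %d basecalls at unknown positions ignored", skipped)
    if not known:
        return "unassigned"
    n = len(known)
    frac = {
        a: sum(1 for k, b in known if genotype_map.at[k, a] == b) / n for a in ALLELES
    }
    best = max(ALLELES, key=lambda a: frac[a])
    return best if frac[best] > MATCH_THRESHOLD else "unassigned"


def assign_reads(reads: pd.DataFrame, genotype_map: pd.DataFrame) -> pd.DataFrame:
    """Vectorised assignment of a tidy basecall table.

    ``reads`` has one row per basecall (read_id, gene_id, unit_id,
    variant_key, base). Returns one row per read with its gene, unit and
    assigned allele.
    """
    known = reads[reads["variant_key"].isin(genotype_map.index)]
    n_unknown = len(reads) - len(known)
    if n_unknown:
        log.info("read assignment: %d basecalls at positions absent from the genotype map", n_unknown)
    if known.empty:
        return pd.DataFrame(columns=["read_id", "gene_id", "unit_id", "allele"])
    gm = genotype_map.loc[known["variant_key"]]
    match = pd.DataFrame(
        {a: (known["base"].to_numpy() == gm[a].to_numpy()) for a in ALLELES},
        index=known.index,
    )
    match["read_id"] = known["read_id"].to_numpy()
    frac = match.groupby("read_id", sort=False)[list(ALLELES)].mean()
    allele = pd.Series("unassigned", index=frac.index, name="allele")
    for a in ALLELES:
        other = [b for b in ALLELES if b != a][0]
        allele[(frac[a] > MATCH_THRESHOLD) & (frac[a] >= frac[other])] = a
    first = known.drop_duplicates("read_id").set_index("read_id")[["gene_id", "unit_id"]]
    out = first.join(allele).reset_index()
    return out[["read_id", "gene_id", "unit_id", "allele"]]


def aggregate_allelic_counts(
    assignments: pd.DataFrame, annotation: pd.DataFrame, unit_meta: pd.DataFrame | None = None
) -> AllelicCountMatrix:
    """Sum assigned reads into a gene x unit matrix with per-allele layers.

    Reads whose gene is absent from the annotation are counted under a
    reserved ``unannotated`` row. The total layer equals the sum of the
    RJF, WL and unassigned layers (every read here covered a variant).
    """
    genes = list(annotation["gene_id"])
    unknown = ~assignments["gene_id"].isin(genes)
    if unknown.any():
        log.warning("%d reads on genes absent from the annotation -> 'unannotated'", int(unknown.sum()))
        genes = genes + ["unannotated"]
    a = assignments.copy()
    a.loc[unknown, "gene_id"] = "unannotated"
    units = sorted(a["unit_id"].unique())
    layers = {}
    for lab in ("RJF", "WL", "unassigned"):
        pivot = (
            a[a["allele"] == lab]
            .groupby(["gene_id", "unit_id"], sort=False)
            .size()
            .unstack("unit_id", fill_value=0)
            .reindex(index=genes, columns=units, fill_value=0)
            .astype(np.int64)
        )
        pivot.index.name = None
        pivot.columns.name = None
        layers[lab] = pivot
    layers["total"] = layers["RJF"] + layers["WL"] + layers["unassigned"]
    if unit_meta is None:
        unit_meta = pd.DataFrame(
            {"sample_id": units, "karyotype": "", "sex": ""}, index=pd.Index(units)
        )
    return AllelicCountMatrix(layers, unit_meta)


def derive_final_variants(
    wl_raw: pd.DataFrame,
    rjf_raw: pd.DataFrame,
    allelic_counts: pd.DataFrame | None = None,
    sample_sexes: dict | None = None,
    female_genotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full two-pass derivation: filter, set algebra, concordance, phasing.

    Returns the final WL-informative variant table ready for N-masking
    bookkeeping and read assignment. The concordance pass is skipped when no
    first-pass quantification is supplied.
    """
    wl = first_pass_variant_filter(wl_raw)
    rjf = first_pass_variant_filter(rjf_raw)
    sets = informative_variant_sets(wl, rjf)
    final = sets["unique_wl"]
    if allelic_counts is not None and sample_sexes is not None and len(allelic_counts):
        kept = second_pass_concordance_filter(allelic_counts, sample_sexes)
        final = final[variant_key(final).isin(set(kept))]
    if female_genotypes is not None:
        final = phase_hemizygous_z(final, female_genotypes)
    return final.reset_index(drop=True)
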