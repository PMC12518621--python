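"""Readers and writers for the formats the pipeline touches.

On-disk interval formats (GTF-lite, VCF) are 1-based inclusive; in-memory
intervals are 0-based half-open, converted through the paired helpers
below. Count matrices round-trip losslessly through TSV (dense) or
MatrixMarket with row/column sidecars (sparse single-cell layers), aligned
by identifier rather than position.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .types import AllelicCountMatrix

log = logging.getLogger(__name__)

ANNOTATION_COLS = [
    "gene_id", "chrom", "start", "end", "exonic_length_bp",
    "tata", "inr", "mir_target", "ancient_paralog",
]


def to_zero_based(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive (GTF/VCF convention) -> 0-based half-open."""
    return start_1based - 1, end_1based_inclusive


def to_one_based(start_0based: int, end_half_open: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start_0based + 1, end_half_open


# ---------------------------------------------------------------------------
# annotation


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLS].to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("tata", "inr", "mir_target", "ancient_paralog"):
        ann[col] = ann[col].astype(bool)
    return ann


def write_gtf_lite(annotation: pd.DataFrame, path) -> None:
    """Gene records as GTF lines (1-based inclusive, gene_id attribute)."""
    with open(path, "w") as fh:
        for _, g in annotation.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            for flag in ("tata", "inr", "mir_target", "ancient_paralog"):
                attrs += f' {flag} "{int(bool(g[flag]))}";'
            fh.write(
                f"{g.chrom}\tzdose\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def _parse_attributes(field: str) -> dict:
    out = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, val = chunk.split(" ", 1)
            out[key] = val.strip().strip('"')
    return out


def read_gtf_lite(path) -> pd.DataFrame:
    """Parse gene (and exon) features from a GTF-lite file.

    Exonic length is the union of exon intervals when exons are present for
    a gene, otherwise end - start + 1 of the gene record. Lines without a
    gene_id attribute are rejected with their line number; malformed lines
    are logged and skipped.
    """
    genes, exons = {}, {}
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                log.warning("gtf line %d malformed (%d fields), skipped", lineno, len(parts))
                n_rejected += 1
                continue
            chrom, _, feature, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                start, end = int(start), int(end)
            except ValueError:
                log.warning("gtf line %d has non-integer coordinates, skipped", lineno)
                n_rejected += 1
                continue
            attrs = _parse_attributes(parts[8])
            gid = attrs.get("gene_id")
            if gid is None:
                log.warning("gtf line %d lacks gene_id, rejected", lineno)
                n_rejected += 1
                continue
            if feature == "gene":
                genes[gid] = {
                    "gene_id": gid, "chrom": chrom, "start": start, "end": end,
                    "tata": attrs.get("tata", "0") == "1",
                    "inr": attrs.get("inr", "0") == "1",
                    "mir_target": attrs.get("mir_target", "0") == "1",
                    "ancient_paralog": attrs.get("ancient_paralog", "0") == "1",
                }
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
    rows = []
    for gid, g in genes.items():
        if gid in exons:
            g["exonic_length_bp"] = interval_union_length(exons[gid])
        else:
            g["exonic_length_bp"] = g["end"] - g["start"] + 1
        rows.append(g)
    if n_rejected:
        log.info("gtf: %d lines rejected", n_rejected)
    return pd.DataFrame(rows, columns=ANNOTATION_COLS)


def interval_union_length(intervals_1based) -> int:
    """Total covered length of a union of 1-based inclusive intervals."""
    ivs = sorted(to_zero_based(s, e) for s, e in intervals_1based)
    total, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# VCF


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf_min(variants: pd.DataFrame, path, genotypes: pd.DataFrame | None = None) -> None:
    """Minimal VCF 4.2: CHROM POS ID REF ALT QUAL FILTER INFO(DP, AF) [GT].

    ``genotypes`` is an optional (variant_key x sample) table of GT strings.
    """
    samples = list(genotypes.columns) if genotypes is not None else []
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT"] + samples
        fh.write("\t".join(cols) + "\n")
        for _, v in variants.iterrows():
            key = f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
            info = f"DP={int(v.depth)};AF={v.af:.6g}"
            row = [str(v.chrom), str(int(v.pos)), key, v.ref, v.alt, f"{v.qual:.6g}", "PASS", info]
            if samples:
                row.append("GT")
                row += [str(genotypes.at[key, s]) if key in genotypes.index else "./." for s in samples]
            fh.write("\t".join(row) + "\n")


def read_vcf_min(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a minimal VCF: SNVs only, multi-allelic sites split to biallelic.

    Indel records are skipped with a counter; records lacking DP or AF are
    kept with missing values (the first-pass filter rejects them later).
    Returns (variant table, genotype-call table with one row per
    variant x sample, calls in {ref-hom, alt-hom, het, missing}).
    """
    from cyvcf2 import VCF

    rows, gt_rows = [], []
    n_indels = 0
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for rec in vcf:
        alts = rec.ALT or []
        n_alt = len(alts)
        af = rec.INFO.get("AF")
        afs = list(af) if isinstance(af, tuple) else [af] * n_alt
        for ai, alt in enumerate(alts):
            if len(rec.REF) != 1 or len(alt) != 1:
                n_indels += 1
                continue
            rows.append(
                {
                    "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt,
                    "qual": rec.QUAL if rec.QUAL is not None else np.nan,
                    "depth": rec.INFO.get("DP", np.nan),
                    "af": afs[ai] if ai < len(afs) and afs[ai] is not None else np.nan,
                    "source": "sample",
                }
            )
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            for si, s in enumerate(samples):
                g = rec.genotypes[si]
                alleles = [x for x in g[:-1] if x is not None]
                present = [x for x in alleles if x >= 0]
                if not present:
                    call = "missing"
                elif all(x == 0 for x in present):
                    call = "ref-hom"
                elif all(x == ai + 1 for x in present):
                    call = "alt-hom"
                elif any(x == ai + 1 for x in present):
                    call = "het"
                else:
                    call = "missing"
                gt_rows.append({"variant_key": key, "sample_id": s, "call": call})
    if n_indels:
        log.info("vcf: %d indel alleles skipped", n_indels)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "depth", "af", "source"])
    genotypes = pd.DataFrame(gt_rows, columns=["variant_key", "sample_id", "call"])
    return variants, genotypes


# ---------------------------------------------------------------------------
# count matrices


def write_counts_tsv(matrix: AllelicCountMatrix, out_dir, prefix: str = "counts") -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for layer, df in sorted(matrix.layers.items()):
        p = out_dir / f"{prefix}.{layer}.tsv"
        df.to_csv(p, sep="\t", index_label="gene_id")
        written.append(p)
    meta_p = out_dir / f"{prefix}.units.tsv"
    matrix.unit_meta.to_csv(meta_p, sep="\t", index_label="unit", float_format="%.10g")
    written.append(meta_p)
    return written


def read_counts_tsv(out_dir, prefix: str = "counts") -> AllelicCountMatrix:
    out_dir = Path(out_dir)
    layers = {}
    for p in sorted(out_dir.glob(f"{prefix}.*.tsv")):
        layer = p.name[len(prefix) + 1 : -4]
        if layer == "units":
            continue
        layers[layer] = pd.read_csv(p, sep="\t", index_col="gene_id").astype(np.int64)
    if "total" not in layers:
        raise FileNotFoundError(f"no {prefix}.total.tsv under {out_dir}")
    ref = layers["total"]
    for name in list(layers):
        df = layers[name]
        if set(df.index) != set(ref.index) or set(df.columns) != set(ref.columns):
            raise ValueError(f"layer {name!r} identifiers disagree with 'total'")
        layers[name] = df.reindex(index=ref.index, columns=ref.columns)
    meta = pd.read_csv(out_dir / f"{prefix}.units.tsv", sep="\t", index_col="unit")
    return AllelicCountMatrix(layers, meta)


def write_counts_mtx(matrix: AllelicCountMatrix, out_dir, prefix: str = "counts") -> list:
    """MatrixMarket layers with gene/unit identifier sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    pd.Series(matrix.genes).to_csv(out_dir / f"{prefix}.genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.units).to_csv(out_dir / f"{prefix}.units_index.tsv", sep="\t", index=False, header=False)
    matrix.unit_meta.to_csv(out_dir / f"{prefix}.units.tsv", sep="\t", index_label="unit", float_format="%.10g")
    for layer, df in sorted(matrix.layers.items()):
        p = out_dir / f"{prefix}.{layer}.mtx"
        mmwrite(str(p), csr_matrix(df.to_numpy()))
        written.append(p)
    return written


def read_counts_mtx(out_dir, prefix: str = "counts") -> AllelicCountMatrix:
    out_dir = Path(out_dir)
    genes = pd.read_csv(out_dir / f"{prefix}.genes.tsv", sep="\t", header=None)[0]
    units = pd.read_csv(out_dir / f"{prefix}.units_index.tsv", sep="\t", header=None)[0]
    layers = {}
    for p in sorted(out_dir.glob(f"{prefix}.*.mtx")):
        layer = p.name[len(prefix) + 1 : -4]
        m = np.asarray(mmread(str(p)).todense()).astype(np.int64)
        if m.shape != (len(genes), len(units)):
            raise ValueError(f"layer {layer!r} dimensions {m.shape} disagree with sidecars")
        layers[layer] = pd.DataFrame(m, index=genes.to_numpy(), columns=units.to_numpy())
    meta = pd.read_csv(out_dir / f"{prefix}.units.tsv", sep="\t", index_col="unit")
    return AllelicCountMatrix(layers, meta)


def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format="%.10g")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
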