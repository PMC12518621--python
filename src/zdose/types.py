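"""Domain containers shared across the pipeline.

The central currency is a gene x unit count matrix with per-allele layers
(``AllelicCountMatrix``); units are bulk samples or single cells. Kinetic
parameters follow the two-state telegraph model with time measured in units
of the mRNA degradation rate (k_deg == 1), so k_on is the burst frequency
and k_syn/k_off the mean burst size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

ALLELES = ("RJF", "WL")
#: grouped micro-chromosomes 9-33 are collapsed under the label "mu"
MICRO = "mu"
SEX_CHROMS = ("Z", "W")


class TelegraphParams(NamedTuple):
    """Two-state telegraph rates in units of mRNA degradation rate."""

    k_on: float
    k_off: float
    k_syn: float

    @property
    def burst_frequency(self) -> float:
        return self.k_on

    @property
    def burst_size(self) -> float:
        return self.k_syn / self.k_off

    @property
    def mean_expression(self) -> float:
        return self.k_syn * self.k_on / (self.k_on + self.k_off)

    def validate(self) -> "TelegraphParams":
        arr = np.asarray(self, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"telegraph rates must be finite and >= 0, got {self}")
        return self


@dataclass
class TelegraphFit:
    """Result of fitting the telegraph model to one gene-allele count vector."""

    gene_id: str
    allele: str
    params: TelegraphParams | None
    loglik: float
    n_cells_used: int
    status: str  # converged | boundary | failed | insufficient_cells

    @property
    def burst_frequency(self) -> float:
        return self.params.k_on if self.params is not None else np.nan

    @property
    def burst_size(self) -> float:
        return self.params.burst_size if self.params is not None else np.nan


@dataclass(frozen=True)
class Genotype:
    """One simulated individual: karyotype and breed origin of every copy.

    ``z_origins``/``w_origins``/``autosome_origins`` list the breed of each
    chromosome copy, e.g. a ZW female has one Z copy and one W copy while the
    triploid intersex carries (Z, Z, W) with three autosomal sets.
    """

    sample_id: str
    karyotype: str  # ZZ | ZW | ZZW
    z_origins: tuple[str, ...]
    w_origins: tuple[str, ...]
    autosome_origins: tuple[str, ...]

    def __post_init__(self):
        expected = {"ZZ": (2, 0, 2), "ZW": (1, 1, 2), "ZZW": (2, 1, 3)}
        if self.karyotype not in expected:
            raise ValueError(f"unknown karyotype {self.karyotype!r}")
        nz, nw, na = expected[self.karyotype]
        if (len(self.z_origins), len(self.w_origins), len(self.autosome_origins)) != (nz, nw, na):
            raise ValueError(f"copy numbers inconsistent with karyotype {self.karyotype}")
        for o in self.z_origins + self.w_origins + self.autosome_origins:
            if o not in ALLELES:
                raise ValueError(f"unknown breed origin {o!r}")

    @property
    def ploidy(self) -> int:
        return len(self.autosome_origins)

    @property
    def sex(self) -> str:
        return {"ZZ": "male", "ZW": "female", "ZZW": "intersex"}[self.karyotype]


def default_genotypes() -> tuple[Genotype, ...]:
    """Two ZW females, two ZZ males and one triploid ZZW intersex line.

    Mirrors a five-line embryonic-fibroblast panel from reciprocal
    RJF x WL crosses; the triploid carries Z(WL) Z(RJF) W(WL) with
    autosomal sets (WL, RJF, WL).
    """
    return (
        Genotype("ZW_1", "ZW", ("WL",), ("RJF",), ("RJF", "WL")),
        Genotype("ZW_2", "ZW", ("RJF",), ("WL",), ("RJF", "WL")),
        Genotype("ZZ_1", "ZZ", ("RJF", "WL"), (), ("RJF", "WL")),
        Genotype("ZZ_2", "ZZ", ("RJF", "WL"), (), ("RJF", "WL")),
        Genotype("ZZW_1", "ZZW", ("WL", "RJF"), ("WL",), ("WL", "RJF", "WL")),
    )


@dataclass
class SimulationDesign:
    """Knobs of the synthetic experiment; the seed determines every output.

    Effect-size parameters
    ----------------------
    u : multiplicative Z-upregulation of k_on (and bulk output) of the single
        Z allele in ZW females; >= 1.
    tau : translation-efficiency boost of Z genes in W-bearing genotypes.
    beta : per-copy autosomal output multiplier in triploid ZZW (buffering).
    rho : miR-2954 repression factor on RNA of miR-target Z genes in ZZ males;
        ZZW males-like intermediate uses sqrt(rho).
    """

    # autosomes outnumber Z ~14:1 so that chrZ holds a realistically small
    # share of each library (sex-dependent composition shifts FPKM ratios by
    # only a few percent, as in real data)
    n_genes_per_chrom: dict = field(
        default_factory=lambda: {
            "1": 2200, "2": 1900, "3": 1600, "4": 1300, "5": 1000, MICRO: 6000, "Z": 1000, "W": 30,
        }
    )
    genotypes: tuple[Genotype, ...] = field(default_factory=default_genotypes)
    u: float = 1.5
    tau: float = 1.2
    beta: float = 0.8
    rho: float = 0.7
    depth: float = 2e6
    variant_density: float = 2.0  # informative variants per kb of exonic sequence
    base_error: float = 0.005
    n_cells: int = 500
    n_spikes: int = 30
    seed: int = 0

    # annotation flag prevalences
    tata_rate: float = 0.15
    inr_rate: float = 0.35
    mir_target_rate_z: float = 0.05
    mir_target_rate_autosome: float = 0.02
    ancient_paralog_rate: float = 0.10

    # bulk / ribo / protein noise model
    baseline_log_sd: float = 0.5  # ln-scale spread of per-copy expression
    nb_dispersion: float = 0.1
    n_tech_reps: int = 3  # technical replicates summed per library
    base_te_log_sd: float = 0.3
    protein_noise_log_sd: float = 0.25
    protein_detect_frac: float = 0.5

    # single-cell model
    capture_mean: float = 0.7
    capture_log_sd: float = 0.2
    qc_fail_frac: float = 0.04
    spike_mean_total: float = 300.0  # expected spike UMIs per cell at capture 1
    # gene-level telegraph parameters: lognormal medians and log2 spreads
    kinetic_medians: tuple = (1.0, 6.0, 50.0)  # (k_on, k_off, k_syn)
    kinetic_log2_sds: tuple = (0.5, 0.4, 0.5)

    # abstract read observations
    variants_per_read: tuple = (2, 4)  # inclusive range of covered variants

    def __post_init__(self):
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_genes_per_chrom.get("Z", 0) < 1:
            raise ValueError("chromosome Z needs at least one gene; the analysis is meaningless without it")
        if any(n < 1 for n in self.n_genes_per_chrom.values()):
            raise ValueError("n_genes_per_chrom entries must be >= 1")
        if self.n_cells < 1 or self.n_spikes < 0:
            raise ValueError("cell/spike counts must be positive")
        if not (0 <= self.base_error < 1):
            raise ValueError("base_error must be in [0, 1)")

    def with_effects(self, **kw) -> "SimulationDesign":
        """Copy of the design with selected fields replaced."""
        return replace(self, **kw)

    def null(self, **kw) -> "SimulationDesign":
        """Copy with all dosage effects switched off (u=tau=beta=rho=1);
        keyword overrides re-enable selected effects."""
        kwargs = {"u": 1.0, "tau": 1.0, "beta": 1.0, "rho": 1.0}
        kwargs.update(kw)
        return replace(self, **kwargs)


class AllelicCountMatrix:
    """Gene x unit integer counts with total / per-allele / unassigned layers.

    Invariant: RJF + WL + unassigned <= total entry-wise (totals may include
    reads that cover no informative variant).
    """

    CORE_LAYERS = ("total", "RJF", "WL", "unassigned")

    def __init__(self, layers: dict, unit_meta: pd.DataFrame):
        if "total" not in layers:
            raise ValueError("a 'total' layer is required")
        tot = layers["total"]
        self.genes = tot.index
        self.units = tot.columns
        self.layers = {}
        for name, df in layers.items():
            if df.shape != tot.shape or not df.index.equals(tot.index) or not df.columns.equals(tot.columns):
                raise ValueError(f"layer {name!r} not aligned with 'total'")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"layer {name!r} has negative entries")
            self.layers[name] = df
        self.unit_meta = unit_meta.loc[self.units]
        self.validate()

    def validate(self):
        present = [l for l in ("RJF", "WL", "unassigned") if l in self.layers]
        if present:
            s = sum(self.layers[l].to_numpy() for l in present)
            if (s > self.layers["total"].to_numpy()).any():
                raise ValueError("allele layers exceed total counts")

    def __getitem__(self, layer: str) -> pd.DataFrame:
        return self.layers[layer]

    @property
    def shape(self):
        return self.layers["total"].shape

    def subset_units(self, units) -> "AllelicCountMatrix":
        layers = {k: v.loc[:, units] for k, v in self.layers.items()}
        return AllelicCountMatrix(layers, self.unit_meta.loc[units])

    def equals(self, other: "AllelicCountMatrix") -> bool:
        return (
            set(self.layers) == set(other.layers)
            and all(self.layers[k].equals(other.layers[k]) for k in self.layers)
            and self.unit_meta.equals(other.unit_meta)
        )


@dataclass
class TestResult:
    """One statistical comparison with its null summary and percentile CI."""

    name: str
    observed: float
    p_value: float
    method: str  # bootstrap_median | mann_whitney | wilcoxon_1sample | spearman
    ci_low: float = np.nan
    ci_high: float = np.nan
    null_size: int = 0
    null_mean: float = np.nan
    tail_count: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "observed": self.observed,
            "p_value": self.p_value,
            "method": self.method,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "null_size": self.null_size,
            "null_mean": self.null_mean,
            "tail_count": self.tail_count,
        }
        d.update(self.extra)
        return d
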