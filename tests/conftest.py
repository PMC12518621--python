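import numpy as np
import pandas as pd
import pytest

from zdose import SimulationDesign, synthdata
from zdose.types import Genotype


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        n_genes_per_chrom={"1": 60, "mu": 60, "Z": 40, "W": 5},
        n_cells=80,
        depth=3e5,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_annotation(small_design):
    return synthdata.make_annotation(small_design)


@pytest.fixture(scope="session")
def small_bulk(small_design, small_annotation):
    return synthdata.simulate_bulk_experiment(small_annotation, small_design)


@pytest.fixture(scope="session")
def small_sc(small_design, small_annotation):
    return synthdata.simulate_sc_experiment(small_annotation, small_design)


@pytest.fixture()
def zw_only_design():
    return SimulationDesign(
        n_genes_per_chrom={"1": 40, "Z": 30},
        genotypes=(Genotype("ZW_1", "ZW", ("WL",), ("RJF",), ("RJF", "WL")),),
        n_cells=60,
        spike_mean_total=60.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def toy_variants():
    """Three WL variants (A, B, C) of which B is shared with RJF."""
    wl = pd.DataFrame(
        {
            "chrom": ["1", "1", "Z"],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "qual": [30.0, 30.0, 30.0],
            "depth": [20, 20, 20],
            "af": [0.9, 0.9, 0.9],
            "source": ["WL"] * 3,
        }
    )
    rjf = wl.iloc[[1]].assign(source="RJF")
    return wl, rjf


def make_counts(values, genes=None, units=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    units = units or [f"u{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=units)
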