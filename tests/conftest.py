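import dataclasses

import pytest
from hypothesis import settings

import ribospike as rs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def proteome():
    """Full synthetic r-protein set (8 proteins incl. the L20 reference)."""
    return rs.synthetic_proteome(seed=7)


@pytest.fixture(scope="session")
def index(proteome):
    return rs.build_unique_peptide_index(proteome)


@pytest.fixture(scope="session")
def small_index():
    """Three-protein index for fast per-sample loops."""
    prots = rs.synthetic_proteome(ids=("L20", "L6", "L16"), mean_length=90, seed=11)
    return rs.build_unique_peptide_index(prots)


@pytest.fixture(scope="session")
def base_design():
    """Noiseless double-spike design (10 pmol 14N + 30 pmol 15N), full enrichment."""
    return rs.SampleDesign(experimental_pmol=0.0, enrichment=1.0, charges=(1, 2), seed=3)


@pytest.fixture(scope="session")
def fit_config(base_design):
    return rs.FitConfig.for_design(base_design)


@pytest.fixture(scope="session")
def spike_spectrum(base_design, index):
    return rs.simulate_spike_alone(base_design, index)


@pytest.fixture(scope="session")
def sample20(base_design, index):
    """20 pmol experimental sample, all-1.0 occupancy truth."""
    design = dataclasses.replace(base_design, experimental_pmol=20.0)
    return rs.simulate_sample(design, rs.OccupancyTruth(), index)
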