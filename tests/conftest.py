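"""Shared fixtures: all data is generated programmatically at test time."""

import pytest

from acep import (
    FeatureSpec,
    Peptide,
    PeptideDataset,
    SimulationParams,
    SVMConfig,
    simulate_dataset,
)
from acep.peptide_io import EPITOPE, NON_EPITOPE
from acep.svm_model import train


def make_peptides(seqs, label=EPITOPE, prefix="p"):
    return [Peptide(f"{prefix}{i + 1}", s, label) for i, s in enumerate(seqs)]


@pytest.fixture(scope="session")
def default_sim() -> PeptideDataset:
    """The generator's default study conditions: 300/class, 2x R/I/V/W vs
    E/G/P/L enrichment, RIV+KWR planted in 40% of positives."""
    return simulate_dataset(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_sim() -> PeptideDataset:
    """A small simulated dataset for fast model tests."""
    return simulate_dataset(SimulationParams(n_pos=60, n_neg=60, seed=2))


@pytest.fixture(scope="session")
def separable_sim() -> PeptideDataset:
    """Strongly separated classes (heavy enrichment, certain motifs)."""
    return simulate_dataset(
        SimulationParams(
            n_pos=60,
            n_neg=60,
            enrichment=8.0,
            planted_motifs=(("RIV", 1.0),),
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def dpc_config() -> SVMConfig:
    """The dipeptide-composition model parameterization (g, c, j)."""
    return SVMConfig(g=0.0005, c=1.0, j=2.0, threshold=0.0)


@pytest.fixture(scope="session")
def dpc_bundle(small_sim, dpc_config):
    return train(small_sim, FeatureSpec("DPC"), dpc_config, seed=11)
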