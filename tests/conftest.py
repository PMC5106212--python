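"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from pcdhkit.auc import AssociationModel
from pcdhkit.synthetic import (
    DEFAULT_SPECIES,
    gen_auc_dataset,
    gen_c2_dimer,
    gen_domain_chain,
    gen_isoform_family,
)


@pytest.fixture(scope="session")
def straight_chain():
    structure, truth = gen_domain_chain(3, residues_per_domain=20, seed=11)
    return structure, truth


@pytest.fixture(scope="session")
def bent_chain():
    structure, truth = gen_domain_chain(
        4, residues_per_domain=20, bend_angles_deg=[10.0, 32.6, 18.6], seed=12,
        calcium_per_junction=3,
    )
    return structure, truth


@pytest.fixture(scope="session")
def c2_dimer():
    chain, _ = gen_domain_chain(2, residues_per_domain=20, seed=13)
    return gen_c2_dimer(chain, separation=8.0, seed=13)


@pytest.fixture(scope="session")
def isoform_family():
    return gen_isoform_family(
        n_isoforms=3,
        n_species=20,
        n_positions=30,
        planted_variable=[3, 7, 11, 19, 25],
        planted_covarying_pair=(10, 20),
        mutation_rate=0.02,
        seed=14,
    )


@pytest.fixture(scope="session")
def dimer_scans():
    scans, truth = gen_auc_dataset(
        AssociationModel("monomer_dimer", kd=20.0),
        noise_sd=0.0065,
        speeds=(11000.0, 13000.0, 15000.0),
        seed=15,
    )
    return scans, truth


@pytest.fixture(scope="session")
def species():
    return DEFAULT_SPECIES


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
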