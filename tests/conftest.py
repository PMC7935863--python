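"""Shared fixtures: model configurations, parameter sets and small helpers."""

import numpy as np
import pytest

from sgdrive import (
    DriveParams,
    ModelConfig,
    individual,
    seed_frequencies,
)
from sgdrive.genetics_core import FEMALE, MALE, trans_het


@pytest.fixture(scope="session")
def unlinked_viability():
    return ModelConfig("viability", "autosome_unlinked")


@pytest.fixture(scope="session")
def unlinked_fecundity():
    return ModelConfig("fecundity", "autosome_unlinked")


@pytest.fixture(scope="session")
def linked_viability():
    return ModelConfig("viability", "autosome_linked")


@pytest.fixture(scope="session")
def x_linked_viability():
    return ModelConfig("viability", "x_linked")


@pytest.fixture(scope="session")
def all_configs(unlinked_viability, unlinked_fecundity, linked_viability, x_linked_viability):
    return [unlinked_viability, unlinked_fecundity, linked_viability, x_linked_viability]


@pytest.fixture
def neutral_params():
    """No cleavage, no deposition, no costs: pure Mendelian two-locus."""
    return DriveParams()


@pytest.fixture
def strong_drive_params():
    return DriveParams(
        q_f=1.0, q_m=1.0, h_f=0.9, h_m=0.9, fR_f=0.5, fR_m=0.5,
        d_dep=0.5, sigma_shadow=0.3,
    )


def default_seed(config):
    """1:3 trans-heterozygote : wildtype cage seeding as frequencies."""
    return seed_frequencies(
        {
            trans_het(config, FEMALE): 15,
            individual("W", "W", sex=FEMALE, config=config): 45,
        },
        {
            trans_het(config, MALE): 15,
            individual("W", "W", sex=MALE, config=config): 45,
        },
    )


def random_params(rng: np.random.Generator) -> DriveParams:
    u = rng.random(12)
    return DriveParams(
        q_f=u[0], q_m=u[1], h_f=u[2], h_m=u[3], fR_f=u[4], fR_m=u[5],
        d_dep=u[6], sigma_shadow=u[7], r_linked=0.5 * u[8],
        chrom_loss=u[9], cost_fecundity_f=u[10] * 0.9, cost_eggviability=u[11] * 0.9,
    )
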