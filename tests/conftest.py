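"""Shared fixtures: the synthetic study system and a small backend budget.

The study system is a 30-residue two-state hinge (4.5 A peak displacement,
0.3 A thermal noise, 50/50 populations) restrained by exact eNOE-like
bound pairs over a 9 A Calpha contact network -- the Calpha-level
equivalent of a 5 A proton NOE network at paper-like restraint density.
"""

from __future__ import annotations

import numpy as np
import pytest

from mscorval.refine import BackendConfig
from mscorval.synthetic import make_two_state_model, restraints_from_model, sample_ensemble

STUDY_DISPLACEMENT = 4.5  # A, peak of the hinge field
STUDY_NOISE = 0.3  # A, per-bead thermal noise
STUDY_LENGTH = 30
STUDY_CUTOFF = 9.0  # A, Calpha-Calpha contact range of a proton-level NOE


def study_model(seed: int = 1, **kw):
    kw.setdefault("length", STUDY_LENGTH)
    kw.setdefault("displacement", STUDY_DISPLACEMENT)
    kw.setdefault("noise_sigma", STUDY_NOISE)
    return make_two_state_model(seed=seed, **kw)


def study_restraints(model, **kw):
    kw.setdefault("contact_cutoff", STUDY_CUTOFF)
    return restraints_from_model(model, **kw)


def small_config(**kw) -> BackendConfig:
    """Desk-scale backend effort used throughout the suite."""
    kw.setdefault("n_conformers_calculated", 16)
    kw.setdefault("n_conformers_kept", 8)
    kw.setdefault("n_steps", 800)
    return BackendConfig(**kw)


@pytest.fixture(scope="session")
def two_state_model():
    return study_model(seed=1)


@pytest.fixture(scope="session")
def two_state_ensemble(two_state_model):
    return sample_ensemble(two_state_model, n_conformers=20, seed=2)


@pytest.fixture(scope="session")
def study_restraint_set(two_state_model):
    return study_restraints(two_state_model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
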