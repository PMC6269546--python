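"""Shared fixtures: synthetic datasets and toy structures built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dmsprops import synthetic
from dmsprops.records import Structure
from dmsprops._geometry import chain_coords

NO_MISSING = {k: 0.0 for k in ("pkb", "logd", "epsa", "permeability", "ccs")}


@pytest.fixture(scope="session")
def dataset_default_noise():
    """n=120 campaign at the default noise level, no missing labels."""
    return synthetic.generate_dataset(120, seed=3, noise_scale=1.0, missing_rates=NO_MISSING)


@pytest.fixture(scope="session")
def dataset_zero_noise():
    """n=120 campaign with all noise off: labels are exact functions of the
    curve parameters and the curves are noiseless."""
    return synthetic.generate_dataset(120, seed=5, noise_scale=0.0, missing_rates=NO_MISSING)


@pytest.fixture()
def butane():
    """Four-site chain with one rotatable dihedral and no charges: the
    torsion term dominates, giving anti plus two gauche-like minima."""
    return Structure(
        elements=["C"] * 4,
        coords=chain_coords(4, dihedrals_deg=[180.0]),
        charges=[0.0] * 4,
        bonds=[(0, 1), (1, 2), (2, 3)],
        rotatable_dihedrals=[(0, 1, 2, 3)],
        total_charge=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
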