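"""Shared fixtures: small synthetic experiments reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from dnacaliper.io import RunConfig
from dnacaliper.presets import get_preset
from dnacaliper.pipeline import _simulate_molecules


@pytest.fixture(scope="session")
def k_endtoend_run():
    """Small potassium force-jump run: [(mol_id, trace, truth_log), ...]."""
    preset = get_preset("k_endtoend", n_molecules=3, cycles=10)
    cfg = RunConfig(experiment="k_endtoend", seed=42, n_molecules=3,
                    cycles_per_molecule=10)
    return preset, _simulate_molecules(preset, cfg)


@pytest.fixture(scope="session")
def na_endtoend_run():
    """Small sodium force-jump run with unfold-then-unloop cycles."""
    preset = get_preset("na_endtoend", n_molecules=3, cycles=12)
    cfg = RunConfig(experiment="na_endtoend", seed=7, n_molecules=3,
                    cycles_per_molecule=12)
    return preset, _simulate_molecules(preset, cfg)


@pytest.fixture(scope="session")
def directional_run():
    """Small directional ramp-then-jump run."""
    preset = get_preset("na_directional", n_molecules=2, cycles=12)
    cfg = RunConfig(experiment="na_directional", seed=5, n_molecules=2,
                    cycles_per_molecule=12)
    return preset, _simulate_molecules(preset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
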