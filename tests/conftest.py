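import dataclasses
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pottsml import cpm_sim as cs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def small_config(**overrides) -> cs.SimulationConfig:
    """60x60 lattice tiled by 144 cells of 25 pixels.

    Motility strengths are scaled so that the bias per gained pixel,
    kappa / A_t, matches the full-scale values (kappa=1500 at A_t=625
    corresponds to kappa=60 at A_t=25).
    """
    base = dict(lattice_size=60, n_cells=144, target_area=25,
                perimeter_threshold=30, temperature=5.0,
                kappa_active=60.0, kappa_passive=0.0, n_active=15,
                equilibration=200, n_snapshots=2, snapshot_interval=100,
                rng_seed=0)
    base.update(overrides)
    return cs.SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiled_state():
    cfg = cs.SimulationConfig(n_active=15, rng_seed=0)
    return cs.initialize_tiling(cfg, np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_equilibrated():
    """A small mixed active/passive state run for 300 MCS."""
    cfg = small_config(n_active=15)
    state = cs.initialize_tiling(cfg, np.random.default_rng(1))
    state.run(300)
    return state


def random_confluent_state(rng, size=20, n_cells=5, kappa=40.0):
    """Random (generally disconnected) confluent labels; valid for
    energy bookkeeping even though cells are not contiguous."""
    labels = rng.integers(1, n_cells + 1, size=(size, size)).astype(np.int16)
    for c in range(1, n_cells + 1):  # ensure every id occurs
        if not (labels == c).any():
            labels[rng.integers(size), rng.integers(size)] = c
    cfg = cs.SimulationConfig(
        lattice_size=size, n_cells=n_cells,
        target_area=size * size // n_cells, perimeter_threshold=20,
        temperature=5.0, kappa_active=kappa, kappa_passive=kappa / 4,
        n_active=2, rng_seed=int(rng.integers(2 ** 31)))
    types = np.array(["active"] * cfg.n_active
                     + ["passive"] * (n_cells - cfg.n_active), dtype=object)
    return cs.SimulationState(labels, types, cfg, rng)
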