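"""Simulator unit and property tests: energies, incremental updates,
connectivity, the Metropolis rule, polarity statistics."""

import math

import numpy as np
import pytest

from pottsml import cpm_sim as cs
from pottsml.cpm_sim import SimulationConfig

from conftest import random_confluent_state, small_config


# ------------------------------------------------------------ energies --

class TestAdhesionEnergy:
    def test_single_cell_has_no_contacts(self):
        cfg = SimulationConfig(lattice_size=8, n_cells=1, target_area=64)
        labels = np.ones((8, 8), dtype=int)
        assert cs.adhesion_energy(labels, cfg) == 0.0

    def test_two_cell_column_split_counts_crossing_pairs(self):
        # 2x2 grid, left column cell 1, right column cell 2: without
        # periodicity there would be 2 crossing pairs -> energy 10; the
        # periodic wrap doubles the contact seam (4 pairs -> 20)
        cfg = SimulationConfig(lattice_size=2, n_cells=2, target_area=2,
                               contact_energy=5.0)
        labels = np.array([[1, 2], [1, 2]])
        assert cs.adhesion_energy(labels, cfg) == 20.0
        # brute-force enumeration over unordered first-order pairs
        total = 0
        for y in range(2):
            for x in range(2):
                for dy, dx in ((0, 1), (1, 0)):
                    if labels[y, x] != labels[(y + dy) % 2, (x + dx) % 2]:
                        total += 5
        assert cs.adhesion_energy(labels, cfg) == total

    def test_perfect_tiling_shared_edges(self, tiled_state):
        # 144 cells x 2 unique shared edges x 25 pairs x J=5
        cfg = tiled_state.config
        assert cs.adhesion_energy(tiled_state.labels, cfg) == 36_000.0

    def test_unlabelled_pixel_rejected(self):
        cfg = SimulationConfig(lattice_size=2, n_cells=2, target_area=2)
        with pytest.raises(ValueError, match="[Uu]nlabelled|invalid"):
            cs.adhesion_energy(np.array([[0, 1], [1, 1]]), cfg)


class TestAreaPerimeterEnergy:
    @pytest.mark.parametrize("areas,expected", [
        ([625], 0.0), ([624], 1.0), ([620, 630], 50.0),
    ])
    def test_area_energy_quadratic(self, areas, expected):
        cfg = SimulationConfig()
        assert cs.area_energy(np.array(areas), cfg) == expected

    @pytest.mark.parametrize("perims,expected", [
        ([150], 0.0),     # at threshold: inactive
        ([151], 1.0),     # one above: quadratic in the excess
        ([96], 0.0),      # isolated 25x25 square: 4*25 - 4 boundary px
        ([140, 155, 160], 25.0 + 100.0),
    ])
    def test_perimeter_energy_one_sided(self, perims, expected):
        cfg = SimulationConfig()
        assert cs.perimeter_energy(np.array(perims), cfg) == expected

    def test_square_cell_boundary_count_is_96(self, tiled_state):
        counts = cs.boundary_pixel_counts(tiled_state.labels)
        assert (counts[1:] == 96).all()


class TestMotilityBias:
    def test_zero_kappa_is_passive(self):
        assert cs.motility_bias(0.0, (1, 0), (3.7, -1.2)) == 0.0

    def test_orthogonal_displacement_is_unbiased(self):
        assert cs.motility_bias(1500.0, (1.0, 0.0), (0.0, 2.0)) == 0.0

    def test_gaining_one_pixel_along_polarity(self):
        # area-625 cell gains a pixel one unit along p: dR_x = 1/625
        assert cs.motility_bias(1500.0, (1.0, 0.0), (1.0 / 625.0, 0.0)) \
            == pytest.approx(-2.4)

    def test_com_oracle_for_gained_pixel(self):
        # recompute dR from the two pixel sets and check the bias value
        labels = np.ones((100, 100), dtype=np.int16)
        labels[20:45, 10:35] = 2   # 25x25 square cell

        before = cs.periodic_com(labels, 2)
        labels2 = labels.copy()
        labels2[32, 35] = 2        # gain one pixel to the right
        after = cs.periodic_com(labels2, 2)
        d_col = after[1] - before[1]
        bias = cs.motility_bias(1500.0, (1.0, 0.0), (d_col, 0.0))
        assert d_col == pytest.approx((35 - before[1]) / 626.0)
        assert bias == pytest.approx(-1500.0 * d_col)


# ---------------------------------------------- incremental vs global --

def _oracle_delta(state, i, sig_to):
    """Global-recompute oracle: H(after) - H(before) + motility bias,
    with COM displacements measured from the pixel sets."""
    cfg = state.config
    size = cfg.lattice_size
    labels = state.labels.copy()
    sig_from = int(labels.ravel()[i])
    after = labels.copy()
    after.ravel()[i] = sig_to
    dh = cs.hamiltonian(after, cfg) - cs.hamiltonian(labels, cfg)

    def min_image(d):
        return (d + size / 2) % size - size / 2
    for sig, sign in ((sig_to, 1), (sig_from, 1)):
        if sig == sig_from and not (after == sig).any():
            continue
        com_b = np.array(cs.periodic_com(labels, sig))
        com_a = np.array(cs.periodic_com(after, sig))
        d_row, d_col = min_image(com_a - com_b)
        kappa = state.kappa[sig]
        # polarity is stored as (x, y) = (col, row)
        dh += cs.motility_bias(kappa, (state.polx[sig], state.poly[sig]),
                               (d_col, d_row))
    return dh


def test_incremental_delta_matches_global_recompute_reference_terms():
    """>=1000 random moves on random confluent lattices: the adhesion +
    area + perimeter delta agrees with the from-scratch Hamiltonian
    difference to 1e-9.  Motility is off here because a scattered
    random 'cell' has no well-defined torus COM; the bias term is
    checked on compact cells below."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 1000:
        state = random_confluent_state(rng, kappa=0.0)
        flat = state.labels_flat
        for _ in range(60):
            i = int(rng.integers(flat.size))
            nbr = state.nbr4[i, int(rng.integers(4))]
            sig_to = int(flat[nbr])
            sig_from = int(flat[i])
            if sig_to == sig_from or state.area[sig_from] <= 1:
                continue
            incr = cs.delta_hamiltonian(state, i, sig_to)
            assert incr == pytest.approx(_oracle_delta(state, i, sig_to),
                                         abs=1e-9)
            checked += 1
    assert checked >= 1000


def test_incremental_delta_with_motility_on_compact_cells(
        small_equilibrated):
    """Full delta (including both cells' bias terms) vs the global
    oracle on an equilibrated state with localised cells."""
    state = small_equilibrated
    rng = np.random.default_rng(43)
    flat = state.labels_flat
    checked = 0
    while checked < 200:
        i = int(rng.integers(flat.size))
        nbr = state.nbr4[i, int(rng.integers(4))]
        sig_to = int(flat[nbr])
        sig_from = int(flat[i])
        if sig_to == sig_from or state.area[sig_from] <= 1:
            continue
        incr = cs.delta_hamiltonian(state, i, sig_to)
        assert incr == pytest.approx(_oracle_delta(state, i, sig_to),
                                     abs=1e-6)
        checked += 1


def test_same_label_copy_is_a_no_op(small_equilibrated):
    state = small_equilibrated
    i = 0
    sig = int(state.labels_flat[0])
    assert cs.delta_hamiltonian(state, i, sig) == pytest.approx(0.0)


def test_pixel_exchange_at_target_area_costs_two():
    # two cells at A_t exchanging one pixel: (A+1-At)^2 + (A-1-At)^2 = 2
    labels = np.ones((10, 10), dtype=np.int16)
    labels[:, 5:] = 2
    cfg = SimulationConfig(lattice_size=10, n_cells=2, target_area=50,
                           kappa_active=0.0, kappa_passive=0.0, n_active=0,
                           contact_energy=0.0, perimeter_threshold=100)
    types = np.array(["passive", "passive"], dtype=object)
    state = cs.SimulationState(labels, types, cfg,
                               np.random.default_rng(0))
    i = 4 + 10 * 3   # column 4 (cell 1) adjacent to column 5 (cell 2)
    assert cs.delta_hamiltonian(state, i, 2) == pytest.approx(2.0)


# --------------------------------------------------------- bookkeeping --

def test_bookkeeping_matches_from_scratch_after_run(small_equilibrated):
    state = small_equilibrated
    labels = state.labels
    n = state.config.n_cells
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    assert np.array_equal(areas[1:], state.area[1:])
    perims = cs.boundary_pixel_counts(labels)
    assert np.array_equal(perims[1:], state.perim[1:n + 1])
    for c in (1, 37, 144):
        row, col = cs.periodic_com(labels, c)
        size = state.size
        assert abs((state.comy[c] - row + size / 2) % size - size / 2) < 1e-6
        assert abs((state.comx[c] - col + size / 2) % size - size / 2) < 1e-6


def test_confluence_preserved(small_equilibrated):
    labels = small_equilibrated.labels
    assert labels.min() >= 1
    assert int(small_equilibrated.area[1:].sum()) == labels.size


def test_connectivity_preserved_everywhere(small_equilibrated):
    from scipy import ndimage
    labels = small_equilibrated.labels
    size = labels.shape[0]
    big = np.tile(labels, (2, 2))   # unwrap the torus into a 2x2 tile
    for c in range(1, 145):
        # periodic connectivity: the cell is connected on the torus iff
        # one component of the tiled mask contains the whole pixel count
        mask = big == c
        lab, n_comp = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, lab, index=range(1, n_comp + 1))
        assert sizes.max() >= (labels == c).sum()


# --------------------------------------------------------- connectivity --

def _two_cell_state(pixels, size=6):
    """Cell 1 occupies ``pixels`` (row, col); cell 2 fills the rest."""
    labels = np.full((size, size), 2, dtype=np.int16)
    for r, c in pixels:
        labels[r, c] = 1
    cfg = SimulationConfig(lattice_size=size, n_cells=2,
                           target_area=size * size // 2,
                           perimeter_threshold=50, n_active=0,
                           kappa_active=0.0, kappa_passive=0.0)
    types = np.array(["passive", "passive"], dtype=object)
    return cs.SimulationState(labels, types, cfg, np.random.default_rng(0))


class TestConnectivity:
    def test_corner_of_block_is_removable(self):
        state = _two_cell_state([(2, 2), (2, 3), (3, 2), (3, 3)])
        assert cs.connectivity_ok(state, 2 * 6 + 2)

    def test_middle_of_bar_splits_the_cell(self):
        state = _two_cell_state([(2, 1), (2, 2), (2, 3)])
        assert not cs.connectivity_ok(state, 2 * 6 + 2)
        assert cs.connectivity_ok(state, 2 * 6 + 1)

    def test_last_pixel_cannot_vanish(self):
        state = _two_cell_state([(2, 2)])
        assert not cs.connectivity_ok(state, 2 * 6 + 2)

    def test_u_shape_needs_the_exact_check(self):
        # locally ambiguous around (1,2): ends reconnect along the U
        pix = [(1, 1), (2, 1), (3, 1), (3, 2), (3, 3), (2, 3), (1, 3),
               (1, 2)]
        state = _two_cell_state(pix)
        assert cs.connectivity_ok(state, 1 * 6 + 2)


# ----------------------------------------------------------- metropolis --

class _ForcedRng:
    """Deterministic pixel/direction choice, real uniforms."""

    def __init__(self, i, d, seed=0):
        self._i = i
        self._d = d
        self._rng = np.random.default_rng(seed)
        self.calls = 0

    def integers(self, *a, **k):
        self.calls += 1
        return self._i if self.calls % 2 == 1 else self._d

    def random(self):
        return self._rng.random()


def test_metropolis_acceptance_rate_matches_boltzmann_factor():
    """A fixed uphill move with dH = T is accepted at rate e^-1."""
    labels = np.ones((10, 10), dtype=np.int16)
    labels[:, 5:] = 2
    cfg = SimulationConfig(lattice_size=10, n_cells=2, target_area=50,
                           contact_energy=0.0, perimeter_threshold=100,
                           kappa_active=0.0, kappa_passive=0.0, n_active=0,
                           temperature=2.0)
    types = np.array(["passive", "passive"], dtype=object)
    state = cs.SimulationState(labels, types, cfg, np.random.default_rng(0))
    i = 4 + 10 * 3
    assert cs.delta_hamiltonian(state, i, 2) == pytest.approx(2.0)  # = T
    rng = _ForcedRng(i=i, d=0, seed=123)   # neighbour East -> cell 2
    n_trials = 60_000
    accepted = 0
    for _ in range(n_trials):
        if cs.metropolis_attempt(state, rng):
            accepted += 1
            cs.apply_move(state, i, 1)     # undo to keep dH fixed
    rate = accepted / n_trials
    se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / n_trials)
    assert abs(rate - math.exp(-1)) < 5 * se


def test_downhill_moves_always_accepted():
    # losing cell larger than the gainer: the exchange lowers H_area
    labels = np.ones((10, 10), dtype=np.int16)
    labels[:, 6:] = 2
    cfg = SimulationConfig(lattice_size=10, n_cells=2, target_area=50,
                           contact_energy=0.0, perimeter_threshold=100,
                           kappa_active=0.0, kappa_passive=0.0, n_active=0,
                           temperature=0.5)
    types = np.array(["passive", "passive"], dtype=object)
    state = cs.SimulationState(labels, types, cfg, np.random.default_rng(0))
    i = 5 + 10 * 3
    assert cs.delta_hamiltonian(state, i, 2) == pytest.approx(-38.0)
    rng = _ForcedRng(i=i, d=0)
    assert cs.metropolis_attempt(state, rng)


def test_connectivity_violation_rejected_regardless_of_energy():
    state = _two_cell_state([(2, 1), (2, 2), (2, 3)])
    i = 2 * 6 + 2
    rng = _ForcedRng(i=i, d=0)
    assert not cs.metropolis_attempt(state, rng)
    assert state.labels[2, 2] == 1


# ------------------------------------------------------------- polarity --

def test_polarity_updates_are_bounded_and_unbiased():
    cfg = small_config(n_active=144, kappa_active=60.0)
    state = cs.initialize_tiling(cfg, np.random.default_rng(3))
    theta0 = state.theta[1:].copy()
    rng = np.random.default_rng(4)
    deltas = []
    for _ in range(200):
        prev = state.theta[1:].copy()
        cs.update_polarities(state, rng)
        step = state.theta[1:] - prev
        assert (np.abs(step) <= math.pi / 36 + 1e-12).all()
        deltas.append(step)
    drift = np.concatenate(deltas).mean()
    assert abs(drift) < 1e-3
    assert np.allclose(np.hypot(state.polx[1:], state.poly[1:]), 1.0)


def test_rotational_diffusion_constant_within_ten_percent():
    """The simulator's polarity angles diffuse with D_r = eta_max^2/6
    per MCS: Var(dtheta over m MCS) = 2 D_r m within 10%."""
    cfg = small_config(n_active=0, kappa_active=0.0, temperature=1e-3,
                       equilibration=0, n_snapshots=40, snapshot_interval=5,
                       rng_seed=13)
    snaps, _ = cs.simulate(cfg)
    theta = np.array([[c.polarity_angle for c in s.cells] for s in snaps])
    inc = np.diff(theta, axis=0).ravel()      # 39 x 144 increments of 5 MCS
    d_r = (math.pi / 36) ** 2 / 6.0
    expected = 2.0 * d_r * cfg.snapshot_interval
    assert abs(inc.var() - expected) / expected < 0.10


# ----------------------------------------------------- tiling & running --

class TestInitializeTiling:
    def test_default_geometry(self, tiled_state):
        assert tiled_state.config.n_cells == 144
        assert (tiled_state.area[1:] == 625).all()
        assert int(tiled_state.area[1:].sum()) == 300 * 300

    def test_requested_number_of_active_cells(self):
        cfg = small_config(n_active=15)
        state = cs.initialize_tiling(cfg, np.random.default_rng(9))
        assert (np.asarray(state.cell_types) == "active").sum() == 15

    def test_non_tileable_configuration_raises(self):
        cfg = SimulationConfig(lattice_size=300, n_cells=143,
                               target_area=625, n_active=1)
        with pytest.raises(ValueError, match="tileable"):
            cs.initialize_tiling(cfg, np.random.default_rng(0))


def test_simulation_is_deterministic_per_seed():
    cfg = small_config(n_active=15, rng_seed=77)
    snaps_a, _ = cs.simulate(cfg)
    snaps_b, _ = cs.simulate(cfg)
    for a, b in zip(snaps_a, snaps_b):
        assert np.array_equal(a.labels, b.labels)
        assert [c.polarity_angle for c in a.cells] == \
            [c.polarity_angle for c in b.cells]


def test_snapshot_times_follow_the_interval():
    cfg = small_config(n_snapshots=5, snapshot_interval=100)
    snaps, _ = cs.simulate(cfg)
    assert [s.mcs_time for s in snaps] == [100, 200, 300, 400, 500]


def test_energy_is_stationary_after_equilibration():
    """Passive layer: no monotone drift of the reference energy."""
    cfg = small_config(n_active=0, kappa_active=0.0, rng_seed=5)
    state = cs.initialize_tiling(cfg, np.random.default_rng(5))
    state.run(300)
    energies = []
    for _ in range(10):
        state.run(30)
        energies.append(cs.hamiltonian(state.labels, cfg))
    energies = np.asarray(energies)
    first, second = energies[:5].mean(), energies[5:].mean()
    spread = energies.std() + 1e-9
    assert abs(second - first) < 3 * spread


# ---------------------------------------------------------------- MSD --

def test_frozen_layer_has_vanishing_msd():
    cfg = small_config(n_active=0, kappa_active=0.0, temperature=1e-4,
                       n_snapshots=4, equilibration=10)
    _, traj = cs.simulate(cfg, record_trajectories=True)
    msd = cs.compute_msd(traj)
    assert msd["passive"]["msd"].max() < 1.0


def test_active_cells_diffuse_faster_than_passive():
    cfg = small_config(n_active=30, kappa_active=60.0, kappa_passive=6.0,
                       n_snapshots=12, equilibration=200, rng_seed=11)
    _, traj = cs.simulate(cfg, record_trajectories=True)
    msd = cs.compute_msd(traj)
    assert msd["active"]["diffusion"] > msd["passive"]["diffusion"]


def test_msd_requires_two_time_points():
    traj = cs.Trajectory(positions=np.zeros((1, 3, 2)), interval=100,
                         cell_types=np.array(["passive"] * 3))
    with pytest.raises(ValueError, match="short"):
        cs.compute_msd(traj)
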