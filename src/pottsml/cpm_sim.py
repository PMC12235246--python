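"""Cellular Potts model of a confluent layer with binary motility.

Cells are 4-connected pixel domains on a periodic square lattice, one
label per pixel (confluent: no medium).  Dynamics are Metropolis
Monte Carlo pixel-copy attempts against the Hamiltonian

    H = sum_{<i,j>} J (1 - delta(sigma_i, sigma_j))
      + lambda_A sum_s (A_s - A_t)^2
      + lambda_P sum_s [P_s > P_t] (P_s - P_t)^2

plus, per proposed move, a motility bias dH_mot = -kappa_a (p_s . dR_s)
for every cell whose centre of mass is displaced, where p_s is the
cell's polarity unit vector and dR_s its COM displacement.  Polarities
undergo rotational diffusion: theta += eta, eta ~ U(-eta_max, eta_max),
once per Monte Carlo step.

A "Monte Carlo step" (MCS) is lattice_size**2 attempts.  High-motility
("active") and low/zero-motility ("passive") cells differ only in kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import _kernel

__all__ = [
    "SimulationConfig", "CellState", "Snapshot", "SimulationState",
    "adhesion_energy", "area_energy", "perimeter_energy", "motility_bias",
    "hamiltonian", "delta_hamiltonian", "connectivity_ok",
    "boundary_pixel_counts", "initialize_tiling", "metropolis_attempt",
    "mcs_sweep", "update_polarities", "simulate", "compute_msd",
]

ACTIVE = "active"
PASSIVE = "passive"


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    Defaults reproduce the standard study conditions: a 300x300
    periodic lattice exactly tiled by 144 cells of target area 625,
    uniform adhesion J = 5, area stiffness 1, one-sided perimeter
    penalty above 150 boundary pixels, polarity noise eta_max = pi/36,
    snapshots every 1000 MCS.
    """

    lattice_size: int = 300
    periodic: bool = True
    n_cells: int = 144
    target_area: int = 625
    contact_energy: float = 5.0
    lambda_area: float = 1.0
    lambda_perimeter: float = 1.0
    perimeter_threshold: int = 150
    temperature: float = 5.0
    kappa_active: float = 1500.0
    kappa_passive: float = 0.0
    n_active: int = 1
    eta_max: float = math.pi / 36.0
    snapshot_interval: int = 1000
    equilibration: int = 10_000
    n_snapshots: int = 10
    adhesion_neighbour_order: int = 1
    copy_neighbour_order: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells * self.target_area > self.lattice_size ** 2:
            raise ValueError("n_cells * target_area exceeds the lattice")
        if not self.periodic:
            raise ValueError("only periodic lattices are supported")
        if not (0 <= self.n_active <= self.n_cells):
            raise ValueError("n_active must lie in [0, n_cells]")
        if self.kappa_active < self.kappa_passive or self.kappa_passive < 0:
            raise ValueError("require kappa_active >= kappa_passive >= 0")
        if self.eta_max <= 0 or self.temperature <= 0:
            raise ValueError("eta_max and temperature must be positive")
        if self.adhesion_neighbour_order not in (1, 2):
            raise ValueError("adhesion_neighbour_order must be 1 or 2")
        if self.copy_neighbour_order not in (1, 2):
            raise ValueError("copy_neighbour_order must be 1 or 2")

    @property
    def gamma(self) -> float | None:
        """Motility ratio kappa_passive / kappa_active (None if inactive)."""
        if self.kappa_active > 0:
            return self.kappa_passive / self.kappa_active
        return None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gamma"] = self.gamma
        return d


@dataclass
class CellState:
    sigma: int
    cell_type: str
    kappa: float
    polarity_angle: float
    area: int
    boundary_length: int
    com: tuple[float, float]

    @property
    def polarity(self) -> tuple[float, float]:
        return (math.cos(self.polarity_angle), math.sin(self.polarity_angle))


@dataclass
class Snapshot:
    """Label grid plus per-cell metadata at one stored MCS time."""
    mcs_time: int
    labels: np.ndarray          # (L, L) int array, 1-based cell ids
    cells: list[CellState]
    config: SimulationConfig | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def types(self) -> np.ndarray:
        return np.array([c.cell_type for c in self.cells])


# --------------------------------------------------------------- energy --

def _neighbour_shifts(order: int) -> list[tuple[int, int]]:
    # unique unordered pair directions; order 2 adds the diagonals
    shifts = [(0, 1), (1, 0)]
    if order == 2:
        shifts += [(1, 1), (1, -1)]
    return shifts


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] != labels.shape[1]:
        raise ValueError("label grid must be square")
    if (labels < 1).any():
        raise ValueError("invalid lattice: unlabelled pixel(s) present")
    return labels


def adhesion_energy(labels: np.ndarray, config: SimulationConfig) -> float:
    """Total contact energy J * #(distinct-cell neighbour pixel pairs)."""
    labels = _check_labels(labels)
    total = 0
    for dy, dx in _neighbour_shifts(config.adhesion_neighbour_order):
        total += int((labels != np.roll(labels, (dy, dx), axis=(0, 1))).sum())
    return config.contact_energy * total


def area_energy(areas: np.ndarray, config: SimulationConfig) -> float:
    areas = np.asarray(areas, dtype=float)
    return float(config.lambda_area * ((areas - config.target_area) ** 2).sum())


def perimeter_energy(boundary_lengths: np.ndarray,
                     config: SimulationConfig) -> float:
    """One-sided quadratic penalty, active only above the threshold."""
    p = np.asarray(boundary_lengths, dtype=float)
    excess = np.clip(p - config.perimeter_threshold, 0.0, None)
    return float(config.lambda_perimeter * (excess ** 2).sum())


def motility_bias(kappa: float, polarity: Sequence[float],
                  delta_com: Sequence[float]) -> float:
    """Energy bias -kappa (p . dR) for one cell's COM displacement."""
    return -kappa * (polarity[0] * delta_com[0] + polarity[1] * delta_com[1])


def boundary_pixel_counts(labels: np.ndarray) -> np.ndarray:
    """Boundary-pixel count per cell id (index 0 unused).

    A boundary pixel has at least one first-order neighbour with a
    different label; periodic wrapping applies.
    """
    labels = _check_labels(labels)
    boundary = np.zeros(labels.shape, dtype=bool)
    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        boundary |= labels != np.roll(labels, (dy, dx), axis=(0, 1))
    return np.bincount(labels[boundary].ravel(),
                       minlength=int(labels.max()) + 1)


def hamiltonian(labels: np.ndarray, config: SimulationConfig) -> float:
    """Reference Hamiltonian (no motility) recomputed from scratch."""
    labels = _check_labels(labels)
    areas = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)[1:]
    perims = boundary_pixel_counts(labels)[1:]
    return (adhesion_energy(labels, config) + area_energy(areas, config)
            + perimeter_energy(perims, config))


# ---------------------------------------------------------------- state --

class SimulationState:
    """Mutable simulator state bridging the config and the jit kernel."""

    def __init__(self, labels: np.ndarray, cell_types: np.ndarray,
                 config: SimulationConfig, rng: np.random.Generator):
        size = config.lattice_size
        labels = _check_labels(labels).astype(np.int16)
        if labels.shape != (size, size):
            raise ValueError("label grid does not match lattice_size")
        self.config = config
        self.size = size
        self.labels_flat = labels.ravel().copy()
        self.nbr4, self.nbr8 = _kernel.build_neighbour_tables(size)
        n = config.n_cells
        counts = np.bincount(self.labels_flat, minlength=n + 1)
        self.area = counts.astype(np.int64)
        self.perim = boundary_pixel_counts(labels).astype(np.int64)
        if self.perim.shape[0] < n + 1:
            self.perim = np.resize(self.perim, n + 1)
        self.comx = np.zeros(n + 1)
        self.comy = np.zeros(n + 1)
        for c in range(1, n + 1):
            cy, cx = periodic_com(labels, c)
            self.comx[c] = cx
            self.comy[c] = cy
        self.cell_types = cell_types
        self.kappa = np.zeros(n + 1)
        self.kappa[1:] = np.where(cell_types == ACTIVE,
                                  config.kappa_active, config.kappa_passive)
        self.theta = np.zeros(n + 1)
        self.theta[1:] = rng.uniform(0.0, 2.0 * math.pi, size=n)
        self.polx = np.cos(self.theta)
        self.poly = np.sin(self.theta)
        self.rng_state = _kernel.seed_state(
            int(rng.integers(0, 2 ** 62)))
        self.visited = np.zeros(size * size, dtype=np.int64)
        self.stack = np.zeros(size * size, dtype=np.int32)
        self.gen = np.zeros(1, dtype=np.int64)
        self.mcs_time = 0

    # -- views -----------------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.labels_flat.reshape(self.size, self.size)

    def cell_states(self) -> list[CellState]:
        out = []
        for c in range(1, self.config.n_cells + 1):
            out.append(CellState(
                sigma=c, cell_type=str(self.cell_types[c - 1]),
                kappa=float(self.kappa[c]),
                polarity_angle=float(self.theta[c]),
                area=int(self.area[c]), boundary_length=int(self.perim[c]),
                com=(float(self.comy[c] % self.size),
                     float(self.comx[c] % self.size))))
        return out

    def snapshot(self) -> Snapshot:
        return Snapshot(mcs_time=self.mcs_time, labels=self.labels.copy(),
                        cells=self.cell_states(), config=self.config)

    def run(self, n_mcs: int) -> int:
        cfg = self.config
        accepted = _kernel.run_mcs(
            self.labels_flat, self.nbr4, self.nbr8,
            self.area, self.perim, self.comx, self.comy,
            self.kappa, self.theta, self.polx, self.poly,
            self.rng_state, self.visited, self.stack, self.gen,
            n_mcs, self.size, cfg.contact_energy, cfg.target_area,
            cfg.lambda_area, cfg.lambda_perimeter,
            float(cfg.perimeter_threshold), cfg.temperature, cfg.eta_max,
            4 if cfg.copy_neighbour_order == 1 else 8,
            cfg.adhesion_neighbour_order)
        self.mcs_time += n_mcs
        return int(accepted)


def periodic_com(labels: np.ndarray, cell_id: int) -> tuple[float, float]:
    """Periodic-aware centre of mass (row, col) of one cell.

    Seam-shift method: anchor on one pixel, wrap every offset to the
    nearest image, average, wrap back into [0, L).
    """
    ys, xs = np.nonzero(labels == cell_id)
    if ys.size == 0:
        raise ValueError(f"unknown cell id {cell_id}")

    def axis_mean(v, size):
        d = (v - v[0] + size // 2) % size - size // 2
        return (v[0] + d.mean()) % size

    return (float(axis_mean(ys, labels.shape[0])),
            float(axis_mean(xs, labels.shape[1])))


# ------------------------------------------------------------ operations --

def initialize_tiling(config: SimulationConfig,
                      rng: np.random.Generator) -> SimulationState:
    """Exact confluent tiling of square cells; random active subset."""
    size = config.lattice_size
    side = math.isqrt(config.target_area)
    per_row = size // side
    if (side * side != config.target_area or per_row * side != size
            or per_row * per_row != config.n_cells):
        raise ValueError(
            "configuration is not exactly tileable by square cells")
    tile = np.arange(1, config.n_cells + 1,
                     dtype=np.int16).reshape(per_row, per_row)
    labels = np.kron(tile, np.ones((side, side), dtype=np.int16))
    types = np.full(config.n_cells, PASSIVE, dtype=object)
    active_ids = rng.choice(config.n_cells, size=config.n_active,
                            replace=False)
    types[active_ids] = ACTIVE
    return SimulationState(labels, types, config, rng)


def connectivity_ok(state: SimulationState, pixel_index: int) -> bool:
    """Would removing this pixel keep its cell connected and non-empty?"""
    state.gen[0] += 1
    return bool(_kernel.connectivity_ok_px(
        state.labels_flat, state.nbr4, state.nbr8, state.area,
        pixel_index, state.visited, state.stack, state.gen[0]))


def delta_hamiltonian(state: SimulationState, pixel_index: int,
                      sigma_to: int) -> float:
    """Incremental energy change (reference terms + motility bias)."""
    if int(state.labels_flat[pixel_index]) == sigma_to:
        return 0.0   # copying a cell's own label is a no-op
    cfg = state.config
    return float(_kernel.delta_hamiltonian_px(
        state.labels_flat, state.nbr4, state.nbr8, state.area,
        state.perim, state.comx, state.comy, state.kappa,
        state.polx, state.poly, pixel_index, sigma_to, state.size,
        cfg.contact_energy, cfg.target_area, cfg.lambda_area,
        cfg.lambda_perimeter, float(cfg.perimeter_threshold),
        cfg.adhesion_neighbour_order))


def apply_move(state: SimulationState, pixel_index: int,
               sigma_to: int) -> None:
    _kernel.apply_move(state.labels_flat, state.nbr4, state.area,
                       state.perim, state.comx, state.comy,
                       pixel_index, sigma_to, state.size)


def metropolis_attempt(state: SimulationState,
                       rng: np.random.Generator) -> bool:
    """One pixel-copy attempt with the Metropolis rule min(1, e^-dH/T)."""
    cfg = state.config
    n_px = state.size * state.size
    i = int(rng.integers(n_px))
    nn = 4 if cfg.copy_neighbour_order == 1 else 8
    d = int(rng.integers(nn))
    j = int(state.nbr4[i, d]) if d < 4 else int(state.nbr8[i, 2 * (d - 4) + 1])
    sig_to = int(state.labels_flat[j])
    if sig_to == state.labels_flat[i]:
        return False
    if not connectivity_ok(state, i):
        return False
    dh = delta_hamiltonian(state, i, sig_to)
    if dh <= 0.0 or rng.random() < math.exp(-dh / cfg.temperature):
        apply_move(state, i, sig_to)
        return True
    return False


def update_polarities(state: SimulationState,
                      rng: np.random.Generator) -> None:
    """Rotational diffusion: theta += eta, eta ~ U(-eta_max, eta_max)."""
    n = state.config.n_cells
    eta = rng.uniform(-state.config.eta_max, state.config.eta_max, size=n)
    state.theta[1:] += eta
    state.polx[1:] = np.cos(state.theta[1:])
    state.poly[1:] = np.sin(state.theta[1:])


def mcs_sweep(state: SimulationState, n_mcs: int = 1) -> int:
    """Run whole Monte Carlo steps through the compiled kernel."""
    return state.run(n_mcs)


def simulate(config: SimulationConfig,
             record_trajectories: bool = False):
    """Run equilibration then emit a snapshot every snapshot_interval MCS.

    Returns (snapshots, trajectory) where trajectory is the per-cell
    unwrapped COM time series sampled at every snapshot (None unless
    requested).
    """
    rng = np.random.default_rng(config.rng_seed)
    state = initialize_tiling(config, rng)
    state.run(config.equilibration)
    state.mcs_time = 0
    snapshots: list[Snapshot] = []
    size = config.lattice_size
    prev = np.stack([state.comx[1:], state.comy[1:]], axis=1).copy()
    unwrapped = prev.copy()
    traj = [] if record_trajectories else None
    for _ in range(config.n_snapshots):
        state.run(config.snapshot_interval)
        snapshots.append(state.snapshot())
        if record_trajectories:
            cur = np.stack([state.comx[1:], state.comy[1:]], axis=1)
            # COMs are stored wrapped; unwrap by minimum-image increments
            # (valid while per-interval displacement < size/2)
            unwrapped = unwrapped + (cur - prev + size / 2) % size - size / 2
            prev = cur.copy()
            traj.append(unwrapped.copy())
    trajectory = None
    if record_trajectories:
        trajectory = Trajectory(
            positions=np.stack(traj, axis=0),
            interval=config.snapshot_interval,
            cell_types=np.asarray(state.cell_types))
    return snapshots, trajectory


@dataclass
class Trajectory:
    """Unwrapped per-cell COM time series (T, C, 2), x then y."""
    positions: np.ndarray
    interval: int
    cell_types: np.ndarray


def compute_msd(trajectory: Trajectory) -> dict:
    """Time-origin-averaged MSD per cell type and a tail-fit D estimate.

    D is fitted on the last half of the lag axis via MSD = 4 D t + c.
    """
    pos = trajectory.positions
    n_t = pos.shape[0]
    if n_t < 2:
        raise ValueError("trajectory too short for an MSD")
    lags = np.arange(1, n_t)
    msd = np.empty((lags.size, pos.shape[1]))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        msd[k] = (d ** 2).sum(axis=2).mean(axis=0)
    out = {"lags_mcs": lags * trajectory.interval}
    for t in (ACTIVE, PASSIVE):
        mask = trajectory.cell_types == t
        if not mask.any():
            continue
        curve = msd[:, mask].mean(axis=1)
        tail = slice(max(1, lags.size // 2), None)
        coeff = np.polyfit(out["lags_mcs"][tail], curve[tail], 1)
        out[t] = {"msd": curve, "diffusion": float(coeff[0] / 4.0)}
    return out
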