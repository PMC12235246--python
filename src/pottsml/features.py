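"""Static per-cell feature extraction from labelled snapshots.

Input is a confluent integer label image (every pixel owned by a
cell); output is one row per cell with the 145-entry registry of
:mod:`pottsml.registry`: local shape, local structure (bond order
parameters and neighbour-distance moments), and neighbour
mean/max/min aggregates of the locals.  All geometry respects the
periodic boundary via minimum-image conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

from . import registry
from .cpm_sim import Snapshot, boundary_pixel_counts, periodic_com

__all__ = [
    "NeighbourGraph", "EllipseFit", "boundary_pixel_count",
    "center_of_mass_periodic", "build_neighbour_graph", "fit_ellipse",
    "alignment_components", "bond_order_psi", "neighbour_distance_moments",
    "aggregate_nonlocal", "extract_features",
]


# ---------------------------------------------------------------- types --

@dataclass
class NeighbourGraph:
    """First-order contact adjacency between cells.

    ``neighbours[c]`` lists the cells sharing at least one first-order
    pixel contact with cell c; ``contacts[c][k]`` is the number of
    contacting pixel pairs with the k-th listed neighbour.
    """

    neighbours: dict[int, np.ndarray]
    contacts: dict[int, np.ndarray]

    def degree(self, cell_id: int) -> int:
        return len(self.neighbours[cell_id])


@dataclass
class EllipseFit:
    semi_major: float
    semi_minor: float
    orientation: float      # radians in [0, pi)
    eccentricity: float     # in [0, 1)
    from_moments: bool = False   # True when the conic fit fell back


# ------------------------------------------------------------ geometry --

def _validate_confluent(labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label grid")
    n = int(labels.max())
    if labels.min() < 1:
        bad = np.argwhere(labels < 1)
        raise ValueError(
            f"snapshot not confluent: unlabelled pixels at {bad[:5].tolist()}")
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    missing = np.nonzero(counts[1:] == 0)[0] + 1
    if missing.size:
        raise ValueError(f"cell ids with no pixels: {missing.tolist()}")
    return n


def boundary_pixel_count(labels: np.ndarray, cell_id: int) -> int:
    """Number of the cell's pixels touching a different cell (order 1)."""
    counts = boundary_pixel_counts(labels)
    if cell_id < 1 or cell_id >= counts.size or not (labels == cell_id).any():
        raise ValueError(f"unknown cell id {cell_id}")
    return int(counts[cell_id])


def center_of_mass_periodic(labels: np.ndarray,
                            cell_id: int) -> tuple[float, float]:
    """Periodic-aware COM (row, col) of one cell."""
    return periodic_com(np.asarray(labels), cell_id)


def build_neighbour_graph(labels: np.ndarray) -> NeighbourGraph:
    """Adjacency from first-order cross-label pixel contacts.

    Two cells are neighbours when at least one pair of first-order
    neighbouring pixels carries their two labels (edge contact; pure
    corner contact does not count).
    """
    labels = np.asarray(labels)
    n = _validate_confluent(labels)
    pairs = []
    for dy, dx in ((0, 1), (1, 0)):
        rolled = np.roll(labels, (-dy, -dx), axis=(0, 1))
        mask = labels != rolled
        a = labels[mask]
        b = rolled[mask]
        pairs.append(np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1))
    if pairs:
        allp = np.concatenate(pairs, axis=0)
        key = allp[:, 0].astype(np.int64) * (n + 1) + allp[:, 1]
        uniq, counts = np.unique(key, return_counts=True)
        ga = (uniq // (n + 1)).astype(int)
        gb = (uniq % (n + 1)).astype(int)
    else:
        ga = gb = counts = np.empty(0, dtype=int)
    nbrs: dict[int, list] = {c: [] for c in range(1, n + 1)}
    cnts: dict[int, list] = {c: [] for c in range(1, n + 1)}
    for a, b, c in zip(ga, gb, counts):
        nbrs[a].append(b)
        cnts[a].append(int(c))
        nbrs[b].append(a)
        cnts[b].append(int(c))
    return NeighbourGraph(
        neighbours={c: np.asarray(v, dtype=int) for c, v in nbrs.items()},
        contacts={c: np.asarray(v, dtype=int) for c, v in cnts.items()})


def fit_ellipse(pixels: np.ndarray,
                boundary: np.ndarray | None = None) -> EllipseFit:
    """Least-squares ellipse through a cell's boundary pixels.

    ``pixels`` are (row, col) coordinates already unwrapped to a
    common image (no seam crossing); ``boundary`` optionally restricts
    the fit to the boundary subset.  Degenerate conic fits (too few
    points, hyperbolic solutions, wildly inconsistent axes) fall back
    to the equivalent ellipse of the second central moments, flagged
    via ``from_moments``.
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("empty pixel set")
    fit_pts = np.asarray(boundary, dtype=float) if boundary is not None \
        else pts
    span = math.sqrt(pts.shape[0])
    if fit_pts.shape[0] >= 5:
        # centre the points first: congruent pixel sets then yield
        # bit-identical fits (translation invariance), and the conic
        # solve is better conditioned
        centred = fit_pts - fit_pts.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = EllipseModel.from_estimate(centred[:, ::-1])  # (x, y)
        if model:
            a, b = (float(v) for v in model.axis_lengths)
            theta = float(model.theta)
            if b > a:
                a, b = b, a
                theta += math.pi / 2
            # reject degenerate fits: collapsed or implausibly large
            if b > 1e-3 and a < 20.0 * max(span, 1.0):
                ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
                return EllipseFit(float(a), float(b),
                                  _stable_orientation(theta, ecc),
                                  min(ecc, 1.0 - 1e-12), False)
    return _moment_ellipse(pts)


def _stable_orientation(theta: float, ecc: float) -> float:
    # a near-circular cell has no meaningful major axis; pin the angle
    # so the output is deterministic under point reordering
    if ecc < 1e-2:
        return 0.0
    return float(theta % math.pi)


def _central_moments(pts: np.ndarray) -> tuple[float, float, float]:
    d = pts - pts.mean(axis=0)
    # +1/12 per axis: variance of the unit pixel itself
    mu_rr = float((d[:, 0] ** 2).mean()) + 1.0 / 12.0
    mu_cc = float((d[:, 1] ** 2).mean()) + 1.0 / 12.0
    mu_rc = float((d[:, 0] * d[:, 1]).mean())
    return mu_rr, mu_cc, mu_rc


def _moment_ellipse(pts: np.ndarray) -> EllipseFit:
    mu_rr, mu_cc, mu_rc = _central_moments(pts)
    common = 0.5 * (mu_rr + mu_cc)
    diff = 0.5 * (mu_rr - mu_cc)
    disc = math.sqrt(diff ** 2 + mu_rc ** 2)
    l1 = common + disc
    l2 = max(common - disc, 1e-12)
    a = 2.0 * math.sqrt(l1)
    b = 2.0 * math.sqrt(l2)
    # orientation of the major axis, measured like the conic fit:
    # angle of the axis in (x, y) = (col, row) convention
    theta = 0.5 * math.atan2(2.0 * mu_rc, mu_cc - mu_rr)
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    return EllipseFit(float(a), float(b), _stable_orientation(theta, ecc),
                      min(ecc, 1.0 - 1e-12), True)


def alignment_components(orientation: float,
                         neighbour_orientations: np.ndarray
                         ) -> tuple[float, float]:
    """Nematic alignment of major axes with the neighbours.

    With dphi the angle between the cell's major axis and each
    neighbour's, returns (mean |cos dphi|, mean |sin dphi|); both lie
    in [0, 1] and are invariant under flipping any axis by pi.
    """
    nb = np.asarray(neighbour_orientations, dtype=float)
    if nb.size == 0:
        raise ValueError("cell has no neighbours")
    dphi = nb - orientation
    return float(np.abs(np.cos(dphi)).mean()), float(np.abs(np.sin(dphi)).mean())


def _min_image(vec: np.ndarray, size: int) -> np.ndarray:
    return (vec + size / 2.0) % size - size / 2.0


def bond_order_psi(cell_com: np.ndarray, neighbour_coms: np.ndarray,
                   n: int, size: int) -> float:
    """Bond orientational order parameter psi_n.

    psi_n = | mean_k exp(i n theta_k) | with theta_k the polar angle
    of the minimum-image vector to neighbour k's COM.
    """
    vecs = _min_image(np.atleast_2d(neighbour_coms) - cell_com, size)
    norms = np.hypot(vecs[:, 0], vecs[:, 1])
    if vecs.shape[0] == 0 or (norms == 0).any():
        raise ValueError("zero-length neighbour vector")
    ang = np.arctan2(vecs[:, 0], vecs[:, 1])  # angle in the (col,row) plane
    return float(np.abs(np.exp(1j * n * ang).mean()))


def neighbour_distance_moments(cell_com: np.ndarray,
                               neighbour_coms: np.ndarray,
                               size: int) -> tuple[float, float, float]:
    """(mean, raw second moment, std) of the neighbour COM distances."""
    vecs = _min_image(np.atleast_2d(neighbour_coms) - cell_com, size)
    d = np.hypot(vecs[:, 0], vecs[:, 1])
    if d.size == 0:
        raise ValueError("cell has no neighbours")
    m1 = float(d.mean())
    m2 = float((d ** 2).mean())
    return m1, m2, math.sqrt(max(0.0, m2 - m1 ** 2))


def aggregate_nonlocal(local: pd.DataFrame,
                       graph: NeighbourGraph) -> pd.DataFrame:
    """Neighbour mean/max/min of every aggregatable local feature.

    Rows are indexed by cell id; permutation of the neighbour lists
    does not change the result.
    """
    cols = [c for c in local.columns if c not in registry.NON_AGGREGATED]
    values = local[cols].to_numpy(dtype=float)
    idx = {c: k for k, c in enumerate(local.index)}
    out = {}
    means = np.empty((len(local), len(cols)))
    maxs = np.empty_like(means)
    mins = np.empty_like(means)
    for k, cell in enumerate(local.index):
        nb = graph.neighbours[cell]
        if nb.size == 0:
            raise ValueError(f"cell {cell} has no neighbours")
        rows = values[[idx[c] for c in nb]]
        means[k] = rows.mean(axis=0)
        maxs[k] = rows.max(axis=0)
        mins[k] = rows.min(axis=0)
    for agg, arr in (("mean", means), ("max", maxs), ("min", mins)):
        for j, base in enumerate(cols):
            out[f"nb_{agg}_{base}"] = arr[:, j]
    return pd.DataFrame(out, index=local.index)


# ------------------------------------------------------------- pipeline --

def _cell_pixel_lists(labels: np.ndarray, n: int):
    """Per-cell (rows, cols) pixel coordinates via one argsort pass."""
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=n + 1)
    size = labels.shape[1]
    ys, xs = np.divmod(order, size)
    splits = np.cumsum(counts)[:-1]
    ys_split = np.split(ys, splits)
    xs_split = np.split(xs, splits)
    return ys_split[1:], xs_split[1:]  # drop label 0 (empty)


def _unwrap(coords: np.ndarray, size: int) -> np.ndarray:
    """Shift periodic pixel coordinates into one connected image."""
    ref = coords[0]
    return ref + (coords - ref + size // 2) % size - size // 2


def extract_features(snapshot: Snapshot | np.ndarray,
                     subset: str | list[str] | None = None,
                     snapshot_id: int | None = None) -> pd.DataFrame:
    """One row per cell with the (optionally subset) feature registry.

    Accepts a Snapshot or a bare label grid.  The returned frame
    carries ``snapshot_id``, ``cell_id`` and (when metadata is
    available) ``true_type`` columns followed by the feature columns;
    it is deterministic given the labels.
    """
    if isinstance(snapshot, Snapshot):
        labels = np.asarray(snapshot.labels)
        types = {c.sigma: c.cell_type for c in snapshot.cells}
        snap_id = snapshot.mcs_time if snapshot_id is None else snapshot_id
    else:
        labels = np.asarray(snapshot)
        types = None
        snap_id = 0 if snapshot_id is None else snapshot_id
    n = _validate_confluent(labels)
    size = labels.shape[0]
    bcounts = boundary_pixel_counts(labels)
    graph = build_neighbour_graph(labels)

    boundary_mask = np.zeros(labels.shape, dtype=bool)
    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        boundary_mask |= labels != np.roll(labels, (dy, dx), axis=(0, 1))

    ys_list, xs_list = _cell_pixel_lists(labels, n)
    coms = np.empty((n, 2))
    local = {name: np.empty(n) for name in
             registry.LOCAL_SHAPE + registry.LOCAL_STRUCTURE}
    fits: list[EllipseFit] = []

    for k in range(n):
        ys = _unwrap(ys_list[k], size)
        xs = _unwrap(xs_list[k], size)
        pts = np.stack([ys, xs], axis=1).astype(float)
        com = pts.mean(axis=0) % size
        coms[k] = com
        area = float(pts.shape[0])
        perim = float(bcounts[k + 1])
        on_boundary = boundary_mask.ravel()[
            (ys_list[k] % size) * size + (xs_list[k] % size)]
        fit = fit_ellipse(pts, pts[on_boundary])
        fits.append(fit)
        a, b = fit.semi_major, fit.semi_minor
        mu_rr, mu_cc, mu_rc = _central_moments(pts)
        common = 0.5 * (mu_rr + mu_cc)
        disc = math.sqrt((0.5 * (mu_rr - mu_cc)) ** 2 + mu_rc ** 2)
        l1, l2 = common + disc, max(common - disc, 0.0)
        w = float(xs.max() - xs.min() + 1)
        h = float(ys.max() - ys.min() + 1)
        local["area"][k] = area
        local["boundary_length"][k] = perim
        local["semi_major"][k] = a
        local["semi_minor"][k] = b
        local["eccentricity"][k] = fit.eccentricity
        local["orientation"][k] = fit.orientation
        local["n_neighbours"][k] = graph.degree(k + 1)
        local["aspect_ratio"][k] = a / b
        local["elongation"][k] = 1.0 - b / a
        local["shape_index"][k] = perim / math.sqrt(area)
        local["circularity"][k] = 4.0 * math.pi * area / perim ** 2
        local["equivalent_diameter"][k] = 2.0 * math.sqrt(area / math.pi)
        local["radius_of_gyration"][k] = math.sqrt(mu_rr + mu_cc)
        local["moment_major"][k] = l1
        local["moment_minor"][k] = l2
        local["moment_anisotropy"][k] = (l1 - l2) / (l1 + l2)
        local["bbox_width"][k] = w
        local["bbox_height"][k] = h
        local["extent"][k] = area / (w * h)
        local["compactness"][k] = area / (math.pi * a * b)
        local["perimeter_area_ratio"][k] = perim / area

    orientations = np.array([f.orientation for f in fits])
    for k in range(n):
        nb = graph.neighbours[k + 1]
        par, perp = alignment_components(orientations[k],
                                         orientations[nb - 1])
        local["parallel_alignment"][k] = par
        local["perpendicular_alignment"][k] = perp
        nb_coms = coms[nb - 1]
        for order in registry.PSI_ORDERS:
            local[f"psi_{order}"][k] = bond_order_psi(
                coms[k], nb_coms, order, size)
        m1, m2, sd = neighbour_distance_moments(coms[k], nb_coms, size)
        local["nb_dist_mean"][k] = m1
        local["nb_dist_second_moment"][k] = m2
        local["nb_dist_std"][k] = sd

    local_df = pd.DataFrame(local, index=pd.RangeIndex(1, n + 1,
                                                       name="cell_id"))
    nonlocal_df = aggregate_nonlocal(local_df, graph)
    table = pd.concat([local_df, nonlocal_df], axis=1)
    table = table[list(registry.FEATURE_NAMES)]
    if not np.isfinite(table.to_numpy()).all():
        bad = table.columns[~np.isfinite(table.to_numpy()).all(axis=0)]
        raise FloatingPointError(f"non-finite feature(s): {list(bad)}")

    if subset is not None:
        cols = registry.SUBSETS[subset] if isinstance(subset, str) else subset
        table = table[cols]
    meta = pd.DataFrame({
        "snapshot_id": np.full(n, snap_id),
        "cell_id": np.arange(1, n + 1),
    }, index=table.index)
    if types is not None:
        meta["true_type"] = [types[c] for c in range(1, n + 1)]
    return pd.concat([meta, table], axis=1).reset_index(drop=True)
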