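"""The per-cell feature registry.

145 features in four groups:

* 23 local shape features - geometry of the cell's own pixel set
  (area, boundary length, fitted-ellipse axes, eccentricity, axis
  alignment with neighbours, neighbour count, and standard
  region-geometry descriptors).
* 14 local structure features - arrangement of the neighbouring cell
  centres (bond order parameters psi_2..psi_12 and the first moment,
  second moment and standard deviation of the neighbour distance).
* 66 non-local shape and 42 non-local structure features - the
  neighbour mean, maximum and minimum of every local feature except
  the major-axis orientation (a circular quantity whose plain average
  is ill-defined).

Non-local names are ``nb_mean_<base>``, ``nb_max_<base>``,
``nb_min_<base>``.
"""

from __future__ import annotations

from dataclasses import dataclass

LOCAL_SHAPE = [
    "area",                 # cell size: pixel count
    "boundary_length",      # pixels with a differently-labelled first-order neighbour
    "semi_major",           # fitted-ellipse semi-major axis a
    "semi_minor",           # fitted-ellipse semi-minor axis b
    "eccentricity",         # sqrt(1 - b^2/a^2)
    "orientation",          # major-axis angle, [0, pi)
    "parallel_alignment",   # mean |cos dphi| over neighbours
    "perpendicular_alignment",  # mean |sin dphi| over neighbours
    "n_neighbours",         # adjacent-cell count
    "aspect_ratio",         # a / b
    "elongation",           # 1 - b / a
    "shape_index",          # P / sqrt(A)
    "circularity",          # 4 pi A / P^2
    "equivalent_diameter",  # 2 sqrt(A / pi)
    "radius_of_gyration",   # sqrt(mu20 + mu02)
    "moment_major",         # larger eigenvalue of the central 2nd-moment tensor
    "moment_minor",         # smaller eigenvalue
    "moment_anisotropy",    # (l1 - l2) / (l1 + l2)
    "bbox_width",
    "bbox_height",
    "extent",               # A / (bbox_width * bbox_height)
    "compactness",          # A / (pi a b): area fill of the fitted ellipse
    "perimeter_area_ratio",  # P / A
]

PSI_ORDERS = tuple(range(2, 13))

LOCAL_STRUCTURE = [f"psi_{n}" for n in PSI_ORDERS] + [
    "nb_dist_mean",            # <d> over neighbour COM distances
    "nb_dist_second_moment",   # <d^2> (raw)
    "nb_dist_std",             # sqrt(<d^2> - <d>^2)
]

# orientation has no meaningful plain neighbour average; every other
# local feature is aggregated over the neighbours.
NON_AGGREGATED = {"orientation"}
AGGREGATES = ("mean", "max", "min")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str       # local_shape | local_structure | nonlocal_shape | nonlocal_structure
    base: str | None = None   # for non-local features: the local feature aggregated
    aggregate: str | None = None


def _build() -> list[FeatureDef]:
    defs = [FeatureDef(n, "local_shape") for n in LOCAL_SHAPE]
    defs += [FeatureDef(n, "local_structure") for n in LOCAL_STRUCTURE]
    for cat, names in (("nonlocal_shape", LOCAL_SHAPE),
                       ("nonlocal_structure", LOCAL_STRUCTURE)):
        for base in names:
            if base in NON_AGGREGATED:
                continue
            for agg in AGGREGATES:
                defs.append(FeatureDef(f"nb_{agg}_{base}", cat, base, agg))
    return defs


FEATURES: tuple[FeatureDef, ...] = tuple(_build())
FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
N_FEATURES = len(FEATURES)

CATEGORIES = ("local_shape", "local_structure",
              "nonlocal_shape", "nonlocal_structure")


def names_in(*categories: str) -> list[str]:
    return [f.name for f in FEATURES if f.category in categories]


#: the seven training subsets
SUBSETS: dict[str, list[str]] = {
    "all": list(FEATURE_NAMES),
    "shape": names_in("local_shape", "nonlocal_shape"),
    "local_shape": names_in("local_shape"),
    "nonlocal_shape": names_in("nonlocal_shape"),
    "structure": names_in("local_structure", "nonlocal_structure"),
    "local_structure": names_in("local_structure"),
    "nonlocal_structure": names_in("nonlocal_structure"),
}


def registry_dict() -> dict:
    """JSON-friendly description of every feature (for sidecar files)."""
    return {
        "n_features": N_FEATURES,
        "features": [
            {"name": f.name, "category": f.category,
             "base": f.base, "aggregate": f.aggregate}
            for f in FEATURES
        ],
        "subsets": {k: len(v) for k, v in SUBSETS.items()},
    }
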