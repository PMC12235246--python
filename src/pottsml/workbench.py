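"""I/O, experiment orchestration and reporting.

A snapshot archive is a directory with:

* ``labels_<mcs>.npz`` - the 16-bit label grid per stored MCS
  (compressed integer array),
* ``cells.csv`` - cell_id, type, kappa, polarity_angle per snapshot,
* ``run_meta.json`` - full configuration echo (including temperature
  and seed) plus per-file checksums.

Experiments (a set of simulation conditions -> feature tables ->
classifier runs) are described by a :class:`RunManifest` and executed
by :func:`run_experiment`; re-running an identical manifest gives
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features
from .cpm_sim import CellState, SimulationConfig, Snapshot, simulate

__all__ = [
    "write_snapshot_archive", "read_snapshot_archive", "RunManifest",
    "Condition", "simulate_condition", "extract_condition",
    "build_dataset", "run_experiment", "render_reports",
]


# -------------------------------------------------------------- archive --

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_snapshot_archive(path: str | Path, snapshots: list[Snapshot],
                           config: SimulationConfig) -> Path:
    """Write label grids, cells.csv and run_meta.json with checksums."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if config.n_cells > np.iinfo(np.uint16).max:
        raise ValueError("cell ids overflow 16-bit storage")
    files = {}
    rows = []
    for snap in snapshots:
        name = f"labels_{snap.mcs_time:08d}.npz"
        np.savez_compressed(path / name,
                            labels=snap.labels.astype(np.uint16))
        files[name] = _sha256(path / name)
        for c in snap.cells:
            rows.append({"snapshot_id": snap.mcs_time, "cell_id": c.sigma,
                         "type": c.cell_type, "kappa": c.kappa,
                         "polarity_angle": c.polarity_angle})
    pd.DataFrame(rows).to_csv(path / "cells.csv", index=False)
    files["cells.csv"] = _sha256(path / "cells.csv")
    meta = {"config": config.to_dict(), "files": files,
            "snapshot_times": [s.mcs_time for s in snapshots]}
    (path / "run_meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_snapshot_archive(path: str | Path,
                          verify: bool = True) -> list[Snapshot]:
    """Load an archive written by :func:`write_snapshot_archive`."""
    path = Path(path)
    meta_file = path / "run_meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing run_meta.json in {path}")
    meta = json.loads(meta_file.read_text())
    cfg_dict = {k: v for k, v in meta["config"].items() if k != "gamma"}
    config = SimulationConfig(**cfg_dict)
    if verify:
        for name, digest in meta["files"].items():
            actual = _sha256(path / name)
            if actual != digest:
                raise IOError(
                    f"checksum mismatch for {name}: archive corrupt "
                    f"(expected {digest[:12]}..., got {actual[:12]}...)")
    cells = pd.read_csv(path / "cells.csv")
    snapshots = []
    for t in meta["snapshot_times"]:
        labels = np.load(path / f"labels_{t:08d}.npz")["labels"].astype(
            np.int32)
        sub = cells[cells.snapshot_id == t]
        cell_states = [
            CellState(sigma=int(r.cell_id), cell_type=str(r.type),
                      kappa=float(r.kappa),
                      polarity_angle=float(r.polarity_angle),
                      area=0, boundary_length=0, com=(0.0, 0.0))
            for r in sub.itertuples()
        ]
        snapshots.append(Snapshot(mcs_time=int(t), labels=labels,
                                  cells=cell_states, config=config))
    return snapshots


# ------------------------------------------------------------ manifests --

@dataclass
class Condition:
    """One simulation condition of the study grid."""
    name: str
    n_active: int
    kappa_active: float
    kappa_passive: float = 0.0
    n_snapshots: int = 20
    seed: int = 0
    target_cells: int | None = None   # default: all balanced cells

    def config(self, base: SimulationConfig | None = None) -> SimulationConfig:
        base = base or SimulationConfig()
        return dataclasses.replace(
            base, n_active=self.n_active, kappa_active=self.kappa_active,
            kappa_passive=self.kappa_passive, n_snapshots=self.n_snapshots,
            rng_seed=self.seed)

    @property
    def gamma(self) -> float:
        return self.kappa_passive / self.kappa_active


@dataclass
class RunManifest:
    conditions: list[Condition]
    subset: str = "local_shape"
    n_networks: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    base_config: SimulationConfig = field(default_factory=SimulationConfig)


def simulate_condition(cond: Condition,
                       base: SimulationConfig | None = None
                       ) -> list[Snapshot]:
    snapshots, _ = simulate(cond.config(base))
    return snapshots


def extract_condition(snapshots: list[Snapshot]) -> list[pd.DataFrame]:
    return [features.extract_features(s, snapshot_id=k)
            for k, s in enumerate(snapshots)]


def build_dataset(cond: Condition,
                  base: SimulationConfig | None = None,
                  frames: list[pd.DataFrame] | None = None
                  ) -> classify.LabelledDataset:
    """simulate -> extract -> balance for one condition."""
    if frames is None:
        frames = extract_condition(simulate_condition(cond, base))
    target = cond.target_cells
    if target is None:
        target = sum(
            2 * min((f.true_type == "active").sum(),
                    (f.true_type == "passive").sum()) for f in frames)
    rng = np.random.default_rng(cond.seed + 7)
    return classify.assemble_dataset(
        frames, target, rng,
        condition={"name": cond.name, "n_active": cond.n_active,
                   "kappa_active": cond.kappa_active,
                   "kappa_passive": cond.kappa_passive,
                   "gamma": cond.gamma, "seed": cond.seed})


def run_experiment(manifest: RunManifest,
                   out_dir: str | Path | None = None) -> dict:
    """simulate -> extract -> train for every condition in the manifest.

    Returns (and optionally writes) a results tree with per-condition
    accuracies, confusion counts and the configuration echo.
    """
    results = {"subset": manifest.subset, "seed": manifest.seed,
               "base_config": manifest.base_config.to_dict(),
               "conditions": {}}
    for cond in manifest.conditions:
        t0 = time.time()
        try:
            ds = build_dataset(cond, manifest.base_config)
            tr, te = classify.split_train_test(
                ds, manifest.train_fraction, seed=manifest.seed)
            res = classify.train_ensemble(
                tr, te, manifest.subset,
                classify.MLPSpec(seed=manifest.seed), manifest.n_networks)
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in condition '{cond.name}': {exc}") from exc
        fn_rate, fp_rate = classify.confusion_analysis(res)
        results["conditions"][cond.name] = {
            "condition": dataclasses.asdict(cond),
            "n_cells": len(ds),
            "accuracies": res.accuracies.tolist(),
            "mean_accuracy": res.mean_accuracy,
            "std_accuracy": res.std_accuracy,
            "confusion": {"tp": res.tp, "tn": res.tn,
                          "fp": res.fp, "fn": res.fn},
            "fn_rate": fn_rate, "fp_rate": fp_rate,
            "wall_seconds": round(time.time() - t0, 2),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, indent=2))
    return results


# -------------------------------------------------------------- reports --

def render_reports(results: dict, out_dir: str | Path) -> list[Path]:
    """Accuracy tables and figures from a results tree."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results.get("conditions"):
        raise ValueError("empty results tree")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, r in results["conditions"].items():
        rows.append({"condition": name,
                     "n_active": r["condition"]["n_active"],
                     "gamma": (r["condition"]["kappa_passive"]
                               / r["condition"]["kappa_active"]),
                     "mean_accuracy": r["mean_accuracy"],
                     "std_accuracy": r["std_accuracy"],
                     "fn_rate": r["fn_rate"], "fp_rate": r["fp_rate"]})
    table = pd.DataFrame(rows).sort_values(["gamma", "n_active"])
    paths = [out / "accuracy_table.csv"]
    table.to_csv(paths[0], index=False)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for gamma, sub in table.groupby("gamma"):
        ax.errorbar(sub.n_active, sub.mean_accuracy, yerr=sub.std_accuracy,
                    marker="o", label=f"$\\gamma$ = {gamma:g}")
    ax.set_xlabel("number of active cells $N_a$")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0.4, 1.02)
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "accuracy_vs_na.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    gammas = sorted(table.gamma.unique())
    nas = sorted(table.n_active.unique())
    if len(gammas) > 1 and len(nas) > 1:
        grid = np.full((len(gammas), len(nas)), np.nan)
        for _, r in table.iterrows():
            grid[gammas.index(r.gamma), nas.index(r.n_active)] = \
                r.mean_accuracy
        fig, ax = plt.subplots(figsize=(5, 3.5))
        mesh = ax.pcolormesh(nas, gammas, grid, shading="nearest",
                             vmin=0.5, vmax=1.0)
        fig.colorbar(mesh, ax=ax, label="accuracy")
        ax.set_xlabel("$N_a$")
        ax.set_ylabel("$\\gamma$")
        fig.tight_layout()
        p = out / "accuracy_map.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
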