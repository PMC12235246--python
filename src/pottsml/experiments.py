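"""The reduced-scale study protocol: condition grid and headline
experiments.

The full study trains on 120 000 balanced cells per condition with 20
networks.  This module runs the same pipeline at a reduced scale
suited to a single CPU: ~900-1800 balanced cells per training
condition, 5-network ensembles, 3000 MCS of equilibration (the
reference energy is stationary well before that).  The ``scale``
parameter shrinks or grows every snapshot count proportionally.

Conditions (all on the default 300x300 lattice, 144 cells):

* active-passive mixtures, kappa_p = 0, kappa_a = 1500, N_a in
  {5, 15, 30, 60};
* finite-motility mixtures with kappa_p = 150: gamma = 0.1
  (kappa_a = 1500), gamma = 0.2 (750) and gamma = 0.4 (375).

Headline quantities:

* ``active_passive_floor``: min over N_a in {15, 60} of the mean test
  accuracy (local shape features, per-condition training);
* ``na_generalisation_floor``: a model trained at N_a = 15 evaluated
  at N_a in {5, 30, 60}, minimum accuracy;
* ``gamma_generalisation_floor``: trained at gamma = 0.2, tested on
  gamma = 0.1, minimum over N_a in {15, 30};
* ``gamma_mismatch_accuracy``: trained at gamma = 0.4, tested on
  gamma = 0.1 at N_a = 30 (the regime where transfer breaks down).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import classify
from .cpm_sim import SimulationConfig
from .workbench import Condition, build_dataset

__all__ = ["ReducedProtocol", "run_headline_experiments"]

SUBSET = "local_shape"

# snapshot counts at scale 1; training conditions get enough balanced
# cells (2 N_a per snapshot) for stable perceptron fits
_CONDITIONS = [
    # name,        n_active, kappa_a, kappa_p, snapshots
    ("ap_na5",     5,  1500.0,   0.0, 20),
    ("ap_na15",    15, 1500.0,   0.0, 30),
    ("ap_na30",    30, 1500.0,   0.0, 10),
    ("ap_na60",    60, 1500.0,   0.0, 12),
    ("g02_na15",   15,  750.0, 150.0, 30),
    ("g02_na30",   30,  750.0, 150.0, 16),
    ("g01_na15",   15, 1500.0, 150.0, 10),
    ("g01_na30",   30, 1500.0, 150.0, 8),
    ("g04_na30",   30,  375.0, 150.0, 16),
]


@dataclasses.dataclass
class ReducedProtocol:
    seed: int = 1
    scale: float = 1.0
    n_networks: int = 5
    equilibration: int = 3000
    temperature: float = 5.0

    def base_config(self) -> SimulationConfig:
        return dataclasses.replace(SimulationConfig(),
                                   equilibration=self.equilibration,
                                   temperature=self.temperature)

    def conditions(self) -> dict[str, Condition]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_CONDITIONS))
        out = {}
        for (name, na, ka, kp, snaps), child in zip(_CONDITIONS, children):
            out[name] = Condition(
                name=name, n_active=na, kappa_active=ka, kappa_passive=kp,
                n_snapshots=max(4, round(snaps * self.scale)),
                seed=int(child.generate_state(1)[0] % (2 ** 31 - 1)))
        return out

    def datasets(self, names=None) -> dict[str, classify.LabelledDataset]:
        base = self.base_config()
        conds = self.conditions()
        names = list(conds) if names is None else names
        return {n: build_dataset(conds[n], base) for n in names}


def run_headline_experiments(protocol: ReducedProtocol,
                             datasets: dict[str, classify.LabelledDataset]
                             ) -> dict:
    """Compute the four headline accuracies from prebuilt datasets."""
    spec = classify.MLPSpec(seed=protocol.seed)
    nn = protocol.n_networks
    seed = protocol.seed

    def transfer(train_name, test_name):
        return classify.generalisation_experiment(
            datasets[train_name], datasets[test_name], SUBSET, spec, nn,
            seed=seed)

    results: dict = {"per_condition": {}}

    # per-condition (train = test) accuracies for the active-passive grid
    for name in ("ap_na15", "ap_na60"):
        res = transfer(name, name)
        results["per_condition"][name] = {
            "mean_accuracy": res.mean_accuracy,
            "std_accuracy": res.std_accuracy,
            "n_cells": len(datasets[name]),
        }
    results["active_passive_floor"] = {
        "value": min(r["mean_accuracy"]
                     for r in results["per_condition"].values()),
        "n": sum(len(datasets[n]) for n in ("ap_na15", "ap_na60")),
    }

    # N_a generalisation: model trained at N_a = 15
    accs = {}
    for test_name in ("ap_na5", "ap_na30", "ap_na60"):
        accs[test_name] = transfer("ap_na15", test_name).mean_accuracy
    results["na_generalisation"] = accs
    results["na_generalisation_floor"] = {
        "value": min(accs.values()),
        "n": len(datasets["ap_na15"]),
    }

    # gamma generalisation: 0.2 -> 0.1 at N_a in {15, 30}
    g_accs = {
        "na15": transfer("g02_na15", "g01_na15").mean_accuracy,
        "na30": transfer("g02_na30", "g01_na30").mean_accuracy,
    }
    results["gamma_generalisation"] = g_accs
    results["gamma_generalisation_floor"] = {
        "value": min(g_accs.values()),
        "n": len(datasets["g02_na15"]) + len(datasets["g02_na30"]),
    }

    # gamma mismatch: 0.4 -> 0.1 at N_a = 30
    res = transfer("g04_na30", "g01_na30")
    results["gamma_mismatch_accuracy"] = {
        "value": res.mean_accuracy,
        "n": len(datasets["g04_na30"]),
    }
    return results
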