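"""Balanced dataset assembly and perceptron classification of motility.

The classifier is a single-hidden-layer perceptron (hidden width equal
to the number of input features, ADAM updates).  Accuracy is the
fraction of correct predictions on a held-out test split; reported
numbers average an ensemble of independently initialised networks.
Datasets are balanced per snapshot by keeping every minority-class
cell and an equal-size random subset of the majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from . import registry

__all__ = [
    "MLPSpec", "LabelledDataset", "EnsembleResult", "AccuracyMap",
    "balance_snapshot", "assemble_dataset", "split_train_test",
    "train_ensemble", "feature_subset_experiment", "confusion_analysis",
    "generalisation_experiment", "accuracy_map",
]

LABEL_COLUMN = "true_type"
ACTIVE, PASSIVE = "active", "passive"


@dataclass
class MLPSpec:
    """Perceptron hyperparameters; hidden width tracks the input size."""
    activation: str = "relu"
    learning_rate: float = 1e-3
    max_epochs: int = 300
    tolerance: float = 1e-4
    seed: int = 0

    def build(self, n_features: int, seed: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(n_features,),
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate,
            max_iter=self.max_epochs,
            tol=self.tolerance,
            random_state=seed,
        )


@dataclass
class LabelledDataset:
    """Feature matrix + binary labels (active=1) with provenance."""
    X: pd.DataFrame
    y: np.ndarray
    provenance: pd.DataFrame   # snapshot_id, cell_id, condition fields
    condition: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)

    def select(self, columns: list[str]) -> "LabelledDataset":
        return replace(self, X=self.X[columns])


@dataclass
class EnsembleResult:
    accuracies: np.ndarray     # one per network
    tp: int                    # active predicted active
    tn: int
    fp: int                    # passive predicted active (pooled)
    fn: int                    # active predicted passive (pooled)
    n_test: int
    subset: str | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))


# ------------------------------------------------------------- datasets --

def balance_snapshot(frame: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Balance one snapshot's cells by subsampling the majority class."""
    labels = frame[LABEL_COLUMN]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("snapshot contains a single motility class")
    n_min = labels.value_counts().min()
    parts = []
    for cls in (ACTIVE, PASSIVE):
        rows = frame[labels == cls]
        if len(rows) > n_min:
            keep = rng.choice(len(rows), size=n_min, replace=False)
            rows = rows.iloc[np.sort(keep)]
        parts.append(rows)
    return pd.concat(parts, axis=0)


def assemble_dataset(frames, target_total: int,
                     rng: np.random.Generator,
                     condition: dict | None = None) -> LabelledDataset:
    """Concatenate balanced per-snapshot subsets up to ``target_total``.

    ``frames`` is an iterable of per-snapshot feature tables (as
    produced by :func:`pottsml.features.extract_features`).  Raises if
    the stream is exhausted before the target is met.
    """
    if target_total % 2:
        raise ValueError("target_total must be even (half per class)")
    rows: list[pd.DataFrame] = []
    total = 0
    used = 0
    for frame in frames:
        if total >= target_total:
            break
        bal = balance_snapshot(frame, rng)
        need = target_total - total
        if len(bal) > need:
            # trim the last snapshot class-pairwise to keep exact balance
            keep = need // 2
            bal = pd.concat([bal[bal[LABEL_COLUMN] == cls].iloc[:keep]
                             for cls in (ACTIVE, PASSIVE)])
        rows.append(bal)
        total += len(bal)
        used += 1
    if total < target_total:
        raise ValueError(
            f"insufficient snapshots: {total} < {target_total} cells")
    data = pd.concat(rows, axis=0).reset_index(drop=True)
    meta_cols = [c for c in data.columns
                 if c not in registry.FEATURE_NAMES]
    y = (data[LABEL_COLUMN] == ACTIVE).to_numpy(dtype=int)
    cond = dict(condition or {})
    cond["snapshots_used"] = used
    return LabelledDataset(
        X=data[[c for c in data.columns if c in registry.FEATURE_NAMES]],
        y=y, provenance=data[meta_cols], condition=cond)


def split_train_test(dataset: LabelledDataset, fraction: float = 0.8,
                     seed: int = 0):
    """Stratified random split into (train, test) datasets."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=dataset.y)
    def take(ii):
        return LabelledDataset(dataset.X.iloc[ii].reset_index(drop=True),
                               dataset.y[ii],
                               dataset.provenance.iloc[ii].reset_index(drop=True),
                               dict(dataset.condition))
    return take(train_idx), take(test_idx)


# ------------------------------------------------------------- training --

def train_ensemble(train: LabelledDataset, test: LabelledDataset,
                   subset: str | list[str] | None = None,
                   spec: MLPSpec | None = None,
                   n_networks: int = 20) -> EnsembleResult:
    """Train independently seeded perceptrons; report test accuracies.

    Features are standardised with train-set statistics only.  The
    pooled confusion counts follow the convention FP = passive called
    active, FN = active called passive.
    """
    spec = spec or MLPSpec()
    if subset is None:
        cols = list(train.X.columns)
    elif isinstance(subset, str):
        cols = registry.SUBSETS[subset]
    else:
        cols = list(subset)
    missing = set(cols) - set(train.X.columns)
    if missing or set(cols) - set(test.X.columns):
        raise ValueError(f"feature columns missing: {sorted(missing)}")
    scaler = StandardScaler().fit(train.X[cols].to_numpy())
    Xtr = scaler.transform(train.X[cols].to_numpy())
    Xte = scaler.transform(test.X[cols].to_numpy())
    accs = []
    tp = tn = fp = fn = 0
    for k in range(n_networks):
        net = spec.build(len(cols), seed=spec.seed + 1000 * k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(Xtr, train.y)
        if net.n_iter_ >= spec.max_epochs:
            warnings.warn(
                f"network {k} hit the epoch cap ({spec.max_epochs}) "
                "before converging; result kept", RuntimeWarning)
        pred = net.predict(Xte)
        accs.append(float((pred == test.y).mean()))
        tp += int(((pred == 1) & (test.y == 1)).sum())
        tn += int(((pred == 0) & (test.y == 0)).sum())
        fp += int(((pred == 1) & (test.y == 0)).sum())
        fn += int(((pred == 0) & (test.y == 1)).sum())
    return EnsembleResult(np.asarray(accs), tp, tn, fp, fn,
                          n_test=len(test.y) * n_networks,
                          subset=subset if isinstance(subset, str) else None)


def feature_subset_experiment(train: LabelledDataset, test: LabelledDataset,
                              spec: MLPSpec | None = None,
                              n_networks: int = 20,
                              subsets: tuple[str, ...] = tuple(registry.SUBSETS),
                              ) -> dict[str, EnsembleResult]:
    """The seven-network comparison over the registry subsets."""
    return {name: train_ensemble(train, test, name, spec, n_networks)
            for name in subsets}


def confusion_analysis(result: EnsembleResult) -> tuple[float, float]:
    """(fn_rate, fp_rate): missed actives and false alarms.

    fn_rate = FN / (FN + TP), fp_rate = FP / (FP + TN).
    """
    if result.n_test == 0:
        raise ValueError("empty test set")
    fn_rate = result.fn / max(result.fn + result.tp, 1)
    fp_rate = result.fp / max(result.fp + result.tn, 1)
    return float(fn_rate), float(fp_rate)


def generalisation_experiment(train_cond: LabelledDataset,
                              test_cond: LabelledDataset,
                              subset: str | list[str] | None = None,
                              spec: MLPSpec | None = None,
                              n_networks: int = 20,
                              fraction: float = 0.8,
                              seed: int = 0) -> EnsembleResult:
    """Train on condition A, evaluate on condition B's test split.

    With A is B this reduces to the standard single-condition
    pipeline (same splits, same seeds).
    """
    train_a, test_a = split_train_test(train_cond, fraction, seed)
    if test_cond is train_cond:
        test_b = test_a
    else:
        _, test_b = split_train_test(test_cond, fraction, seed)
    return train_ensemble(train_a, test_b, subset, spec, n_networks)


@dataclass
class AccuracyMap:
    """Mean accuracy on a (gamma, N_a) grid with a linear interpolant."""
    gammas: np.ndarray
    n_actives: np.ndarray
    accuracy: np.ndarray       # shape (len(gammas), len(n_actives))
    missing: list = field(default_factory=list)

    def interpolate(self, gamma: float, n_active: float) -> float:
        interp = RegularGridInterpolator(
            (self.gammas, self.n_actives), self.accuracy,
            method="linear", bounds_error=True)
        return float(interp((gamma, n_active)))


def accuracy_map(datasets: dict[tuple[float, int], LabelledDataset],
                 subset: str | list[str] | None = "local_shape",
                 spec: MLPSpec | None = None,
                 n_networks: int = 20,
                 fraction: float = 0.8,
                 seed: int = 0) -> AccuracyMap:
    """Mean test accuracy per (gamma, N_a) node, trained per node."""
    gammas = sorted({g for g, _ in datasets})
    nas = sorted({n for _, n in datasets})
    acc = np.full((len(gammas), len(nas)), np.nan)
    missing = []
    for i, g in enumerate(gammas):
        for j, na in enumerate(nas):
            ds = datasets.get((g, na))
            if ds is None:
                missing.append((g, na))
                continue
            tr, te = split_train_test(ds, fraction, seed)
            acc[i, j] = train_ensemble(tr, te, subset, spec,
                                       n_networks).mean_accuracy
    return AccuracyMap(np.asarray(gammas, dtype=float),
                       np.asarray(nas, dtype=float), acc, missing)
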