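"""Feature-importance analyses: Shapley attributions and PCA.

The Shapley explainer is interventional: the contribution of a
coalition S is the model's mean output when the features in S come
from the explained row and the rest from a background sample.  For
small feature counts every coalition is enumerated and the resulting
constrained weighted regression recovers the exact Shapley values;
for larger inputs coalitions are subsampled (the Shapley kernel
weights and the sum-to-prediction constraint are kept, so additivity
holds by construction).  A permutation-importance fallback is
provided for quick rankings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import registry
from .classify import (EnsembleResult, LabelledDataset, MLPSpec,
                       train_ensemble)

__all__ = [
    "ImportanceReport", "ShapleyExplanation", "EnsemblePredictor",
    "shap_rank", "shapley_values", "permutation_importance",
    "pca_select", "retrain_on_selection",
]


class EnsemblePredictor:
    """Mean active-class probability of an ensemble of fitted nets.

    Bundles the scaler and the networks so explanations operate on
    raw (unstandardised) feature rows.
    """

    def __init__(self, scaler: StandardScaler, nets: list, columns: list[str]):
        self.scaler = scaler
        self.nets = nets
        self.columns = columns

    @classmethod
    def fit(cls, train: LabelledDataset, subset=None,
            spec: MLPSpec | None = None,
            n_networks: int = 5) -> "EnsemblePredictor":
        spec = spec or MLPSpec()
        if subset is None:
            cols = list(train.X.columns)
        else:
            cols = registry.SUBSETS[subset] if isinstance(subset, str) \
                else list(subset)
        scaler = StandardScaler().fit(train.X[cols].to_numpy())
        X = scaler.transform(train.X[cols].to_numpy())
        nets = []
        import warnings
        from sklearn.exceptions import ConvergenceWarning
        for k in range(n_networks):
            net = spec.build(len(cols), seed=spec.seed + 1000 * k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(X, train.y)
            nets.append(net)
        return cls(scaler, nets, cols)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        return np.mean([n.predict_proba(Xs)[:, 1] for n in self.nets],
                       axis=0)


@dataclass
class ShapleyExplanation:
    values: np.ndarray          # (n_rows, n_features)
    base_value: float           # mean model output on the background
    predictions: np.ndarray     # model output per explained row
    columns: list[str]

    def additivity_residual(self) -> np.ndarray:
        return self.predictions - (self.base_value
                                   + self.values.sum(axis=1))


@dataclass
class ImportanceReport:
    ranking: pd.DataFrame       # feature, score, category, rank
    method: str
    selection: list[str]
    retrained: EnsembleResult | None = None
    reference: EnsembleResult | None = None
    details: dict = field(default_factory=dict)


# ------------------------------------------------------------- Shapley --

def _kernel_weights(m: int, sizes: np.ndarray) -> np.ndarray:
    # log space: binomials overflow already for ~60 features, and only
    # relative weights matter for the weighted regression
    lw = np.empty(sizes.shape, dtype=float)
    for k, s in enumerate(sizes):
        s = int(s)
        log_comb = (math.lgamma(m + 1) - math.lgamma(s + 1)
                    - math.lgamma(m - s + 1))
        lw[k] = math.log(m - 1) - log_comb - math.log(s) - math.log(m - s)
    return np.exp(lw - lw.max())


def _coalitions(m: int, max_exact: int, rng: np.random.Generator,
                n_samples: int) -> np.ndarray:
    if 2 ** m - 2 <= max_exact:
        rows = [[(mask >> j) & 1 for j in range(m)]
                for mask in range(1, 2 ** m - 1)]
        return np.asarray(rows, dtype=bool)
    # sample subset sizes with the Shapley kernel distribution
    sizes = np.arange(1, m)
    pk = (m - 1) / (sizes * (m - sizes))
    pk = pk / pk.sum()
    out = np.zeros((n_samples, m), dtype=bool)
    draw = rng.choice(sizes, size=n_samples, p=pk)
    for r, s in enumerate(draw):
        out[r, rng.choice(m, size=s, replace=False)] = True
    return out


def shapley_values(predict, rows: np.ndarray, background: np.ndarray,
                   rng: np.random.Generator | None = None,
                   max_exact: int = 2048,
                   n_samples: int = 2048) -> ShapleyExplanation:
    """Interventional Shapley values of ``predict`` for each row.

    ``predict`` maps an (n, m) matrix to n outputs.  Masked features
    are replaced by every background row in turn and the outputs
    averaged.  The constrained weighted regression on the coalition
    outputs yields the Shapley values; with full enumeration
    (2^m - 2 <= max_exact) they are exact.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background sample is empty")
    rng = rng or np.random.default_rng(0)
    n_rows, m = rows.shape
    Z = _coalitions(m, max_exact, rng, n_samples)
    sizes = Z.sum(axis=1)
    w = _kernel_weights(m, sizes)
    base = float(predict(background).mean())
    preds = predict(rows)
    values = np.empty((n_rows, m))
    nb = background.shape[0]
    for r in range(n_rows):
        # model output per coalition, averaged over the background
        stacked = np.repeat(background[None, :, :], Z.shape[0], axis=0)
        stacked[:, :, :] = np.where(Z[:, None, :], rows[r][None, None, :],
                                    stacked)
        out = predict(stacked.reshape(-1, m)).reshape(Z.shape[0], nb)
        v = out.mean(axis=1) - base
        total = preds[r] - base
        # weighted LSQ with sum(phi) = total enforced by substitution
        A = Z[:, :-1].astype(float) - Z[:, [-1]].astype(float)
        b = v - Z[:, -1].astype(float) * total
        sw = np.sqrt(w)
        phi_part, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
        phi = np.empty(m)
        phi[:-1] = phi_part
        phi[-1] = total - phi_part.sum()
        values[r] = phi
    return ShapleyExplanation(values, base, preds, [])


def shap_rank(predictor: EnsemblePredictor, background: pd.DataFrame,
              evaluate: pd.DataFrame,
              rng: np.random.Generator | None = None,
              max_exact: int = 2048, n_samples: int = 2048
              ) -> tuple[pd.DataFrame, ShapleyExplanation]:
    """Mean |Shapley value| per feature over the evaluated rows."""
    cols = predictor.columns
    expl = shapley_values(predictor, evaluate[cols].to_numpy(),
                          background[cols].to_numpy(), rng,
                          max_exact, n_samples)
    expl.columns = cols
    score = np.abs(expl.values).mean(axis=0)
    cats = {f.name: f.category for f in registry.FEATURES}
    rank = pd.DataFrame({
        "feature": cols,
        "score": score,
        "category": [cats.get(c, "custom") for c in cols],
    }).sort_values("score", ascending=False).reset_index(drop=True)
    rank["rank"] = np.arange(1, len(rank) + 1)
    return rank, expl


def permutation_importance(predictor: EnsemblePredictor,
                           X: pd.DataFrame, y: np.ndarray,
                           rng: np.random.Generator | None = None,
                           n_repeats: int = 3) -> pd.DataFrame:
    """Accuracy drop when one column is shuffled (fallback ranking)."""
    rng = rng or np.random.default_rng(0)
    cols = predictor.columns
    Xv = X[cols].to_numpy(dtype=float)
    base = float(((predictor(Xv) > 0.5).astype(int) == y).mean())
    drops = np.zeros(len(cols))
    for j in range(len(cols)):
        for _ in range(n_repeats):
            Xp = Xv.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            acc = float(((predictor(Xp) > 0.5).astype(int) == y).mean())
            drops[j] += (base - acc) / n_repeats
    cats = {f.name: f.category for f in registry.FEATURES}
    rank = pd.DataFrame({
        "feature": cols, "score": drops,
        "category": [cats.get(c, "custom") for c in cols],
    }).sort_values("score", ascending=False).reset_index(drop=True)
    rank["rank"] = np.arange(1, len(rank) + 1)
    return rank


# ----------------------------------------------------------------- PCA --

def pca_select(dataset: LabelledDataset, k: int | None = None,
               variance_threshold: float = 0.95,
               seed: int = 0):
    """Principal components of the standardised feature matrix.

    Returns (pca, scaler, transformed LabelledDataset) where the
    transformed dataset keeps the leading components covering
    ``variance_threshold`` of the variance (or exactly ``k``).
    """
    X = dataset.X.to_numpy(dtype=float)
    if k is not None and k > X.shape[1]:
        raise ValueError(f"k={k} exceeds n_features={X.shape[1]}")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    pca = PCA(n_components=None, random_state=seed).fit(Xs)
    if k is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_threshold) + 1)
    Xt = pca.transform(Xs)[:, :k]
    cols = [f"pc_{j + 1}" for j in range(k)]
    new = LabelledDataset(pd.DataFrame(Xt, columns=cols), dataset.y,
                          dataset.provenance, dict(dataset.condition))
    return pca, scaler, new


# ------------------------------------------------------------- retrain --

def retrain_on_selection(train: LabelledDataset, test: LabelledDataset,
                         selection: list[str],
                         spec: MLPSpec | None = None,
                         n_networks: int = 5) -> EnsembleResult:
    """Delegate to the standard pipeline on a reduced design matrix."""
    if not selection:
        raise ValueError("empty feature selection")
    return train_ensemble(train, test, list(selection), spec, n_networks)
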