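"""Pluggable base learners behind the cascade architectures.

Families:

* ``rf_classifier`` / ``rf_regressor`` — scikit-learn random forests.
* ``xgb_regressor`` — gradient-boosted trees (scikit-learn
  ``GradientBoostingRegressor``; exposes n_estimators, max_depth, learning
  rate, row subsample and column subsample knobs).
* ``ann_regressor`` — :class:`TwoLayerMLPRegressor`, a numpy implementation
  of a two-hidden-layer perceptron with per-layer dropout, a
  {tanh, swish, linear, relu} activation menu, the Adam optimizer and mean
  absolute error loss.

``default_search_spaces`` mirrors the published hyperparameter grids (trees
50..1000 step 50, depth <= 31, node counts 5..150 step 5, dropout
{0.1, 0.3, 0.5}, learning rates per family); ``small_search_spaces`` is a
budget-friendly shrink for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)

__all__ = [
    "LearnerSpec",
    "build_estimator",
    "TwoLayerMLPRegressor",
    "default_search_spaces",
    "small_search_spaces",
]

LEARNER_FAMILIES = ("rf_classifier", "rf_regressor", "xgb_regressor",
                    "ann_regressor")


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of one cascade component."""

    family: str
    feature_subset: str = "FS-1"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; "
                             f"expected one of {LEARNER_FAMILIES}")

    def with_params(self, params: dict) -> "LearnerSpec":
        merged = {**self.hyperparameters, **params}
        return LearnerSpec(self.family, self.feature_subset, merged, self.seed)


# ---------------------------------------------------------------------------
# numpy two-hidden-layer perceptron
# ---------------------------------------------------------------------------

def _swish(x):
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return x * sig


def _swish_grad(x):
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return sig * (1.0 + x * (1.0 - sig))


_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
    "swish": (_swish, _swish_grad),
}


class TwoLayerMLPRegressor(BaseEstimator, RegressorMixin):
    """Two-hidden-layer perceptron trained with Adam on MAE loss.

    Dropout is applied per hidden layer during training (inverted dropout,
    inactive at predict time).  Deterministic for a fixed ``seed``.
    """

    def __init__(self, hidden1=32, hidden2=32, activation1="relu",
                 activation2="relu", dropout1=0.0, dropout2=0.0,
                 learning_rate=0.001, epochs=150, batch_size=32, seed=0):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.activation1 = activation1
        self.activation2 = activation2
        self.dropout1 = dropout1
        self.dropout2 = dropout2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def _init_weights(self, n_in, rng):
        sizes = [n_in, int(self.hidden1), int(self.hidden2), 1]
        weights, biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / a)
            weights.append(rng.normal(0.0, scale, (a, b)))
            biases.append(np.zeros(b))
        return weights, biases

    def fit(self, X, y):
        for act in (self.activation1, self.activation2):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        W, b = self._init_weights(X.shape[1], rng)
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        acts = [_ACTIVATIONS[self.activation1], _ACTIVATIONS[self.activation2]]
        drops = [float(self.dropout1), float(self.dropout2)]
        n = X.shape[0]
        batch = max(1, min(int(self.batch_size), n))
        step = 0
        for _ in range(int(self.epochs)):
            perm = rng.permutation(n)
            for start in range(0, n, batch):
                idx = perm[start:start + batch]
                xb, yb = X[idx], y[idx]
                # forward
                zs, hs, masks = [], [xb], []
                h = xb
                for layer in range(2):
                    z = h @ W[layer] + b[layer]
                    h = acts[layer][0](z)
                    if drops[layer] > 0:
                        mask = (rng.random(h.shape) >= drops[layer]) / (1 - drops[layer])
                        h = h * mask
                    else:
                        mask = None
                    zs.append(z)
                    hs.append(h)
                    masks.append(mask)
                yhat = (h @ W[2] + b[2]).ravel()
                # backward (MAE)
                delta = (np.sign(yhat - yb) / len(yb))[:, None]
                grads_W = [None, None, None]
                grads_b = [None, None, None]
                grads_W[2] = hs[2].T @ delta
                grads_b[2] = delta.sum(axis=0)
                upstream = delta @ W[2].T
                for layer in (1, 0):
                    if masks[layer] is not None:
                        upstream = upstream * masks[layer]
                    dz = upstream * acts[layer][1](zs[layer])
                    grads_W[layer] = hs[layer].T @ dz
                    grads_b[layer] = dz.sum(axis=0)
                    if layer:
                        upstream = dz @ W[layer].T
                # adam update
                step += 1
                lr_t = self.learning_rate * (
                    np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step))
                for layer in range(3):
                    mW[layer] = beta1 * mW[layer] + (1 - beta1) * grads_W[layer]
                    vW[layer] = beta2 * vW[layer] + (1 - beta2) * grads_W[layer] ** 2
                    W[layer] -= lr_t * mW[layer] / (np.sqrt(vW[layer]) + eps)
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * grads_b[layer]
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * grads_b[layer] ** 2
                    b[layer] -= lr_t * mb[layer] / (np.sqrt(vb[layer]) + eps)
        self.weights_ = W
        self.biases_ = b
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "weights_"):
            raise RuntimeError("TwoLayerMLPRegressor is not fitted")
        h = np.asarray(X, dtype=float)
        acts = [_ACTIVATIONS[self.activation1], _ACTIVATIONS[self.activation2]]
        for layer in range(2):
            h = acts[layer][0](h @ self.weights_[layer] + self.biases_[layer])
        return (h @ self.weights_[2] + self.biases_[2]).ravel()


# ---------------------------------------------------------------------------
# estimator factory
# ---------------------------------------------------------------------------

def _rf_params(params: dict, is_classifier: bool) -> dict:
    out = dict(params)
    # historical 'auto' alias: all features for regression, sqrt for
    # classification (matching older scikit-learn semantics)
    if out.get("max_features") == "auto":
        out["max_features"] = "sqrt" if is_classifier else 1.0
    return out


def build_estimator(spec: LearnerSpec):
    """Instantiate the estimator described by a :class:`LearnerSpec`."""
    params = spec.hyperparameters
    if spec.family == "rf_classifier":
        return RandomForestClassifier(
            random_state=spec.seed, **_rf_params(params, True))
    if spec.family == "rf_regressor":
        return RandomForestRegressor(
            random_state=spec.seed, **_rf_params(params, False))
    if spec.family == "xgb_regressor":
        out = dict(params)
        if "colsample" in out:
            out["max_features"] = float(out.pop("colsample"))
        return GradientBoostingRegressor(random_state=spec.seed, **out)
    if spec.family == "ann_regressor":
        return TwoLayerMLPRegressor(seed=spec.seed, **params)
    raise ValueError(f"unknown learner family {spec.family!r}")


def default_search_spaces() -> dict[str, dict[str, list]]:
    """Published-scale randomized-search spaces per learner family."""
    trees = list(range(50, 1001, 50))
    return {
        "rf_classifier": {
            "n_estimators": trees,
            "max_features": ["auto", "sqrt"],
            "max_depth": list(range(1, 32)),
        },
        "rf_regressor": {
            "n_estimators": trees,
            "max_features": ["auto", "sqrt"],
            "max_depth": list(range(1, 32)),
        },
        "xgb_regressor": {
            "n_estimators": trees,
            "max_depth": list(range(1, 32)),
            # printed rates are garbled in the source grid; {0.5, 0.1, 0.01}
            # is the sane reading and stays configurable
            "learning_rate": [0.5, 0.1, 0.01],
            "subsample": [round(x, 2) for x in np.arange(0.05, 1.0001, 0.05)],
            "colsample": [round(x, 2) for x in np.arange(0.05, 1.0001, 0.05)],
            "loss": ["squared_error", "absolute_error"],
        },
        "ann_regressor": {
            "hidden1": list(range(5, 151, 5)),
            "hidden2": list(range(5, 151, 5)),
            "learning_rate": [0.1, 0.01, 0.001, 0.0001],
            "dropout1": [0.1, 0.3, 0.5],
            "dropout2": [0.1, 0.3, 0.5],
            "activation1": ["tanh", "swish", "linear", "relu"],
            "activation2": ["tanh", "swish", "linear", "relu"],
        },
    }


def small_search_spaces() -> dict[str, dict[str, list]]:
    """Scaled-down spaces keeping run times desk-friendly."""
    return {
        "rf_classifier": {
            "n_estimators": [25, 50, 100],
            "max_features": ["auto", "sqrt"],
            "max_depth": [5, 10, 20, 31],
        },
        "rf_regressor": {
            "n_estimators": [25, 50, 100],
            "max_features": ["auto", "sqrt"],
            "max_depth": [5, 10, 20, 31],
        },
        "xgb_regressor": {
            "n_estimators": [25, 50, 100],
            "max_depth": [2, 3, 5],
            "learning_rate": [0.5, 0.1, 0.01],
            "subsample": [0.6, 0.8, 1.0],
            "colsample": [0.6, 0.8, 1.0],
        },
        "ann_regressor": {
            "hidden1": [5, 10, 20],
            "hidden2": [10, 20, 40],
            "learning_rate": [0.01, 0.001],
            "dropout1": [0.1, 0.3],
            "dropout2": [0.1, 0.3],
            "activation1": ["swish", "relu", "tanh"],
            "activation2": ["relu", "linear"],
            "epochs": [30],
            "batch_size": [64],
        },
    }
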