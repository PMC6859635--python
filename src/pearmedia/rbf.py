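"""Radial-basis-function network regression.

A single-hidden-layer network whose hidden units are Gaussian kernels of
the distance to learned centers:

    Y(x) = sum_j W_j * exp(-||x - c_j||^2 / (2 sigma_j^2)) + b

Inputs are standardized to zero mean / unit variance (the factor ranges
span two orders of magnitude between IBA and minors); the target is
standardized internally as well and un-scaled at prediction.  Centers are
initialized by k-means, widths by the nearest-center heuristic, and all
parameters (weights, bias and optionally centers/widths) are trained by
full-batch gradient descent on the mean squared error.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .factors import FACTOR_NAMES

_MIN_WIDTH = 1e-3


@dataclass
class RBFNetwork:
    """Gaussian-kernel network with input/target standardization constants."""

    centers: np.ndarray        # (n_hidden, d), standardized input space
    widths: np.ndarray         # (n_hidden,)
    weights: np.ndarray        # (n_hidden,)
    bias: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float = 0.0
    y_std: float = 1.0
    feature_names: tuple[str, ...] = FACTOR_NAMES
    response: str = ""
    loss_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.widths = np.asarray(self.widths, float)
        self.weights = np.asarray(self.weights, float)
        n_h = len(self.centers)
        if not (len(self.widths) == len(self.weights) == n_h):
            raise ValueError("centers, widths and weights must have equal length")
        if (self.widths <= 0).any():
            raise ValueError("widths must be positive")

    @property
    def n_hidden(self) -> int:
        return len(self.centers)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def activations(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError(
                f"input dimension {X.shape[1]} != center dimension "
                f"{self.centers.shape[1]}"
            )
        Z = self._standardize(X)
        d2 = ((Z[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths ** 2))

    def predict(self, X) -> np.ndarray | float:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(float)
        X = np.asarray(X, float)
        scalar = X.ndim == 1
        out = self.activations(X) @ self.weights + self.bias
        out = self.y_mean + self.y_std * out
        return float(out[0]) if scalar else out

    def to_json(self) -> str:
        d = {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "feature_names": list(self.feature_names),
            "response": self.response,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "RBFNetwork":
        d = json.loads(s)
        return cls(
            centers=np.array(d["centers"]), widths=np.array(d["widths"]),
            weights=np.array(d["weights"]), bias=d["bias"],
            x_mean=np.array(d["x_mean"]), x_std=np.array(d["x_std"]),
            y_mean=d["y_mean"], y_std=d["y_std"],
            feature_names=tuple(d["feature_names"]), response=d["response"],
        )


def rbf_predict(net: RBFNetwork, x) -> np.ndarray | float:
    """Functional alias for :meth:`RBFNetwork.predict`."""
    return net.predict(x)


def _init_network(Z: np.ndarray, y_std_space: np.ndarray, n_hidden: int,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
    km = KMeans(n_clusters=n_hidden, n_init=4, random_state=seed)
    km.fit(Z)
    centers = km.cluster_centers_
    if n_hidden == 1:
        widths = np.array([max(np.mean(np.linalg.norm(Z - centers[0], axis=1)),
                               _MIN_WIDTH)])
    else:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        widths = np.maximum(d.min(axis=1), _MIN_WIDTH)
    return centers, widths


def train_rbf(train: pd.DataFrame, response: str, n_hidden: int = 15,
              learning_rate: float = 0.05, epochs: int = 2000, seed: int = 0,
              train_centers: bool = True,
              feature_names: tuple[str, ...] = FACTOR_NAMES) -> RBFNetwork:
    """Fit an RBF network by k-means initialization + gradient descent.

    ``epochs = 0`` returns the initialization unchanged (zero weights, bias
    at the target mean).  The per-epoch training MSE (in original target
    units) is recorded on ``loss_history``.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    X = train[list(feature_names)].to_numpy(float)
    y = train[response].to_numpy(float)
    if len(X) < n_hidden:
        raise ValueError("need at least n_hidden training records")
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std = np.where(x_std == 0, 1.0, x_std)
    y_mean, y_std = float(y.mean()), float(y.std())
    if y_std == 0:
        y_std = 1.0
    Z = (X - x_mean) / x_std
    t = (y - y_mean) / y_std

    centers, widths = _init_network(Z, t, n_hidden, seed)
    W = np.zeros(n_hidden)
    b = 0.0
    n = len(Z)
    history = []
    for _ in range(epochs):
        diff = Z[:, None, :] - centers[None, :, :]          # (n, h, d)
        d2 = (diff ** 2).sum(axis=2)
        act = np.exp(-d2 / (2.0 * widths ** 2))
        pred = act @ W + b
        e = pred - t
        history.append(float(np.mean(e ** 2)) * y_std ** 2)
        gW = 2.0 / n * (act.T @ e)
        gb = 2.0 / n * e.sum()
        if train_centers:
            common = (e[:, None] * act) * W[None, :]        # (n, h)
            gC = 2.0 / n * np.einsum("nh,nhd->hd", common, diff) / widths[None, :].T ** 2
            gS = 2.0 / n * (common * d2).sum(axis=0) / widths ** 3
            centers = centers - learning_rate * gC
            widths = np.maximum(widths - learning_rate * gS, _MIN_WIDTH)
        W = W - learning_rate * gW
        b = b - learning_rate * gb
    return RBFNetwork(
        centers=centers, widths=widths, weights=W, bias=float(b),
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        feature_names=tuple(feature_names), response=response,
        loss_history=tuple(history),
    )


def select_hidden_units(train: pd.DataFrame, response: str,
                        candidates=(5, 10, 15, 20), holdout_fraction: float = 0.25,
                        seed: int = 0, **kwargs) -> tuple[int, dict[int, float]]:
    """Choose the hidden-unit count minimizing held-out RMSE."""
    rng = np.random.default_rng(seed)
    n = len(train)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(n * holdout_fraction)))
    hold = train.iloc[perm[:n_hold]]
    fit = train.iloc[perm[n_hold:]]
    scores: dict[int, float] = {}
    for n_h in candidates:
        if len(fit) < n_h:
            continue
        net = train_rbf(fit, response, n_hidden=n_h, seed=seed, **kwargs)
        pred = net.predict(hold)
        scores[n_h] = float(np.sqrt(np.mean((hold[response].to_numpy(float) - pred) ** 2)))
    best = min(scores, key=scores.get)
    return best, scores
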