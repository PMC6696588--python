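"""Replay recorded picking histories into alternative estimators.

A learning history fixes the exact order in which pool instances entered
training, so any estimator can be refit on the training set the forest had
at a given budget fraction ("yoked" replay).  Support-vector machines
(RBF and linear) and multi-layer perceptrons are supported; MLP hidden
layers all have width equal to the pair-instance feature count.

Models that predict a single class on the external set are flagged
degenerate and scored MCC/F1 = 0.0 rather than dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .al_engine import LearningHistory
from .evaluation import confusion

__all__ = ["ReplaySpec", "ReplayResult", "reconstruct_training", "replay"]

ESTIMATOR_FAMILIES = ("svm-rbf", "svm-linear", "mlp")

# Grid defaults: six logarithmic regularization values crossed with five
# seeds for the MLP; modest C/gamma grids for the SVMs.
DEFAULT_ALPHAS = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
DEFAULT_SEEDS = (0, 1, 2, 3, 4)
DEFAULT_C = (0.1, 1.0, 10.0)
DEFAULT_GAMMA = ("scale", 0.01, 0.1)
DEFAULT_CHECKPOINTS = (0.20, 0.75)


@dataclass
class ReplaySpec:
    """What to refit: estimator family, hyperparameter grid, checkpoints."""

    family: str = "svm-rbf"
    c_values: Sequence[float] = DEFAULT_C
    gamma_values: Sequence = DEFAULT_GAMMA
    hidden_layer_counts: Sequence[int] = tuple(range(1, 11))
    alphas: Sequence[float] = DEFAULT_ALPHAS
    seeds: Sequence[int] = DEFAULT_SEEDS
    checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS
    mlp_max_iter: int = 300

    def __post_init__(self):
        if self.family not in ESTIMATOR_FAMILIES:
            raise ValueError(f"unknown estimator family {self.family!r}")
        if any(not 0 < c <= 1 for c in self.checkpoints):
            raise ValueError("checkpoints must lie in (0, 1]")


@dataclass
class ReplayResult:
    """One row per (hyperparameter point, seed, checkpoint) evaluation."""

    family: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def degenerate_rows(self) -> pd.DataFrame:
        return self.table[self.table["degenerate"]]

    def to_csv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def reconstruct_training(history: LearningHistory, fraction: float) -> list[int]:
    """Pool indices of the training set at a budget fraction, in picked order.

    The set is the two seed instances plus the first ceil(fraction * pool)
    picked instances, capped at the full pool.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n_keep = min(history.n_pool, 2 + math.ceil(fraction * history.n_pool))
    if n_keep > len(history.picked_order):
        raise ValueError(
            f"history covers only {len(history.picked_order)}/{history.n_pool} "
            f"instances; cannot reconstruct fraction {fraction}"
        )
    return list(history.picked_order[:n_keep])


def _make_estimator(spec: ReplaySpec, params: dict, n_features: int, seed: int):
    if spec.family == "svm-rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"], random_state=seed)
    if spec.family == "svm-linear":
        return SVC(kernel="linear", C=params["C"], random_state=seed)
    layers = (n_features,) * params["n_layers"]
    return MLPClassifier(
        hidden_layer_sizes=layers,
        alpha=params["alpha"],
        random_state=seed,
        max_iter=spec.mlp_max_iter,
    )


def _grid(spec: ReplaySpec):
    if spec.family == "svm-rbf":
        for C in spec.c_values:
            for gamma in spec.gamma_values:
                yield {"C": C, "gamma": gamma}
    elif spec.family == "svm-linear":
        for C in spec.c_values:
            yield {"C": C}
    else:
        for n_layers in spec.hidden_layer_counts:
            for alpha in spec.alphas:
                yield {"n_layers": n_layers, "alpha": alpha}


def replay(
    history: LearningHistory,
    spec: ReplaySpec,
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    X_ext: np.ndarray,
    y_ext: np.ndarray,
) -> ReplayResult:
    """Refit the spec's grid on the history's training sets and evaluate externally.

    Non-convergent fits are recorded (``converged=False``) but not fatal.
    """
    X_pool = np.asarray(X_pool)
    y_pool = np.asarray(y_pool, dtype=int)
    rows = []
    for checkpoint in spec.checkpoints:
        idx = reconstruct_training(history, checkpoint)
        X_tr, y_tr = X_pool[idx], y_pool[idx]
        for params in _grid(spec):
            for seed in spec.seeds:
                est = _make_estimator(spec, params, X_pool.shape[1], seed)
                converged = True
                with warnings.catch_warnings():
                    warnings.simplefilter("error", ConvergenceWarning)
                    try:
                        est.fit(X_tr, y_tr)
                    except ConvergenceWarning:
                        converged = False
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", ConvergenceWarning)
                            est.fit(X_tr, y_tr)
                pred = est.predict(X_ext)
                point = confusion(pred, y_ext)
                rows.append(
                    {
                        "family": spec.family,
                        **params,
                        "seed": seed,
                        "checkpoint": checkpoint,
                        "n_training": len(idx),
                        "converged": converged,
                        "degenerate": len(np.unique(pred)) == 1,
                        **{k: v for k, v in point.as_dict().items() if k != "degenerate"},
                    }
                )
    return ReplayResult(family=spec.family, table=pd.DataFrame(rows))
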