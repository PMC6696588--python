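"""Confusion-matrix metrics, metric surfaces and active projections.

All derived metrics are computed from raw (TP, TN, FP, FN) counts.  A
zero-denominator in any metric yields 0.0 together with a ``degenerate``
flag, so that "dysfunctional" single-class models are surfaced rather than
silently scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MetricPoint",
    "MetricSurface",
    "ProjectionTrace",
    "confusion",
    "mcc_from_counts",
    "f1_from_counts",
    "metric_surface",
    "active_projection",
]

DEFAULT_EPSILON = 0.075


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0.0 when any marginal (row or column sum of the confusion
    matrix) is zero, the standard degenerate-case convention.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 (harmonic mean of PPV and TPR); 0.0 when TP and an error count are 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 2 * tp / denom


def _rate(num: int, denom: int) -> float:
    return num / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class MetricPoint:
    """Confusion counts plus the derived metrics at one evaluation point."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def mcc(self) -> float:
        return mcc_from_counts(self.tp, self.tn, self.fp, self.fn)

    @property
    def f1(self) -> float:
        return f1_from_counts(self.tp, self.fp, self.fn)

    @property
    def ppv(self) -> float:
        return _rate(self.tp, self.tp + self.fp)

    @property
    def tpr(self) -> float:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return _rate(self.tn, self.tn + self.fp)

    @property
    def degenerate(self) -> bool:
        """True when the MCC denominator vanishes (e.g. single-class predictions)."""
        return (self.tp + self.fp) * (self.tp + self.fn) * (self.tn + self.fp) * (
            self.tn + self.fn
        ) == 0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "mcc": self.mcc,
            "f1": self.f1,
            "ppv": self.ppv,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "degenerate": self.degenerate,
        }


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> MetricPoint:
    """Tally a binary prediction vector against truth into a :class:`MetricPoint`."""
    pred = np.asarray(predicted).astype(int)
    true = np.asarray(truth).astype(int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return MetricPoint(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class MetricSurface:
    """A metric's value over the (TNR, TPR) unit square at a fixed class ratio.

    ``grid[i, j]`` holds the metric at ``tnr = tnr_axis[i]``,
    ``tpr = tpr_axis[j]``.
    """

    metric: Literal["mcc", "f1"]
    n_pos: int
    n_neg: int
    tnr_axis: np.ndarray
    tpr_axis: np.ndarray
    grid: np.ndarray

    def value_at(self, tnr: float, tpr: float) -> float:
        i = int(np.argmin(np.abs(self.tnr_axis - tnr)))
        j = int(np.argmin(np.abs(self.tpr_axis - tpr)))
        return float(self.grid[i, j])


def metric_surface(
    metric: str, n_pos: int, n_neg: int, grid_resolution: int = 201
) -> MetricSurface:
    """Tabulate MCC or F1 over (TNR, TPR) for ``n_pos`` actives / ``n_neg`` inactives.

    Each grid cell converts the rates to rounded integer counts
    (tp = round(tpr * n_pos), tn = round(tnr * n_neg)) and applies the exact
    count-based formula, so cells agree with :func:`mcc_from_counts` /
    :func:`f1_from_counts` by construction.
    """
    metric = metric.lower()
    if metric not in ("mcc", "f1"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one instance per class")
    axis = np.linspace(0.0, 1.0, grid_resolution)
    grid = np.empty((grid_resolution, grid_resolution))
    for i, tnr in enumerate(axis):
        tn = int(round(tnr * n_neg))
        fp = n_neg - tn
        for j, tpr in enumerate(axis):
            tp = int(round(tpr * n_pos))
            fn = n_pos - tp
            if metric == "mcc":
                grid[i, j] = mcc_from_counts(tp, tn, fp, fn)
            else:
                grid[i, j] = f1_from_counts(tp, fp, fn)
    return MetricSurface(
        metric=metric, n_pos=n_pos, n_neg=n_neg, tnr_axis=axis, tpr_axis=axis, grid=grid
    )


@dataclass
class ProjectionTrace:
    """An active projection: the (TNR, TPR) trajectory with its termination point.

    ``termination_index`` is the first index t such that no later point
    departs from point t by ``epsilon`` or more in either TPR or TNR
    (stable-zone rule).  The truncated trace is a prefix of the input.
    """

    tnr: np.ndarray
    tpr: np.ndarray
    training_fraction: np.ndarray
    termination_index: int
    epsilon: float = DEFAULT_EPSILON
    mode: str = "stable-zone"
    extras: dict = field(default_factory=dict)

    @property
    def terminal_training_fraction(self) -> float:
        return float(self.training_fraction[self.termination_index])

    def truncated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k = self.termination_index + 1
        return self.tnr[:k], self.tpr[:k], self.training_fraction[:k]


def _stable_zone_index(tpr: np.ndarray, tnr: np.ndarray, epsilon: float) -> int:
    n = len(tpr)
    for t in range(n):
        if np.all(np.abs(tpr[t + 1 :] - tpr[t]) < epsilon) and np.all(
            np.abs(tnr[t + 1 :] - tnr[t]) < epsilon
        ):
            return t
    return n - 1


def _successive_index(tpr: np.ndarray, tnr: np.ndarray, epsilon: float) -> int:
    n = len(tpr)
    for t in range(n - 1):
        if np.all(np.abs(np.diff(tpr[t:])) < epsilon) and np.all(
            np.abs(np.diff(tnr[t:])) < epsilon
        ):
            return t
    return n - 1


def active_projection(
    history,
    epsilon: float = DEFAULT_EPSILON,
    mode: Literal["stable-zone", "successive"] = "stable-zone",
) -> ProjectionTrace:
    """Build the (TNR, TPR) projection of a learning run, with termination.

    ``history`` may be a :class:`probeal.al_engine.LearningHistory` (anything
    exposing ``external_metrics`` and ``training_fractions``) or a tuple of
    ``(tpr, tnr, training_fraction)`` sequences.

    Termination rules (both shipped; stable-zone is the default):

    - ``stable-zone``: the minimal index t such that every later point stays
      within ``epsilon`` of point t in both TPR and TNR.
    - ``successive``: the minimal index t after which every successive change
      in TPR and TNR is below ``epsilon``.
    """
    if hasattr(history, "external_metrics"):
        points = history.external_metrics
        if len(points) == 0:
            raise ValueError("history has no external metric points")
        tpr = np.array([p.tpr for p in points])
        tnr = np.array([p.tnr for p in points])
        frac = np.asarray(history.training_fractions, dtype=float)
    else:
        tpr, tnr, frac = (np.asarray(a, dtype=float) for a in history)
        if len(tpr) == 0:
            raise ValueError("empty trace")
    if not (len(tpr) == len(tnr) == len(frac)):
        raise ValueError("trace component lengths differ")
    if mode == "stable-zone":
        idx = _stable_zone_index(tpr, tnr, epsilon)
    elif mode == "successive":
        idx = _successive_index(tpr, tnr, epsilon)
    else:
        raise ValueError(f"unknown termination mode {mode!r}")
    return ProjectionTrace(
        tnr=tnr,
        tpr=tpr,
        training_fraction=frac,
        termination_index=idx,
        epsilon=epsilon,
        mode=mode,
    )


def plot_projection(surface: MetricSurface, trace: ProjectionTrace, out_path: str) -> None:
    """Render a metric surface heatmap with the projection trajectory overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        surface.tnr_axis,
        surface.tpr_axis,
        surface.grid.T,
        shading="auto",
        cmap="viridis",
        vmin=-1.0 if surface.metric == "mcc" else 0.0,
        vmax=1.0,
    )
    fig.colorbar(mesh, ax=ax, label=surface.metric.upper())
    tnr, tpr, frac = trace.truncated()
    ax.plot(tnr, tpr, "-o", color="white", markersize=3, linewidth=1)
    ax.annotate(
        f"{100 * trace.terminal_training_fraction:.1f}% training",
        (tnr[-1], tpr[-1]),
        color="white",
        fontsize=8,
        xytext=(5, 5),
        textcoords="offset points",
    )
    ax.set_xlabel("TNR")
    ax.set_ylabel("TPR")
    ax.set_title(
        f"{surface.metric.upper()} surface ({surface.n_pos} actives / {surface.n_neg} inactives)"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
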