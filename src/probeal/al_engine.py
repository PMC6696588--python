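"""Random-forest active learning over a pool of ligand–target pair instances.

The loop seeds training with one randomly drawn active and one inactive
instance, then repeats fit → evaluate-external → (record) → pick with one
of three picking strategies:

- ``random``    uniform draw from the remaining pool;
- ``greedy``    the instance with the highest mean tree vote for the active
                class (exploitative);
- ``curiosity`` the instance with the highest across-tree vote variance,
                i.e. vote fraction closest to 0.5 (explorative).

Forests have 100 trees by default; all other hyperparameters stay at the
scikit-learn defaults and are recorded in the run manifest.  Ties in the
pickers break toward the lowest pool index for reproducibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import MetricPoint, confusion

logger = logging.getLogger(__name__)

__all__ = [
    "PICKER_STRATEGIES",
    "ForestSnapshot",
    "LearningHistory",
    "seed_start",
    "pick_next",
    "run_active_learning",
    "replicate",
    "aggregate_histories",
    "fit_forest",
    "refit_at_fraction",
]

PICKER_STRATEGIES = ("random", "greedy", "curiosity")
N_TREES_DEFAULT = 100


def fit_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int = N_TREES_DEFAULT, random_state: int = 0
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=random_state, n_jobs=1
    )
    forest.fit(X, y)
    return forest


def tree_vote_fractions(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting 'active' for each row (hard per-tree votes)."""
    votes = np.zeros(len(X))
    for tree in forest.estimators_:
        votes += tree.predict(X)
    return votes / len(forest.estimators_)


@dataclass
class ForestSnapshot:
    """A fitted forest plus its vote fractions over the remaining pool."""

    iteration: int
    forest: RandomForestClassifier
    pool_votes: np.ndarray  # aligned with the `remaining` index set

    def __post_init__(self):
        if len(self.forest.estimators_) == 0:
            raise ValueError("snapshot holds an unfitted forest")


def seed_start(y_pool: np.ndarray, rng: np.random.Generator) -> list[int]:
    """Pick one random active and one random inactive pool index."""
    y = np.asarray(y_pool)
    actives = np.flatnonzero(y == 1)
    inactives = np.flatnonzero(y == 0)
    if len(actives) == 0 or len(inactives) == 0:
        raise ValueError("pool must contain at least one active and one inactive")
    return [int(rng.choice(actives)), int(rng.choice(inactives))]


def pick_next(
    pool_votes: np.ndarray,
    remaining: Sequence[int],
    strategy: str,
    rng: np.random.Generator,
) -> int:
    """Select the next pool index; ``pool_votes`` is aligned with ``remaining``.

    Ties break to the lowest pool index (remaining is kept in ascending
    order by the loop).
    """
    if len(remaining) == 0:
        raise ValueError("remaining pool is empty")
    if strategy not in PICKER_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    remaining = np.asarray(remaining)
    if strategy == "random":
        return int(rng.choice(remaining))
    votes = np.asarray(pool_votes)
    if len(votes) != len(remaining):
        raise ValueError("vote vector not aligned with remaining pool")
    if strategy == "greedy":
        score = votes
    else:  # curiosity: across-tree vote variance p(1-p), maximal at p=0.5
        score = votes * (1.0 - votes)
    # scores sharing a true value can differ by float rounding (variance of
    # p and 1-p is identical); merge within 1e-9 so ties break by pool index
    best = np.flatnonzero(score >= score.max() - 1e-9)
    if len(best) > 1:
        logger.debug("%d tied maxima; picking lowest pool index", len(best))
    return int(remaining[best[0]])


@dataclass
class LearningHistory:
    """Ordered pick record and per-iteration evaluations of one AL run."""

    strategy: str
    seed: int
    n_pool: int
    n_trees: int
    picked_order: list[int] = field(default_factory=list)
    training_sizes: list[int] = field(default_factory=list)
    external_metrics: list[MetricPoint] = field(default_factory=list)
    retrospective_metrics: list[MetricPoint | None] = field(default_factory=list)
    weight_iterations: list[int] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def training_fractions(self) -> np.ndarray:
        return np.asarray(self.training_sizes) / self.n_pool

    @property
    def picked_labels(self) -> list[int]:
        return self.manifest.get("picked_labels", [])

    def weight_matrix(self) -> np.ndarray:
        if not self.weights:
            raise ValueError("no feature weights were recorded")
        return np.vstack(self.weights)

    def metric_at_fraction(self, fraction: float) -> MetricPoint:
        """External metric point at the first iteration reaching ``fraction``."""
        fracs = self.training_fractions
        idx = int(np.searchsorted(fracs, fraction))
        idx = min(idx, len(self.external_metrics) - 1)
        return self.external_metrics[idx]

    def save(self, directory, name: str) -> dict[str, str]:
        """Serialize to delimited text plus a JSON sidecar under ``directory``."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"table": str(directory / f"{name}.tsv")}
        self.to_frame().to_csv(paths["table"], sep="\t", index=False)
        sidecar = {
            "strategy": self.strategy,
            "seed": self.seed,
            "n_pool": self.n_pool,
            "n_trees": self.n_trees,
            "picked_order": self.picked_order,
            "weight_iterations": self.weight_iterations,
            "manifest": {
                k: v for k, v in self.manifest.items() if k != "forest_params"
            },
        }
        paths["sidecar"] = str(directory / f"{name}.json")
        Path(paths["sidecar"]).write_text(json.dumps(sidecar, indent=2))
        if self.weights:
            paths["weights"] = str(directory / f"{name}.weights.tsv")
            pd.DataFrame(
                self.weight_matrix(), index=self.weight_iterations
            ).to_csv(paths["weights"], sep="\t", index_label="iteration")
        return paths

    @classmethod
    def load(cls, directory, name: str) -> "LearningHistory":
        import json
        from pathlib import Path

        directory = Path(directory)
        sidecar = json.loads((directory / f"{name}.json").read_text())
        table = pd.read_csv(directory / f"{name}.tsv", sep="\t")
        history = cls(
            strategy=sidecar["strategy"],
            seed=sidecar["seed"],
            n_pool=sidecar["n_pool"],
            n_trees=sidecar["n_trees"],
            picked_order=list(sidecar["picked_order"]),
            manifest=sidecar.get("manifest", {}),
        )
        history.training_sizes = table["n_training"].tolist()
        history.external_metrics = [
            MetricPoint(tp=int(r.ext_tp), tn=int(r.ext_tn), fp=int(r.ext_fp), fn=int(r.ext_fn))
            for r in table.itertuples(index=False)
        ]
        history.retrospective_metrics = [None] * len(history.external_metrics)
        weights_path = directory / f"{name}.weights.tsv"
        if weights_path.exists():
            wdf = pd.read_csv(weights_path, sep="\t", index_col="iteration")
            history.weight_iterations = list(wdf.index)
            history.weights = [row.to_numpy() for _, row in wdf.iterrows()]
        return history

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.external_metrics):
            row = {
                "iteration": i,
                "n_training": self.training_sizes[i],
                "training_fraction": self.training_sizes[i] / self.n_pool,
            }
            row.update({f"ext_{k}": v for k, v in m.as_dict().items()})
            retro = (
                self.retrospective_metrics[i]
                if i < len(self.retrospective_metrics)
                else None
            )
            if retro is not None:
                row.update({f"retro_{k}": v for k, v in retro.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def run_active_learning(
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    X_ext: np.ndarray,
    y_ext: np.ndarray,
    strategy: Literal["random", "greedy", "curiosity"] = "curiosity",
    n_trees: int = N_TREES_DEFAULT,
    rng_seed: int = 0,
    weight_interval: int | None = None,
    stop_fraction: float = 1.0,
    retrospective: bool = False,
) -> LearningHistory:
    """Run one active-learning trajectory until the pool is exhausted.

    The external set is evaluated after every fit (i.e. after incorporating
    the most recent pick and before the next one).  ``stop_fraction`` allows
    truncating a run early at a training-budget fraction; the default runs
    until the pool is exhausted.  ``weight_interval`` records the forest's
    feature-importance vector every that-many iterations.
    """
    X_pool = np.asarray(X_pool)
    y_pool = np.asarray(y_pool, dtype=int)
    n_pool = len(y_pool)
    if n_pool < 2:
        raise ValueError("pool too small")
    rng = np.random.default_rng(rng_seed)
    history = LearningHistory(
        strategy=strategy, seed=rng_seed, n_pool=n_pool, n_trees=n_trees
    )
    history.manifest = {
        "strategy": strategy,
        "rng_seed": rng_seed,
        "n_trees": n_trees,
        "stop_fraction": stop_fraction,
        "forest_params": RandomForestClassifier(n_estimators=n_trees).get_params(),
        "picked_labels": [],
    }

    train = seed_start(y_pool, rng)
    remaining = sorted(set(range(n_pool)) - set(train))
    history.picked_order.extend(train)
    history.manifest["picked_labels"].extend(int(y_pool[i]) for i in train)

    max_training = max(2, math.ceil(stop_fraction * n_pool))
    iteration = 0
    while True:
        forest = fit_forest(
            X_pool[train],
            y_pool[train],
            n_trees=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
        )
        history.training_sizes.append(len(train))
        history.external_metrics.append(
            confusion(forest.predict(X_ext), y_ext)
        )
        if retrospective and remaining:
            history.retrospective_metrics.append(
                confusion(forest.predict(X_pool[remaining]), y_pool[remaining])
            )
        else:
            history.retrospective_metrics.append(None)
        if weight_interval is not None and iteration % weight_interval == 0:
            history.weight_iterations.append(iteration)
            history.weights.append(forest.feature_importances_.copy())
        if not remaining or len(train) >= max_training:
            break
        if strategy == "random":
            votes = None
        else:
            votes = tree_vote_fractions(forest, X_pool[remaining])
        nxt = pick_next(
            votes if votes is not None else np.zeros(len(remaining)),
            remaining,
            strategy,
            rng,
        )
        remaining.remove(nxt)
        train.append(nxt)
        history.picked_order.append(nxt)
        history.manifest["picked_labels"].append(int(y_pool[nxt]))
        iteration += 1
    return history


def replicate(
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    X_ext: np.ndarray,
    y_ext: np.ndarray,
    strategy: str = "curiosity",
    n_repeats: int = 10,
    base_seed: int = 0,
    **kwargs,
) -> list[LearningHistory]:
    """Repeat a run with seeds ``base_seed .. base_seed + n_repeats - 1``."""
    return [
        run_active_learning(
            X_pool, y_pool, X_ext, y_ext, strategy=strategy, rng_seed=base_seed + i, **kwargs
        )
        for i in range(n_repeats)
    ]


def aggregate_histories(histories: Sequence[LearningHistory]) -> pd.DataFrame:
    """Mean/sd of the external metrics across repeats, per iteration."""
    frames = [h.to_frame().assign(seed=h.seed) for h in histories]
    stacked = pd.concat(frames, ignore_index=True)
    agg = (
        stacked.groupby("iteration")
        .agg(
            training_fraction=("training_fraction", "mean"),
            mcc_mean=("ext_mcc", "mean"),
            mcc_sd=("ext_mcc", "std"),
            f1_mean=("ext_f1", "mean"),
            f1_sd=("ext_f1", "std"),
            tpr_mean=("ext_tpr", "mean"),
            tnr_mean=("ext_tnr", "mean"),
            n_runs=("seed", "count"),
        )
        .reset_index()
    )
    return agg


def refit_at_fraction(
    history: LearningHistory,
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    fraction: float,
    n_trees: int | None = None,
    random_state: int = 0,
) -> RandomForestClassifier:
    """Refit a forest on the training set a run had at a budget fraction."""
    from .yoked_models import reconstruct_training

    idx = reconstruct_training(history, fraction)
    return fit_forest(
        np.asarray(X_pool)[idx],
        np.asarray(y_pool, dtype=int)[idx],
        n_trees=n_trees or history.n_trees,
        random_state=random_state,
    )
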