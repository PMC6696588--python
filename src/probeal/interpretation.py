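"""Model introspection: feature-weight time series, tree rendering, root nodes.

- Per-iteration forest feature weights are row-wise z-scaled into a
  relative-weight matrix for heatmap display (iterations top to bottom,
  with a dashed line at the chemical/protein block boundary).
- Individual decision trees are exported to DOT text with node colors
  encoding class (yellow = inhibitory/active, cyan = non-inhibitory) and
  color intensity encoding node purity.
- The fraction of trees per forest whose root splits on a target-block
  feature is estimated with a Student-t confidence interval across forests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .descriptors import _windows  # shared residue-window iterator

__all__ = [
    "FeatureWeightMatrix",
    "RootFractionEstimate",
    "zscale_weights",
    "record_weights",
    "usage_count_weights",
    "export_tree",
    "root_fraction",
    "motif_uniqueness",
]


@dataclass
class FeatureWeightMatrix:
    """Iterations x features matrix of z-scaled relative feature weights."""

    matrix: np.ndarray
    iterations: tuple[int, ...]
    feature_names: tuple[str, ...]
    block_boundary: int
    scaling_tag: str = "z-scaled"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.iterations), columns=list(self.feature_names)
        )

    def to_csv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="iteration")


def zscale_weights(
    raw: np.ndarray,
    iterations: Sequence[int] | None = None,
    feature_names: Sequence[str] | None = None,
    block_boundary: int = 0,
) -> FeatureWeightMatrix:
    """Row-wise (w - mean) / sd with population sd; constant rows become zeros."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)  # population sd
    scaled = np.where(sd > 0, (raw - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    n_iter, n_feat = scaled.shape
    return FeatureWeightMatrix(
        matrix=scaled,
        iterations=tuple(iterations) if iterations is not None else tuple(range(n_iter)),
        feature_names=(
            tuple(feature_names)
            if feature_names is not None
            else tuple(f"f{i}" for i in range(n_feat))
        ),
        block_boundary=block_boundary,
    )


def record_weights(
    forest: RandomForestClassifier, method: str = "importance"
) -> np.ndarray:
    """Per-feature weight vector from a fitted forest.

    ``importance`` uses the library's impurity-based importances;
    ``usage`` counts how many internal tree nodes split on each feature
    (the node-usage reading), normalized to sum to 1.
    """
    if not hasattr(forest, "estimators_") or not forest.estimators_:
        raise ValueError("forest is not fitted")
    if method == "importance":
        return forest.feature_importances_.copy()
    if method == "usage":
        return usage_count_weights(forest)
    raise ValueError(f"unknown weight method {method!r}")


def usage_count_weights(forest: RandomForestClassifier) -> np.ndarray:
    """Fraction of internal decision nodes (forest-wide) using each feature."""
    counts = np.zeros(forest.n_features_in_)
    for est in forest.estimators_:
        t = est.tree_
        used = t.feature[t.feature >= 0]  # leaves are -2
        np.add.at(counts, used, 1)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _node_color(p_active: float) -> str:
    """Yellow for active-leaning nodes, cyan for inactive, intensity = purity."""
    purity = abs(2 * p_active - 1)  # 0 at 50/50, 1 when pure
    alpha = int(round(40 + 215 * purity))
    base = "#ffff00" if p_active >= 0.5 else "#00ffff"
    return f"{base}{alpha:02x}"


def export_tree(
    tree: DecisionTreeClassifier,
    feature_names: Sequence[str],
    class_names: Sequence[str] = ("inactive", "active"),
    external_mcc: float | None = None,
    external_f1: float | None = None,
) -> str:
    """Export a fitted tree to DOT with purity-colored nodes.

    ``external_mcc`` / ``external_f1`` annotate the tree's own performance
    on the external set below the graph.
    """
    if not hasattr(tree, "tree_"):
        raise ValueError("tree is not fitted")
    t = tree.tree_
    active_idx = int(np.argmax(tree.classes_)) if len(tree.classes_) == 2 else 0
    lines = [
        "digraph decision_tree {",
        '  node [shape=box, style="filled,rounded", fontname="helvetica"];',
    ]
    if external_mcc is not None or external_f1 is not None:
        parts = []
        if external_mcc is not None:
            parts.append(f"MCC={external_mcc:.2f}")
        if external_f1 is not None:
            parts.append(f"F1={external_f1:.2f}")
        lines.append(f'  label="{" / ".join(parts)}"; labelloc="b";')
    for node in range(t.node_count):
        counts = t.value[node][0] * t.weighted_n_node_samples[node]
        n_samples = int(t.n_node_samples[node])
        total = counts.sum()
        p_active = counts[active_idx] / total if total > 0 else 0.0
        color = _node_color(p_active)
        if t.children_left[node] == -1:  # leaf
            cls = class_names[int(np.argmax(counts))]
            label = f"{cls}\\nsamples={n_samples}\\nactive={p_active:.2f}"
        else:
            feat = feature_names[t.feature[node]]
            label = (
                f"{feat} <= {t.threshold[node]:.3f}\\n"
                f"samples={n_samples}\\nactive={p_active:.2f}"
            )
        lines.append(f'  n{node} [label="{label}", fillcolor="{color}"];')
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left != -1:
            lines.append(f'  n{node} -> n{left} [label="yes"];')
            lines.append(f'  n{node} -> n{right} [label="no"];')
    lines.append("}")
    return "\n".join(lines)


@dataclass
class RootFractionEstimate:
    """Across-forest estimate of the target-descriptor root-node fraction."""

    fractions: tuple[float, ...]
    mean: float
    ci95: tuple[float, float] | None

    @property
    def n_forests(self) -> int:
        return len(self.fractions)


def root_fraction(
    forests: Sequence[RandomForestClassifier], block_boundary: int
) -> RootFractionEstimate:
    """Fraction of trees whose root splits on a target-block feature.

    Target features are those with index >= ``block_boundary`` (ligand
    block comes first).  With >= 2 forests a Student-t 95% CI on the
    per-forest fractions is attached; with one forest, a point estimate only.
    """
    if not forests:
        raise ValueError("need at least one fitted forest")
    fractions = []
    for forest in forests:
        roots = np.array([est.tree_.feature[0] for est in forest.estimators_])
        # a root of -2 means a single-leaf tree; count it as non-target
        fractions.append(float(np.mean(roots >= block_boundary)))
    mean = float(np.mean(fractions))
    ci = None
    if len(fractions) >= 2:
        sem = stats.sem(fractions)
        if sem > 0:
            lo, hi = stats.t.interval(0.95, len(fractions) - 1, loc=mean, scale=sem)
            ci = (float(lo), float(hi))
        else:
            ci = (mean, mean)
    return RootFractionEstimate(fractions=tuple(fractions), mean=mean, ci95=ci)


def motif_uniqueness(sequences: Mapping[str, str], k: int) -> dict[str, set[str]]:
    """Inverted index k-mer -> set of target ids whose sequence contains it.

    Unique markers are the k-mers carried by exactly one target.
    """
    index: dict[str, set[str]] = {}
    for tid, seq in sequences.items():
        for w in set(_windows(seq, k)):
            index.setdefault(w, set()).add(tid)
    return index


def unique_motifs(sequences: Mapping[str, str], k: int) -> dict[str, str]:
    """k-mers present in exactly one target, mapped to that target."""
    return {
        kmer: next(iter(carriers))
        for kmer, carriers in motif_uniqueness(sequences, k).items()
        if len(carriers) == 1
    }


def plot_weight_heatmap(weights: FeatureWeightMatrix, out_path: str) -> None:
    """Heatmap of relative weights, initial iterations at the top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(weights.matrix, aspect="auto", cmap="magma", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="relative weight (z-scaled)")
    if 0 < weights.block_boundary < weights.matrix.shape[1]:
        ax.axvline(weights.block_boundary - 0.5, linestyle="--", color="yellow")
    ax.set_xlabel("feature")
    ax.set_ylabel("iteration (early at top)")
    ax.set_yticks(range(len(weights.iterations)))
    ax.set_yticklabels(weights.iterations)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
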