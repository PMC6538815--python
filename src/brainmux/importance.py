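"""Feature importance by weight paths, occurrence-based selection, and
mapping of selected features back to patches and atlas regions.

Importance follows the Gedeon weight-path construction: absolute weights of
the first two hidden layers are column-normalized into shares, multiplied
along every input->hidden1->hidden2 path, summed, and rescaled so the most
important input scores 1. Selection repeats the ranking over random subject
subsamples and keeps features whose rate of appearing in the top quantile
cannot be explained by chance (one-sided binomial test, Bonferroni-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.preprocessing import StandardScaler

from brainmux.multiplex_metrics import METRIC_NAMES
from brainmux.regression_suite import DnnConfig, fit_dnn
from brainmux.volume_io import Patch, PatchGrid

__all__ = [
    "ImportanceVector",
    "SelectionResult",
    "gedeon_importance",
    "occurrence_selection",
    "feature_to_patch",
    "label_patches_with_atlas",
]


@dataclass
class ImportanceVector:
    """Per-feature relative importance normalized to [0, 1]."""

    values: np.ndarray
    seed: int = 0
    model_kind: str = "dnn"


@dataclass
class SelectionResult:
    """Features recurring in top-importance sets more often than chance."""

    selected: np.ndarray  # feature indices, sorted
    occurrences: np.ndarray  # per-feature count over runs
    p_adjusted: np.ndarray  # per-feature Bonferroni-adjusted p
    mean_importance: np.ndarray  # per-feature mean relative importance over runs
    runs: int
    top_quantile: float
    alpha: float

    def to_frame(self, grid: PatchGrid | None = None) -> pd.DataFrame:
        rows = []
        for f in self.selected:
            row = {
                "feature": int(f),
                "occurrences": int(self.occurrences[f]),
                "p_adjusted": float(self.p_adjusted[f]),
                "mean_importance": float(self.mean_importance[f]),
            }
            if grid is not None:
                metric, patch = feature_to_patch(int(f), grid)
                row.update(metric=metric, patch_id=patch.patch_id, side=patch.side)
            rows.append(row)
        return pd.DataFrame(rows)


def gedeon_importance(W1: np.ndarray, W2: np.ndarray) -> ImportanceVector:
    """Relative input importance from the first two hidden layers' weights.

    ``P_ij = |W1_ij| / sum_k |W1_kj]`` and ``Q_jl = |W2_jl| / sum_m |W2_ml|``
    are the per-column absolute-weight shares; the raw importance of input i
    is ``sum_l sum_j P_ij Q_jl`` and the result is rescaled by its maximum so
    importances lie in [0, 1]. An all-zero column contributes zero shares
    (warned) rather than dividing by zero.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.shape[1] != W2.shape[0]:
        raise ValueError(
            f"W1 columns ({W1.shape[1]}) must match W2 rows ({W2.shape[0]})"
        )

    def column_shares(W: np.ndarray) -> np.ndarray:
        a = np.abs(W)
        norms = a.sum(axis=0)
        dead = norms == 0
        if dead.any():
            warnings.warn(f"{int(dead.sum())} zero-norm column(s): shares set to 0")
        return a / np.where(dead, 1.0, norms)

    raw = (column_shares(W1) @ column_shares(W2)).sum(axis=1)
    top = raw.max()
    values = raw / top if top > 0 else raw
    return ImportanceVector(values=values)


def occurrence_selection(
    X: np.ndarray,
    y: np.ndarray,
    config: DnnConfig | None = None,
    runs: int = 50,
    subsample: float = 0.9,
    top_quantile: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    max_retries: int = 3,
) -> SelectionResult:
    """Select features that recur in top-importance sets across resamples.

    Each of ``runs`` rounds trains the deep net on a random ``subsample``
    fraction of subjects (features z-scored per round), computes the weight-
    path importance, and marks the features in the top ``top_quantile``. A
    feature marked in ``c`` of ``runs`` rounds is tested one-sided against a
    binomial with success rate ``top_quantile``; p-values are Bonferroni-
    corrected over the M features, and features with adjusted p < ``alpha``
    are selected. A degenerate training round is retried with the next seed.

    The default network uses strong weight decay (L2 = 1): weight-path
    importance is only meaningful when irrelevant input weights are shrunk,
    and L2 spreads weight across correlated informative inputs instead of
    letting the net pick an arbitrary sparse subset per initialization.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs")
    if not 0 < top_quantile < 1:
        raise ValueError("top_quantile must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    S, M = X.shape
    config = config or DnnConfig(hidden_sizes=(64, 32), epochs=400, l2=1.0)
    n_sub = max(2, int(round(subsample * S)))

    counts = np.zeros(M, dtype=int)
    imp_sum = np.zeros(M)
    rng = np.random.default_rng(seed)
    for r in range(runs):
        for attempt in range(max_retries + 1):
            idx = rng.choice(S, size=n_sub, replace=False)
            run_seed = int(rng.integers(2**31))
            try:
                scaler = StandardScaler().fit(X[idx])
                model = fit_dnn(
                    scaler.transform(X[idx]), y[idx], replace(config, seed=run_seed)
                )
                imp = gedeon_importance(model.coefs[0], model.coefs[1]).values
                if not np.all(np.isfinite(imp)):
                    raise FloatingPointError("non-finite importance")
                break
            except (FloatingPointError, ValueError) as exc:
                warnings.warn(f"run {r} attempt {attempt} failed ({exc}); retrying")
        else:
            raise RuntimeError(f"run {r}: training failed {max_retries + 1} times")
        cutoff = np.quantile(imp, 1.0 - top_quantile)
        counts += imp >= cutoff
        imp_sum += imp

    p_raw = np.array(
        [
            binomtest(int(c), runs, top_quantile, alternative="greater").pvalue
            for c in counts
        ]
    )
    p_adj = np.minimum(1.0, p_raw * M)
    selected = np.flatnonzero(p_adj < alpha)
    return SelectionResult(
        selected=selected,
        occurrences=counts,
        p_adjusted=p_adj,
        mean_importance=imp_sum / runs,
        runs=runs,
        top_quantile=top_quantile,
        alpha=alpha,
    )


def feature_to_patch(feature_index: int, grid: PatchGrid) -> tuple[str, Patch]:
    """Invert the metric-major column ordering of the feature matrix."""
    n = grid.n_patches
    if not 0 <= feature_index < 8 * n:
        raise IndexError(f"feature index {feature_index} out of range [0, {8 * n})")
    metric = METRIC_NAMES[feature_index // n]
    return metric, grid.patches[feature_index % n]


def label_patches_with_atlas(
    grid: PatchGrid,
    atlas: np.ndarray,
    label_table: dict[int, str] | None = None,
) -> list[list[tuple[str | int, float]]]:
    """Atlas regions overlapping each patch, sorted by overlap fraction.

    ``atlas`` is an integer label volume in the grid's template space
    (label 0 = background/outside). Fractions are voxel counts divided by
    the patch volume, so they sum to the patch's in-atlas fraction.
    """
    atlas = np.asarray(atlas)
    if tuple(atlas.shape) != tuple(grid.template_shape):
        raise ValueError(
            f"atlas shape {atlas.shape} does not match template {grid.template_shape}"
        )
    l1, l2, l3 = grid.patch_dims
    n_vox = l1 * l2 * l3
    out = []
    for p in grid.patches:
        c0, c1, c2 = p.corner
        box = atlas[c0 : c0 + l1, c1 : c1 + l2, c2 : c2 + l3]
        labels, counts = np.unique(box, return_counts=True)
        pairs = [
            (label_table.get(int(lab), int(lab)) if label_table else int(lab),
             cnt / n_vox)
            for lab, cnt in zip(labels, counts)
            if lab != 0
        ]
        pairs.sort(key=lambda t: -t[1])
        out.append(pairs)
    return out
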