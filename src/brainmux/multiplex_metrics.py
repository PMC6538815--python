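"""Multiplex nodal metrics and the per-cohort feature matrix.

Eight metrics are computed per node (patch) and subject (layer):

* strength ``s_i = sum_j w_ij`` — weighted degree;
* inverse participation ``Y_i = sum_j (w_ij / s_i)^2`` — concentration of a
  node's weight over its neighbors: 1 when a single connection dominates,
  1/(N-1) when weights are uniform;
* multistrength ``m_i`` — the layer's strength at node i relative to the
  across-layer mean, ``m_i = s_i * A / o_i`` with ``o_i`` the overlapping
  strength (strength summed over the A reference layers);
* multi-inverse participation ``Ym_i = (s_i / o_i)^2`` — the layer's squared
  share of node i's across-layer strength;
* and the degree-conditional mean of each of the four, where node i receives
  the mean of the metric over all nodes sharing its exact thresholded degree.

Stacked metric-major, the feature vector has M = 8 x |N| entries per subject
(4800 on the default 600-patch grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from brainmux.network_construction import DegreeVector, Layer, layer_degrees

__all__ = [
    "METRIC_NAMES",
    "Multiplex",
    "MultiplexReference",
    "NodalFeatures",
    "FeatureMatrix",
    "strengths",
    "inverse_participation",
    "multistrength",
    "multi_inverse_participation",
    "conditional_by_degree",
    "compute_nodal_features",
    "assemble_feature_matrix",
    "MultiplexFeatureSource",
]

METRIC_NAMES = (
    "strength",
    "inverse_participation",
    "multistrength",
    "multi_inverse_participation",
    "conditional_strength",
    "conditional_inverse_participation",
    "conditional_multistrength",
    "conditional_multi_inverse_participation",
)


@dataclass
class Multiplex:
    """Ordered collection of layers sharing one grid — one layer per subject."""

    layers: list[Layer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("multiplex needs at least one layer")
        n = self.layers[0].n_nodes
        ref = self.layers[0].grid_ref
        for lay in self.layers:
            if lay.n_nodes != n or lay.grid_ref != ref:
                raise ValueError("all layers must share the same grid and node count")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def ages(self) -> np.ndarray:
        return np.array([lay.age for lay in self.layers])


@dataclass
class MultiplexReference:
    """Across-layer aggregate used by the multiplex metrics.

    ``overlapping_strength[i]`` is node i's strength summed over the
    ``layer_count`` reference layers. During cross-validation the reference
    is built from training-fold layers only and frozen for test subjects, so
    no test-subject information leaks into any feature.
    """

    overlapping_strength: np.ndarray
    layer_count: int

    @classmethod
    def from_layers(cls, layers: Sequence[Layer]) -> "MultiplexReference":
        if not layers:
            raise ValueError("reference needs at least one layer")
        o = np.zeros(layers[0].n_nodes)
        for lay in layers:
            o += strengths(lay)
        return cls(overlapping_strength=o, layer_count=len(layers))


@dataclass
class NodalFeatures:
    """The eight per-node metric vectors for one subject."""

    subject_id: str
    s: np.ndarray
    Y: np.ndarray
    m: np.ndarray
    Ym: np.ndarray
    s_k: np.ndarray
    Y_k: np.ndarray
    m_k: np.ndarray
    Ym_k: np.ndarray

    def stacked(self) -> np.ndarray:
        """Metric-major concatenation: [s | Y | m | Ym | s_k | Y_k | m_k | Ym_k]."""
        return np.concatenate(
            [self.s, self.Y, self.m, self.Ym, self.s_k, self.Y_k, self.m_k, self.Ym_k]
        )


@dataclass
class FeatureMatrix:
    """S x M feature matrix (M = 8 x |N|) with ages and column labels."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "age_years", self.y)
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def strengths(layer: Layer) -> np.ndarray:
    """s_i = sum_j w_ij (diagonal is zero, so self-similarity is excluded)."""
    return layer.weights.sum(axis=1)


def inverse_participation(layer: Layer) -> np.ndarray:
    """Y_i = sum_j (w_ij / s_i)^2; defined as 0 for isolated nodes (s_i = 0)."""
    w = layer.weights
    s = w.sum(axis=1)
    out = np.zeros_like(s)
    ok = s > 0
    if not ok.all():
        warnings.warn("isolated node(s) with zero strength: Y set to 0")
    shares = w[ok] / s[ok, None]
    out[ok] = (shares**2).sum(axis=1)
    return out


def _check_ref(layer: Layer, ref: MultiplexReference) -> None:
    if ref.overlapping_strength.shape[0] != layer.n_nodes:
        raise ValueError(
            f"reference has {ref.overlapping_strength.shape[0]} nodes, "
            f"layer has {layer.n_nodes}"
        )


def multistrength(
    layer: Layer, ref: MultiplexReference, mode: str = "relative"
) -> np.ndarray:
    """Strength of the layer relative to the across-layer mean at each node.

    Default ("relative"): ``m_i = s_i * A / o_i`` when ``o_i > 0``, else 0 —
    equal to 1 when the layer matches the multiplex average at node i.
    Alternative ("overlap"): the plain overlapping strength ``o_i`` itself,
    for comparison with conventions that aggregate rather than normalize.
    """
    _check_ref(layer, ref)
    o = ref.overlapping_strength
    if mode == "overlap":
        return o.copy()
    if mode != "relative":
        raise ValueError(f"unknown multistrength mode {mode!r}")
    s = strengths(layer)
    out = np.zeros_like(s)
    ok = o > 0
    out[ok] = s[ok] * ref.layer_count / o[ok]
    return out


def multi_inverse_participation(
    layer: Layer, ref: MultiplexReference, mode: str = "relative"
) -> np.ndarray:
    """The layer's squared share of each node's across-layer strength.

    ``Ym_i = (s_i / o_i)^2`` when ``o_i > 0``, else 0. Equals 1 when the
    layer is the sole contributor at node i, and 1/A^2 when all A reference
    layers contribute equally.
    """
    _check_ref(layer, ref)
    if mode != "relative":
        raise ValueError(f"unknown multi-inverse-participation mode {mode!r}")
    o = ref.overlapping_strength
    s = strengths(layer)
    out = np.zeros_like(s)
    ok = o > 0
    out[ok] = (s[ok] / o[ok]) ** 2
    return out


def conditional_by_degree(
    values: np.ndarray, degrees: DegreeVector, bins: int | None = None
) -> np.ndarray:
    """Per-node mean of a metric over the node's exact degree class.

    ``out_i = mean(values_j : k_j == k_i)`` — the Kronecker-delta conditional
    mean evaluated at each node's own degree. Every node belongs to its own
    class, so the mean is always defined. Optional ``bins`` quantizes degrees
    into that many equal-width bins first (for very heterogeneous degree
    sequences); default is the exact-match convention.
    """
    values = np.asarray(values, dtype=float)
    k = np.asarray(degrees.degrees)
    if values.shape != k.shape:
        raise ValueError("values and degrees must align")
    if bins is not None:
        edges = np.linspace(k.min(), k.max() + 1, bins + 1)
        k = np.digitize(k, edges[1:-1])
    classes, inverse = np.unique(k, return_inverse=True)
    sums = np.bincount(inverse, weights=values, minlength=classes.size)
    counts = np.bincount(inverse, minlength=classes.size)
    return (sums / counts)[inverse]


def compute_nodal_features(
    layer: Layer,
    ref: MultiplexReference,
    tau: float | str = "median",
    multistrength_mode: str = "relative",
) -> NodalFeatures:
    """All eight nodal metric vectors for one subject's layer."""
    deg = layer_degrees(layer, tau)
    s = strengths(layer)
    Y = inverse_participation(layer)
    m = multistrength(layer, ref, mode=multistrength_mode)
    Ym = multi_inverse_participation(layer, ref)
    return NodalFeatures(
        subject_id=layer.subject_id,
        s=s,
        Y=Y,
        m=m,
        Ym=Ym,
        s_k=conditional_by_degree(s, deg),
        Y_k=conditional_by_degree(Y, deg),
        m_k=conditional_by_degree(m, deg),
        Ym_k=conditional_by_degree(Ym, deg),
    )


def feature_columns(n_nodes: int) -> list[str]:
    """Metric-major, patch-minor column labels."""
    return [f"{metric}_{pid:04d}" for metric in METRIC_NAMES for pid in range(n_nodes)]


def assemble_feature_matrix(
    mux: Multiplex,
    ref: MultiplexReference | None = None,
    tau: float | str = "median",
    multistrength_mode: str = "relative",
) -> FeatureMatrix:
    """Stack per-subject nodal features into the S x (8|N|) matrix.

    ``ref`` defaults to the reference built from all layers of ``mux``; pass
    a training-fold reference explicitly to avoid leakage during CV.
    """
    if ref is None:
        ref = MultiplexReference.from_layers(mux.layers)
    rows = [
        compute_nodal_features(lay, ref, tau, multistrength_mode).stacked()
        for lay in mux.layers
    ]
    X = np.vstack(rows)
    return FeatureMatrix(X=X, y=mux.ages, columns=feature_columns(mux.n_nodes))


class MultiplexFeatureSource:
    """Leakage-safe feature builder for cross-validation over a multiplex.

    For each split, the multiplex reference is fitted on the training-fold
    layers only and applied to both folds, so test subjects never influence
    any feature. Layer-local metrics (s, Y, degrees) are cached up front.
    """

    def __init__(
        self,
        mux: Multiplex,
        tau: float | str = "median",
        multistrength_mode: str = "relative",
    ) -> None:
        self.mux = mux
        self.tau = tau
        self.mode = multistrength_mode
        self.y = mux.ages

    def __len__(self) -> int:
        return len(self.mux.layers)

    @property
    def n_features(self) -> int:
        return 8 * self.mux.n_nodes

    def make(
        self, train_idx: np.ndarray, test_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        ref = MultiplexReference.from_layers([self.mux.layers[i] for i in train_idx])
        rows = {}
        for i in np.concatenate([train_idx, test_idx]):
            rows[int(i)] = compute_nodal_features(
                self.mux.layers[int(i)], ref, self.tau, self.mode
            ).stacked()
        X_train = np.vstack([rows[int(i)] for i in train_idx])
        X_test = np.vstack([rows[int(i)] for i in test_idx])
        return X_train, X_test
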