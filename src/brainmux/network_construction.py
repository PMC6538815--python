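"""Per-subject weighted networks from patch-vector similarity.

Each subject contributes one layer of the multiplex: a symmetric |N| x |N|
matrix of absolute Pearson correlations between the subject's patch
intensity vectors. The absolute value folds anticorrelation onto correlation,
reflecting left/right structural symmetry. The diagonal is zero (no
self-loops), so nodal strength counts only connections to other patches.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from brainmux.volume_io import PatchVectorSet

__all__ = ["Layer", "DegreeVector", "pearson_abs", "build_layer", "layer_degrees"]


@dataclass
class Layer:
    """One subject's weighted adjacency matrix (a multiplex layer)."""

    subject_id: str
    age: float
    weights: np.ndarray  # |N| x |N|, symmetric, zero diagonal, entries in [0,1]
    grid_ref: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        """Compressed dense matrix with a JSON header sidecar."""
        path = Path(path)
        np.savez_compressed(path, weights=self.weights)
        meta = {"subject_id": self.subject_id, "age": self.age, "grid_ref": self.grid_ref}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Layer":
        path = Path(path)
        weights = np.load(path.with_suffix(".npz"))["weights"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(weights=weights, **meta)

    def to_edge_list(self, path: str | Path) -> None:
        """Export as a plain-text (i, j, w) edge list, upper triangle only."""
        n = self.n_nodes
        with open(path, "w") as fh:
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{i}\t{j}\t{self.weights[i, j]:.10g}\n")


@dataclass
class DegreeVector:
    """Thresholded node degrees of one layer."""

    degrees: np.ndarray  # integer per node
    tau: float  # resolved weight cutoff


def pearson_abs(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute Pearson correlation of two equal-length vectors.

    A zero-variance vector has no defined correlation; the weight is set to
    0 (no similarity information) with a warning rather than propagating NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt(du @ du)
    nv = np.sqrt(dv @ dv)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("zero-variance patch vector: correlation weight set to 0")
        return 0.0
    r = float(du @ dv / (nu * nv))
    return min(abs(r), 1.0)


def build_layer(p: PatchVectorSet, age: float) -> Layer:
    """Absolute-Pearson adjacency over all patch pairs of one subject.

    The upper triangle is computed once and mirrored, so the matrix is
    bit-exactly symmetric. Zero-variance rows get zero weights (warned).
    """
    X = np.asarray(p.vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 patch vectors")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    dead = norms == 0.0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance patch vector(s): weights set to 0"
        )
    safe = np.where(dead, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.abs(unit @ unit.T)
    np.clip(corr, 0.0, 1.0, out=corr)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    w = np.triu(corr, 1)
    w = w + w.T
    return Layer(subject_id=p.subject_id, age=float(age), weights=w, grid_ref=p.grid_ref)


def layer_degrees(layer: Layer, tau: float | str = "median") -> DegreeVector:
    """Node degrees of a dense weighted layer at weight cutoff ``tau``.

    ``k_i`` counts neighbors ``j != i`` with ``w_ij >= tau``. The sentinel
    ``"median"`` resolves to the median off-diagonal weight of the layer,
    which gives a non-degenerate degree distribution on arbitrary inputs.
    """
    w = layer.weights
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    if tau == "median":
        tau_val = float(np.median(w[iu]))
    else:
        tau_val = float(tau)
        if not 0.0 <= tau_val <= 1.0:
            raise ValueError("tau must be in [0, 1] or 'median'")
    above = w >= tau_val
    np.fill_diagonal(above, False)
    return DegreeVector(degrees=above.sum(axis=1).astype(int), tau=tau_val)
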