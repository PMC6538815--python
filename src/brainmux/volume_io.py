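"""Reading registered volumes, intensity normalization, hemisphere split,
and extraction of patch vectors on a fixed template grid.

Axis convention
---------------
Arrays are held in ``(coronal, axial, sagittal)`` order:

* axis 0 — coronal (anterior–posterior), patch extent ``l1``;
* axis 1 — axial (inferior–superior), patch extent ``l2``;
* axis 2 — sagittal (left–right, left hemisphere at low indices),
  patch extent ``l3``.

NIfTI images are reoriented to RAS+ on load and transposed into this order,
so every subject registered to the same template shares voxel coordinates.
Patch boxes are half-open ``[corner, corner + dims)`` in 0-based voxel
coordinates, which makes disjointness unambiguous.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "RegisteredVolume",
    "HemisphereVolume",
    "PatchGrid",
    "PatchVectorSet",
    "load_registered_volume",
    "save_registered_volume",
    "normalize_intensity",
    "split_hemispheres",
    "build_patch_grid",
    "extract_patch_vectors",
]

AXIS_LABELS = ("coronal", "axial", "sagittal")

#: default patch extents (coronal, axial, sagittal) — 10 x 15 x 20 = 3000 voxels
DEFAULT_PATCH_DIMS = (10, 15, 20)


@dataclass
class RegisteredVolume:
    """A template-registered 3D volume in (coronal, axial, sagittal) order."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = AXIS_LABELS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class HemisphereVolume:
    """One hemisphere sub-array of a registered volume."""

    data: np.ndarray
    side: str  # "left" | "right"
    origin_offset: tuple[int, int, int]  # voxel coords of this slab in the parent


@dataclass(frozen=True)
class Patch:
    """One axis-aligned box: id, hemisphere, half-open corner in template coords."""

    patch_id: int
    side: str
    corner: tuple[int, int, int]


@dataclass
class PatchGrid:
    """The fixed, cohort-shared tiling of template space into labeled boxes.

    The grid is computed once from a template mask and reused for every
    subject, so patch *i* covers the same anatomical district in all of them.
    """

    patch_dims: tuple[int, int, int]
    patches: list[Patch]
    template_shape: tuple[int, int, int]
    mask_occupancy: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def voxels_per_patch(self) -> int:
        l1, l2, l3 = self.patch_dims
        return l1 * l2 * l3

    @property
    def grid_ref(self) -> str:
        """Deterministic content hash identifying this grid."""
        payload = json.dumps(
            {
                "patch_dims": list(self.patch_dims),
                "template_shape": list(self.template_shape),
                "patches": [[p.patch_id, p.side, list(p.corner)] for p in self.patches],
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patch_dims": list(self.patch_dims),
            "template_shape": list(self.template_shape),
            "mask_occupancy": self.mask_occupancy.tolist(),
            "patches": [
                {"patch_id": p.patch_id, "side": p.side, "corner": list(p.corner)}
                for p in self.patches
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatchGrid":
        payload = json.loads(Path(path).read_text())
        return cls(
            patch_dims=tuple(payload["patch_dims"]),
            patches=[
                Patch(p["patch_id"], p["side"], tuple(p["corner"]))
                for p in payload["patches"]
            ],
            template_shape=tuple(payload["template_shape"]),
            mask_occupancy=np.asarray(payload["mask_occupancy"], dtype=float),
        )


@dataclass
class PatchVectorSet:
    """Per-subject matrix of flattened patch intensities (|N| x 3000)."""

    subject_id: str
    vectors: np.ndarray
    grid_ref: str


def load_registered_volume(path: str | Path) -> RegisteredVolume:
    """Read a 3D NIfTI volume and resolve it to the canonical axis order.

    The image is reoriented to RAS+ with nibabel, then transposed to
    (coronal, axial, sagittal). Voxel sizes are reordered accordingly.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {img.ndim}D")
    img = nib.as_closest_canonical(img)
    ras = np.asarray(img.get_fdata())
    if not np.all(np.isfinite(ras)):
        raise ValueError(f"non-finite intensities in {path}")
    # RAS axes are (sagittal, coronal, axial); reorder to (coronal, axial, sagittal)
    data = np.ascontiguousarray(ras.transpose(1, 2, 0))
    zooms = img.header.get_zooms()[:3]
    voxel_size = (float(zooms[1]), float(zooms[2]), float(zooms[0]))
    return RegisteredVolume(
        data=data, voxel_size=voxel_size, subject_id=path.name.split(".")[0]
    )


def save_registered_volume(v: RegisteredVolume, path: str | Path) -> Path:
    """Write a RegisteredVolume as NIfTI (RAS+, identity-scaled affine)."""
    path = Path(path)
    ras = np.ascontiguousarray(v.data.transpose(2, 0, 1))
    affine = np.diag([v.voxel_size[2], v.voxel_size[0], v.voxel_size[1], 1.0])
    nib.save(nib.Nifti1Image(ras, affine), str(path))
    return path


def normalize_intensity(
    v: RegisteredVolume,
    clip_percentiles: tuple[float, float] | None = None,
) -> RegisteredVolume:
    """Min–max rescale intensities to [0, 1].

    Optional percentile clipping (``clip_percentiles=(lo, hi)``) winsorizes
    outlier voxels before rescaling. A zero background stays exactly 0
    because the minimum of a skull-stripped volume is the background.
    """
    data = np.asarray(v.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite intensities")
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    dmin, dmax = float(data.min()), float(data.max())
    if dmax <= dmin:
        raise ValueError("constant volume: degenerate intensity normalization")
    out = (data - dmin) / (dmax - dmin)
    return RegisteredVolume(
        data=out,
        voxel_size=v.voxel_size,
        axis_labels=v.axis_labels,
        subject_id=v.subject_id,
    )


def split_hemispheres(v: RegisteredVolume) -> tuple[HemisphereVolume, HemisphereVolume]:
    """Split the volume at the sagittal midplane into left/right slabs.

    The left slab takes the first ``floor(dim/2)`` sagittal slices (left is
    at low indices in RAS-derived coordinates); for odd dimensions the right
    slab is one slice wider. The two slabs partition the parent volume.
    """
    s_dim = v.data.shape[2]
    mid = s_dim // 2
    left = HemisphereVolume(data=v.data[:, :, :mid], side="left", origin_offset=(0, 0, 0))
    right = HemisphereVolume(
        data=v.data[:, :, mid:], side="right", origin_offset=(0, 0, mid)
    )
    return left, right


def _tile_candidates(
    mask: np.ndarray,
    bbox_min: np.ndarray,
    bbox_max: np.ndarray,
    dims: Sequence[int],
) -> list[tuple[tuple[int, int, int], float]]:
    """Non-overlapping boxes tiling a bounding box, with mask occupancy."""
    out = []
    # anchored tiling: corners at bbox_min + i*dims, fully inside the bbox
    corners0 = range(int(bbox_min[0]), int(bbox_max[0]) + 2 - dims[0], dims[0])
    corners1 = range(int(bbox_min[1]), int(bbox_max[1]) + 2 - dims[1], dims[1])
    corners2 = range(int(bbox_min[2]), int(bbox_max[2]) + 2 - dims[2], dims[2])
    n_vox = dims[0] * dims[1] * dims[2]
    for c0 in corners0:
        for c1 in corners1:
            for c2 in corners2:
                box = mask[c0 : c0 + dims[0], c1 : c1 + dims[1], c2 : c2 + dims[2]]
                occ = float(np.count_nonzero(box)) / n_vox
                out.append(((c0, c1, c2), occ))
    return out


def build_patch_grid(
    template_mask: np.ndarray,
    patch_dims: Sequence[int] = DEFAULT_PATCH_DIMS,
    per_hemisphere: int = 300,
) -> PatchGrid:
    """Tile each hemisphere's mask bounding box and keep the fullest boxes.

    Per hemisphere, the mask's bounding box is tiled with non-overlapping
    ``patch_dims`` boxes anchored at the bounding-box minimum corner; the
    ``per_hemisphere`` boxes with highest in-mask occupancy are kept (ties
    broken by candidate order: side, then corner lexicographic). Final patch
    ids are assigned in (side, corner) order, left hemisphere first.

    The grid is computed once from the template and shared by all subjects.
    """
    mask = np.asarray(template_mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("template mask must be 3D")
    dims = tuple(int(d) for d in patch_dims)
    s_dim = mask.shape[2]
    mid = s_dim // 2

    selected: list[tuple[str, tuple[int, int, int], float]] = []
    for side, lo, hi in (("left", 0, mid), ("right", mid, s_dim)):
        hemi = np.zeros_like(mask)
        hemi[:, :, lo:hi] = mask[:, :, lo:hi]
        if not hemi.any():
            raise ValueError(f"template mask empty in {side} hemisphere")
        nz = np.nonzero(hemi)
        bbox_min = np.array([a.min() for a in nz])
        bbox_max = np.array([a.max() for a in nz])
        cands = _tile_candidates(hemi, bbox_min, bbox_max, dims)
        if len(cands) < per_hemisphere:
            raise ValueError(
                f"{side} hemisphere: only {len(cands)} candidate boxes for "
                f"per_hemisphere={per_hemisphere}"
            )
        # stable sort keeps candidate (corner-lexicographic) order among ties
        order = sorted(range(len(cands)), key=lambda i: -cands[i][1])
        keep = sorted(order[:per_hemisphere])
        for i in keep:
            corner, occ = cands[i]
            selected.append((side, corner, occ))

    # patch ids in (side, corner lexicographic) order, left first
    selected.sort(key=lambda t: (t[0] != "left", t[1]))
    patches = [Patch(i, side, corner) for i, (side, corner, _) in enumerate(selected)]
    occupancy = np.array([occ for _, _, occ in selected])
    return PatchGrid(
        patch_dims=dims,
        patches=patches,
        template_shape=tuple(mask.shape),
        mask_occupancy=occupancy,
    )


def extract_patch_vectors(v: RegisteredVolume, grid: PatchGrid) -> PatchVectorSet:
    """Flatten each grid patch of the volume into a row vector.

    Rows follow grid patch order; within a row, voxels are flattened
    coronal-major, i.e. C order on (coronal, axial, sagittal) axes. The
    order is arbitrary but must be identical across subjects.
    """
    if tuple(v.data.shape) != tuple(grid.template_shape):
        raise ValueError(
            f"volume shape {v.data.shape} does not match grid template shape "
            f"{grid.template_shape}"
        )
    l1, l2, l3 = grid.patch_dims
    vectors = np.empty((grid.n_patches, l1 * l2 * l3), dtype=float)
    for row, p in enumerate(grid.patches):
        c0, c1, c2 = p.corner
        vectors[row] = v.data[c0 : c0 + l1, c1 : c1 + l2, c2 : c2 + l3].ravel(order="C")
    return PatchVectorSet(subject_id=v.subject_id, vectors=vectors, grid_ref=grid.grid_ref)
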