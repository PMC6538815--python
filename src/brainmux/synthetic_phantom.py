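"""Synthetic aging-brain phantoms and feature-level cohorts.

Two generator tiers make the whole pipeline testable without MRI data:

* **Volume tier** — template-shaped phantoms of two cuboid "hemispheres",
  each built of nested tissue shells (outer CSF-like, mid GM-like, inner
  WM-like). Aging is emulated by two monotone effects: the GM-like intensity
  decreases linearly with the generative age (atrophy-like signal loss) and
  the CSF-like outer shell thickens linearly (sulcal widening). A smoothed
  Gaussian texture plus voxelwise noise provides subject-level variability.
  The default hemisphere extent (60 x 150 x 100 voxels, coronal x axial x
  sagittal) is chosen so the default 10 x 15 x 20 patch grid tiles each
  hemisphere into exactly 300 full-occupancy boxes.

* **Feature tier** — S x M matrices with a known subset of columns carrying
  a planted age effect (linear plus saturating sigmoid), for fast tests of
  the regression and selection machinery.

What the phantoms do not emulate: real cortical geometry, multi-site
scanner effects, registration error, and non-monotone developmental change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from brainmux.volume_io import RegisteredVolume, save_registered_volume

__all__ = [
    "PhantomSpec",
    "FeatureCohortSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_feature_cohort",
]


@dataclass
class PhantomSpec:
    """Generative parameters of the aging-brain phantom.

    Intensities are on the normalized [0, 1] scale of a T1-like contrast
    (CSF dark, WM bright). ``csf_base``/``csf_slope`` set the outer shell's
    normalized thickness and its growth per year; ``gm_slope`` is the GM-like
    intensity change per year (negative = atrophy-like darkening).
    """

    hemisphere_extent: tuple[int, int, int] = (60, 150, 100)  # coronal, axial, sagittal
    csf_intensity: float = 0.10
    gm_intensity: float = 0.50  # at age 0
    wm_intensity: float = 0.80
    gm_slope: float = -0.002  # intensity / year
    csf_base: float = 0.05  # normalized shell thickness at age 0
    csf_slope: float = 0.001  # thickness / year
    gm_thickness: float = 0.18  # normalized GM shell thickness, age-invariant
    noise_sd: float = 0.01
    texture_sd: float = 0.02
    texture_corr_length: float = 3.0  # voxels (Gaussian smoothing sigma)
    age_range: tuple[float, float] = (7.0, 80.0)

    @property
    def template_shape(self) -> tuple[int, int, int]:
        c, a, s = self.hemisphere_extent
        return (c, a, 2 * s)

    def validate(self) -> None:
        lo, hi = self.age_range
        for age in (lo, hi):
            gm = self.gm_intensity + self.gm_slope * age
            t_csf = self.csf_base + self.csf_slope * age
            if not 0.0 <= gm <= 1.0:
                raise ValueError(f"GM intensity {gm:.3f} outside [0,1] at age {age:g}")
            if not 0.0 < t_csf < 1.0 - self.gm_thickness:
                raise ValueError(
                    f"CSF shell thickness {t_csf:.3f} leaves no room for GM/WM "
                    f"at age {age:g}"
                )
        for name in ("csf_intensity", "gm_intensity", "wm_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class FeatureCohortSpec:
    """Feature-level cohort with planted age signal."""

    n: int = 300
    m: int = 100
    n_signal: int = 10
    noise_sd: float = 0.1
    age_range: tuple[float, float] = (7.0, 80.0)
    seed: int = 0


def _hemisphere_depth(extent: tuple[int, int, int]) -> np.ndarray:
    """Normalized depth from the cuboid surface: 0 at faces, 1 at the core."""
    depths = []
    for L in extent:
        u = np.arange(L)
        depths.append(np.minimum(u, L - 1 - u) / ((L - 1) / 2.0))
    d0, d1, d2 = np.meshgrid(*depths, indexing="ij")
    return np.minimum(np.minimum(d0, d1), d2)


def generate_phantom(
    age: float, spec: PhantomSpec | None = None, seed: int = 0
) -> tuple[RegisteredVolume, np.ndarray]:
    """One phantom volume and its brain mask, deterministic given (age, seed).

    Both hemispheres carry nested shells: CSF-like for normalized depth below
    the age-dependent shell thickness, GM-like in the middle band, WM-like in
    the core. GM intensity falls and the CSF shell thickens linearly with
    age; spatially smoothed Gaussian texture and voxelwise noise are added.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age:g} outside spec range [{lo:g}, {hi:g}]")
    t_csf = spec.csf_base + spec.csf_slope * age
    gm_now = spec.gm_intensity + spec.gm_slope * age

    depth = _hemisphere_depth(spec.hemisphere_extent)
    hemi = np.where(
        depth < t_csf,
        spec.csf_intensity,
        np.where(depth < t_csf + spec.gm_thickness, gm_now, spec.wm_intensity),
    )
    data = np.concatenate([hemi, hemi[:, :, ::-1]], axis=2)

    rng = np.random.default_rng(seed)
    if spec.texture_sd > 0:
        tex = gaussian_filter(
            rng.standard_normal(data.shape), sigma=spec.texture_corr_length
        )
        data = data + tex * (spec.texture_sd / tex.std())
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    np.clip(data, 0.0, 1.0, out=data)

    mask = np.ones(spec.template_shape, dtype=bool)
    vol = RegisteredVolume(data=data, subject_id=f"phantom_age{age:05.1f}")
    return vol, mask


def _draw_ages(
    n: int,
    age_range: tuple[float, float],
    rng: np.random.Generator,
    stratified: bool = False,
    bin_edges: tuple[float, ...] = (7.0, 20.0, 40.0, 60.0, 80.0),
) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least 2 subjects")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"invalid age range [{lo:g}, {hi:g}]")
    if not stratified:
        return rng.uniform(lo, hi, size=n)
    n_bins = len(bin_edges) - 1
    counts = [n // n_bins + (1 if b < n % n_bins else 0) for b in range(n_bins)]
    ages = np.concatenate(
        [
            rng.uniform(bin_edges[b], bin_edges[b + 1], size=counts[b])
            for b in range(n_bins)
        ]
    )
    rng.shuffle(ages)
    return ages


def generate_cohort(
    n: int = 120,
    age_range: tuple[float, float] | None = None,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    stratified: bool = False,
) -> tuple[list[RegisteredVolume], pd.DataFrame]:
    """A cohort of phantoms with ages drawn uniformly on the range.

    Ages are uniform on ``age_range`` (or stratified into the standard four
    lifespan bins with counts differing by at most one). Each subject gets a
    derived seed. With ``out_dir`` set, volumes are written as NIfTI and the
    cohort table as ``cohort.csv`` (subject_id, age_years).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    ages = _draw_ages(n, age_range or spec.age_range, rng, stratified)
    volumes = []
    rows = []
    for i, age in enumerate(ages):
        vol, _ = generate_phantom(float(age), spec, seed=int(rng.integers(2**31)))
        vol.subject_id = f"sub-{i:04d}"
        volumes.append(vol)
        rows.append({"subject_id": vol.subject_id, "age_years": float(age)})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for vol in volumes:
            save_registered_volume(vol, out_dir / f"{vol.subject_id}.nii.gz")
        table.to_csv(out_dir / "cohort.csv", index=False)
    return volumes, table


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_feature_cohort(
    spec: FeatureCohortSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix with planted age signal; returns (X, y, signal_indices).

    Planted columns follow ``a_j * age_n + b_j * sigmoid((age - mid)/12)``
    plus Gaussian noise, with ``age_n`` the age scaled to [-1, 1] and signed
    coefficient magnitudes drawn uniformly on [0.5, 1.5]. Null columns are
    standard normal noise. Deterministic given the spec's seed.
    """
    if spec.n_signal > spec.m:
        raise ValueError("n_signal cannot exceed the number of features")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    y = rng.uniform(lo, hi, size=spec.n)
    mid = (lo + hi) / 2.0
    age_n = (y - mid) / ((hi - lo) / 2.0)

    X = rng.standard_normal((spec.n, spec.m))
    signal_idx = rng.choice(spec.m, size=spec.n_signal, replace=False)
    signal_idx.sort()
    for j in signal_idx:
        a = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        b = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        X[:, j] = (
            a * age_n
            + b * _sigmoid((y - mid) / 12.0)
            + rng.normal(0.0, spec.noise_sd, size=spec.n)
        )
    return X, y, signal_idx
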