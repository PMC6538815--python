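"""End-to-end glue: volumes -> grid -> layers -> features -> cross-validation."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from brainmux.multiplex_metrics import Multiplex, MultiplexFeatureSource
from brainmux.network_construction import build_layer
from brainmux.regression_suite import CVResult, DnnConfig, repeated_kfold
from brainmux.synthetic_phantom import PhantomSpec, generate_cohort, generate_phantom
from brainmux.volume_io import (
    PatchGrid,
    RegisteredVolume,
    build_patch_grid,
    extract_patch_vectors,
    normalize_intensity,
)

__all__ = ["volumes_to_multiplex", "run_phantom_pipeline"]


def volumes_to_multiplex(
    volumes: Sequence[RegisteredVolume],
    ages: Sequence[float],
    grid: PatchGrid,
) -> Multiplex:
    """Normalize each volume, extract its patch vectors, and build its layer."""
    if len(volumes) != len(ages):
        raise ValueError("volumes and ages disagree on subject count")
    layers = []
    for vol, age in zip(volumes, ages):
        vecs = extract_patch_vectors(normalize_intensity(vol), grid)
        layers.append(build_layer(vecs, age))
    return Multiplex(layers=layers)


def run_phantom_pipeline(
    n: int = 120,
    spec: PhantomSpec | None = None,
    per_hemisphere: int | None = None,
    config=None,
    k: int = 10,
    repetitions: int = 5,
    seed: int = 0,
) -> tuple[CVResult, float]:
    """Full pipeline on a phantom cohort; returns (CVResult, null-model MAE).

    The null MAE is that of the best constant predictor (the mean age of the
    cohort), the natural no-information baseline for a regression pipeline.
    """
    spec = spec or PhantomSpec()
    volumes, table = generate_cohort(n=n, spec=spec, seed=seed)
    ages = table["age_years"].to_numpy()
    _, mask = generate_phantom(float(np.mean(spec.age_range)), spec, seed=0)
    if per_hemisphere is None:
        dims = (10, 15, 20)
        per_hemisphere = int(
            np.prod([e // d for e, d in zip(spec.hemisphere_extent, dims)])
        )
    grid = build_patch_grid(mask, per_hemisphere=per_hemisphere)
    mux = volumes_to_multiplex(volumes, ages, grid)
    source = MultiplexFeatureSource(mux)
    result = repeated_kfold(
        source, config=config or DnnConfig(), k=k, repetitions=repetitions, seed=seed
    )
    null_mae = float(np.mean(np.abs(ages - ages.mean())))
    return result, null_mae
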