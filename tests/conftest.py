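import numpy as np
import pytest
from hypothesis import settings

from brainmux import PhantomSpec, build_patch_grid, generate_phantom
from brainmux.multiplex_metrics import Multiplex
from brainmux.network_construction import Layer
from brainmux.pipeline import volumes_to_multiplex
from brainmux.synthetic_phantom import generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


#: small phantom whose hemispheres tile into 30 patches each (60 nodes)
SMALL_SPEC = PhantomSpec(hemisphere_extent=(30, 75, 40))


def layer_from_weights(w, subject_id="s", age=0.0, grid_ref="g"):
    w = np.asarray(w, dtype=float)
    return Layer(subject_id=subject_id, age=age, weights=w, grid_ref=grid_ref)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_grid():
    _, mask = generate_phantom(40.0, SMALL_SPEC, seed=0)
    return build_patch_grid(mask, per_hemisphere=30)


@pytest.fixture(scope="session")
def small_multiplex(small_grid):
    """12-subject phantom multiplex on the 60-node grid."""
    volumes, table = generate_cohort(n=12, spec=SMALL_SPEC, seed=42)
    return volumes_to_multiplex(volumes, table["age_years"].to_numpy(), small_grid)


@pytest.fixture(scope="session")
def toy_layer():
    """4-node layer with hand-checkable weights."""
    w = np.zeros((4, 4))
    pairs = {(0, 1): 0.9, (0, 2): 0.2, (0, 3): 0.6, (1, 2): 0.5, (1, 3): 0.1, (2, 3): 0.8}
    for (i, j), v in pairs.items():
        w[i, j] = w[j, i] = v
    return layer_from_weights(w)
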