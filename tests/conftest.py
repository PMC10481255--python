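import numpy as np
import pytest

from nawm.config import EffectConfig, GridSpec
from nawm.images import make_template


@pytest.fixture(scope="session")
def small_template():
    """16^3 template at 2.5 mm — enough voxels for voxel-wise statistics."""
    return make_template(shape=(16, 16, 16), voxel_mm=2.5, seed=42)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape=(16, 16, 16), voxel_mm=2.5)


@pytest.fixture(scope="session")
def small_study():
    """One in-memory study at desk scale (n=120, 16^3 grid)."""
    from nawm.pipeline import build_study_table

    cfg = EffectConfig(n=120, seed=2024)
    table, objs = build_study_table(
        cfg, grid=GridSpec(shape=(16, 16, 16)), return_objects=True
    )
    return table, objs


def random_blob(rng: np.random.Generator, shape=(8, 8, 8), p=0.5) -> np.ndarray:
    """Random binary mask for morphology property tests."""
    return rng.uniform(size=shape) < p
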