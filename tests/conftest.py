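import numpy as np
import pytest

from osteoflow.stacks import ImageStack, ProjectionImage
from osteoflow.synthetic import NOISELESS, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Five well-separated interior cells, no noise: the workhorse fixture."""
    spec = SceneSpec(
        image_size=(384, 384),
        n_cells=5,
        min_cell_separation=100.0,
        noise=NOISELESS,
        seed=11,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    spec = SceneSpec(
        image_size=(384, 384),
        n_cells=5,
        min_cell_separation=100.0,
        seed=11,
    )
    return generate_scene(spec)


def make_projection(dapi, phalloidin=None, runx2=None, **kwargs):
    dapi = np.asarray(dapi, dtype=np.float64)
    if phalloidin is None:
        phalloidin = np.zeros_like(dapi)
    if runx2 is None:
        runx2 = np.zeros_like(dapi)
    return ProjectionImage(
        channels={"dapi": dapi, "phalloidin": np.asarray(phalloidin, dtype=np.float64),
                  "runx2": np.asarray(runx2, dtype=np.float64)},
        **kwargs,
    )


def make_stack(dapi, phalloidin=None, runx2=None, **kwargs):
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.ndim == 2:
        dapi = dapi[None]
    if phalloidin is None:
        phalloidin = np.zeros_like(dapi)
    if runx2 is None:
        runx2 = np.zeros_like(dapi)
    return ImageStack(
        channels={"dapi": dapi, "phalloidin": np.asarray(phalloidin, dtype=np.float64),
                  "runx2": np.asarray(runx2, dtype=np.float64)},
        **kwargs,
    )
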