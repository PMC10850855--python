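import math

import numpy as np
import pytest

from cellcurate.features import PreprocessedImage
from cellcurate.mesh import CellMesh, Contour
from cellcurate.synthetic import SceneConfig, capsule_mesh, generate_dataset
from cellcurate.synthetic import dataset_tables as _dataset_tables


@pytest.fixture
def rect_mesh() -> CellMesh:
    """11-row rectangle mesh: left (x, 0), right (x, 2) for x = 0..10."""
    x = np.arange(11, dtype=float)
    return CellMesh(np.column_stack([x, np.zeros(11), x, np.full(11, 2.0)]))


@pytest.fixture
def regular_64gon() -> Contour:
    """Counter-clockwise regular 64-gon of circumradius 5 centred at origin."""
    theta = 2 * np.pi * np.arange(64) / 64
    return Contour(5.0 * np.column_stack([np.cos(theta), np.sin(theta)]),
                   normalize=False)


@pytest.fixture
def make_capsule():
    def _make(center=(60, 60), theta=0.4, length=40.0, width=10.0, n_rows=None):
        return capsule_mesh(center, theta, length, width, n_rows=n_rows)

    return _make


def flat_pimage(shape, value=0.0) -> PreprocessedImage:
    return PreprocessedImage(np.full(shape, float(value)), 0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic cells (10 frames x 20), default defect mix, fixed seed."""
    config = SceneConfig(seed=7)
    scenes = generate_dataset(config, 10)
    images, records, truth = _dataset_tables(scenes)
    return config, images, records, truth
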