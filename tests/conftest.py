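"""Shared fixtures: tiny synthetic datasets and numeric helpers."""

import numpy as np
import pytest

from rdsunet.synthetic_scenes import SceneSpec, generate_dataset


def tiny_scene_spec(image_size=64, seed=0):
    """A small-scene spec used across tests (fast to draw, all classes present)."""
    return SceneSpec(image_size=image_size, corn_scale=(10, 20),
                     weed_scale=(2, 6), n_corn=(1, 2), n_weeds=(2, 8),
                     seed=seed)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 12-scene 64x64 VOC dataset on disk, shared read-only by tests."""
    root = tmp_path_factory.mktemp("tinyvoc")
    index = generate_dataset(tiny_scene_spec(), 12, root, seed=7)
    return index


def numeric_grad(f, x, eps=1e-3):
    """Central finite differences of scalar f at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
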