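import numpy as np
import pytest

from dragoneye.orchard import build_dataset


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    """Tiny five-regime dataset (6 images per regime at 256 px)."""
    root = tmp_path_factory.mktemp("ds") / "mini"
    manifest = build_dataset(root, n_per_scene=6, image_size=256, seed=3)
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
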