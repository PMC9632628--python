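"""Synthetic scene generator: determinism, occlusion-aware labelling,
enhancement operators, dataset layout."""

import numpy as np
import pytest

from dragoneye import orchard
from dragoneye.orchard import LabeledImage, SceneSpec


def test_same_seed_is_bit_identical():
    spec = SceneSpec(seed=99, lighting="side", n_fruits=7, image_size=192)
    a, b = orchard.generate_scene(spec), orchard.generate_scene(spec)
    assert np.array_equal(a.image, b.image)
    assert a.boxes == b.boxes and a.visibility == b.visibility


def test_empty_scene_has_no_labels():
    out = orchard.generate_scene(SceneSpec(seed=1, n_fruits=0, image_size=128))
    assert out.image.shape == (128, 128, 3)
    assert out.boxes == [] and out.visibility == []


@pytest.mark.parametrize("lighting", orchard.LIGHTING_REGIMES)
def test_all_regimes_render(lighting):
    out = orchard.generate_scene(SceneSpec(seed=5, lighting=lighting, n_fruits=4,
                                           image_size=128))
    assert out.image.dtype == np.uint8
    assert all(0.0 <= b[i] <= 1.0 for b in out.boxes for i in range(1, 5))


def test_night_darker_than_front():
    night = orchard.generate_scene(SceneSpec(seed=8, lighting="night", n_fruits=0,
                                             image_size=128))
    front = orchard.generate_scene(SceneSpec(seed=8, lighting="front", n_fruits=0,
                                             image_size=128))
    assert night.image.mean() < front.image.mean()


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        SceneSpec(seed=0, lighting="noon")
    with pytest.raises(ValueError):
        SceneSpec(seed=0, fruit_scale_range=(0.3, 0.1))


class TestLabelFilter:
    def base(self, vis):
        return LabeledImage(np.zeros((8, 8, 3), np.uint8),
                            [(0, 0.5, 0.5, 0.2, 0.2)] * len(vis), list(vis))

    def test_visible_kept_hidden_dropped_boundary_kept(self):
        out = orchard.label_filter(self.base([1.0, 0.04, 0.05, 0.051]))
        assert out.visibility == [1.0, 0.05, 0.051]

    def test_occlusion_reduces_labelled_count(self):
        """Crowded scenes lose labels to the visibility rule."""
        drawn = labelled = 0
        for seed in range(40):
            spec = SceneSpec(seed=seed, n_fruits=10, occlusion_prob=0.9,
                             fruit_scale_range=(0.15, 0.3), image_size=160)
            out = orchard.generate_scene(spec)
            labelled += len(out.boxes)
            drawn += 10
        assert labelled < drawn


class TestAugment:
    @pytest.fixture()
    def scene(self):
        return orchard.generate_scene(SceneSpec(seed=21, n_fruits=5, image_size=128))

    @pytest.mark.parametrize("kind", orchard.AUGMENT_KINDS)
    def test_labels_unchanged_and_deterministic(self, scene, kind):
        a = orchard.augment(scene, kind, seed=3)
        b = orchard.augment(scene, kind, seed=3)
        assert a.boxes == scene.boxes
        assert np.array_equal(a.image, b.image)

    def test_unknown_kind_raises(self, scene):
        with pytest.raises(ValueError):
            orchard.augment(scene, "solarize", seed=0)

    def test_pixelation_idempotent(self, scene):
        once = orchard.augment(scene, "pixelation", seed=5)
        twice = orchard.augment(once, "pixelation", seed=5)
        assert np.array_equal(once.image, twice.image)

    def test_defocus_reduces_variance(self):
        drops = 0
        for seed in range(10):
            s = orchard.generate_scene(SceneSpec(seed=seed, n_fruits=6, image_size=128))
            blurred = orchard.augment(s, "defocus_blur", seed=seed)
            if blurred.image.astype(float).var() < s.image.astype(float).var():
                drops += 1
        assert drops == 10


def test_scale_controllability():
    """Mean labelled box width tracks the requested fruit-scale range."""
    def mean_width(scale_range):
        widths = []
        for seed in range(60):
            spec = SceneSpec(seed=seed, n_fruits=1, occlusion_prob=0.0,
                             fruit_scale_range=scale_range, image_size=160)
            out = orchard.generate_scene(spec)
            widths.extend(b[3] for b in out.boxes)
        return np.mean(widths)

    small, large = mean_width((0.05, 0.1)), mean_width((0.15, 0.3))
    requested_ratio = (0.15 + 0.3) / (0.05 + 0.1)
    assert large / small == pytest.approx(requested_ratio, rel=0.10)


class TestDataset:
    def test_split_counts_and_layout(self, mini_dataset):
        root, manifest = mini_dataset
        for regime, counts in manifest["scenes"].items():
            assert counts == {"train": 5, "val": 1}
        train_imgs = list((root / "images/train").glob("*.png"))
        assert len(train_imgs) == 25
        assert len(list((root / "images/val").glob("*.png"))) == 5
        # label round-trip at 1e-6
        for img in train_imgs[:5]:
            lbl = root / "labels/train" / (img.stem + ".txt")
            assert lbl.exists()
            for c, cx, cy, w, h in orchard.read_label_file(lbl):
                assert c == 0
                assert 0.0 <= cx <= 1.0 and 0.0 < w <= 1.0

    def test_label_round_trip(self, tmp_path):
        boxes = [(0, 0.123456, 0.654321, 0.111111, 0.222222)]
        p = tmp_path / "x.txt"
        orchard.write_label_file(p, boxes)
        back = orchard.read_label_file(p)
        assert np.allclose(np.array(back), np.array(boxes), atol=1e-6)

    def test_regeneration_is_identical(self, tmp_path):
        m1 = orchard.build_dataset(tmp_path / "a", n_per_scene=2, image_size=96, seed=5)
        m2 = orchard.build_dataset(tmp_path / "b", n_per_scene=2, image_size=96, seed=5)
        imgs1 = sorted((tmp_path / "a/images/train").glob("*.png"))
        imgs2 = sorted((tmp_path / "b/images/train").glob("*.png"))
        for p1, p2 in zip(imgs1, imgs2):
            assert p1.read_bytes() == p2.read_bytes()
        assert [i["seed"] for i in m1["images"]] == [i["seed"] for i in m2["images"]]
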