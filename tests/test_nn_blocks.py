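"""Block contracts: exact parameter accounting, fusion normalization,
attention shape preservation, spatial covariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dragoneye import autograd as ag
from dragoneye import nn_blocks as nb

# every parameterized configuration of the reference table, with its
# printed trainable-parameter count (the row-21 C3 slip excluded here;
# covered in the architecture tests)
TABLE_CONFIGS = [
    (nb.Conv, (3, 32, 6, 2, 2), 3520),
    (nb.GhostConv, (32, 64, 3, 2), 10144),
    (nb.C3Ghost, (64, 64, 3), 12072),
    (nb.GhostConv, (64, 128, 3, 2), 38720),
    (nb.C3Ghost, (128, 128, 4), 47040),
    (nb.CoordAttention, (128,), 6704),
    (nb.GhostConv, (128, 256, 3, 2), 151168),
    (nb.C3Ghost, (256, 256, 5), 186976),
    (nb.CoordAttention, (256,), 13360),
    (nb.GhostConv, (256, 512, 3, 2), 597248),
    (nb.C3Ghost, (512, 512, 4), 679680),
    (nb.CoordAttention, (512,), 51296),
    (nb.SPPF, (512, 512, 5), 656896),
    (nb.GhostConv, (512, 256, 1, 1), 69248),
    (nb.C3, (512, 256, 1, False), 361984),
    (nb.GhostConv, (256, 128, 1, 1), 18240),
    (nb.C3, (256, 128, 1, False), 90880),
    (nb.GhostConv, (128, 128, 3, 2), 75584),
    (nb.C3, (896, 256, 1, False), 460288),
    (nb.GhostConv, (256, 256, 3, 2), 298624),
    (nb.C3, (1024, 512, 1, False), 1444864),
]


@pytest.mark.parametrize("cls,args,expected", TABLE_CONFIGS,
                         ids=[f"{c.__name__}{a}" for c, a, _ in TABLE_CONFIGS])
def test_closed_form_equals_enumeration_equals_reference(cls, args, expected):
    """Closed-form parameter count == brute-force weight enumeration ==
    the reference per-layer value, for every configuration in the table."""
    blk = cls(*args)
    assert blk.closed_form_params() == expected
    assert blk.param_count() == expected


def test_minimal_conv_and_derived_subcounts():
    assert nb.Conv(1, 1, 1, 1).param_count() == 3
    assert nb.Conv(512, 256, 1, 1).param_count() == 131584  # SPPF reduce conv
    assert nb.SPPF(64, 64, 5).param_count() == 10432


def test_ghost_bottleneck_counts_and_stride2_rejection():
    assert nb.GhostBottleneck(32, 32).param_count() == 1208
    assert nb.GhostBottleneck(128, 128).param_count() == 10976
    with pytest.raises(NotImplementedError):
        nb.GhostBottleneck(32, 32, s=2)
    with pytest.raises(ValueError):
        nb.GhostConv(16, 31)  # odd output width
    with pytest.raises(ValueError):
        nb.Conv(0, 4, 1, 1)


def test_detect_head_counts():
    assert nb.Detect([128, 256, 512], nc=1, no_override=30).param_count() == 26970
    assert nb.detect_head([128, 256, 512], n_anchors=3, n_classes=1).param_count() == 16182
    assert nb.detect_head([1], n_anchors=1, n_classes=1, no_override=1).param_count() == 2


@pytest.mark.parametrize("c", [64, 128, 256, 512])
def test_ghost_compression_approaches_the_split_factor(c):
    """params(plain conv) / params(ghost conv) -> s as channels grow."""
    plain = nb.Conv(c, c, 3, 1).param_count()
    ghost = nb.GhostConv(c, c, 3, 1).param_count()
    ratio = plain / ghost
    assert 2 * 0.8 <= ratio <= 2 * 1.05
    # and the closed-form ratio of the ghost-module analysis agrees
    rc = nb.ghost_compression_ratio(c, c, 3)
    assert 2 * 0.8 <= rc <= 2.0


@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6))
@settings(max_examples=50, deadline=None)
def test_fusion_weights_normalize_into_unit_interval(raw):
    fuse = nb.BiFPNConcat(len(raw))
    fuse.w.data[...] = np.array(raw, dtype=np.float32)
    w = fuse.normalized_weights()
    assert np.all(w >= 0.0) and np.all(w <= 1.0)
    assert w.sum() <= 1.0  # sum = S/(S+eps) < 1


def test_fusion_init_symmetric_and_channel_sum(rng):
    fuse = nb.BiFPNConcat(3)
    xs = [ag.Tensor(rng.normal(size=(1, c, 4, 4)).astype(np.float32))
          for c in (128, 512, 256)]
    out = fuse(xs)
    assert out.shape == (1, 896, 4, 4)
    w = fuse.normalized_weights()
    np.testing.assert_allclose(w, w[::-1], atol=1e-7)  # symmetric at init
    with pytest.raises(ValueError):
        fuse([xs[0], xs[1], ag.Tensor(np.zeros((1, 4, 8, 8), np.float32))])
    with pytest.raises(ValueError):
        nb.BiFPNConcat(0)


def test_coord_attention_preserves_shape_and_can_be_identity(rng):
    blk = nb.CoordAttention(32).eval()
    x = rng.normal(size=(2, 32, 8, 6)).astype(np.float32)
    y = blk(ag.Tensor(x))
    assert y.shape == x.shape
    # force both gates to ~1: zero the gate batch-norm scales, large shifts
    for conv in (blk.conv_h, blk.conv_w):
        conv.bn.weight.data[...] = 0.0
        conv.bn.bias.data[...] = 30.0
    y1 = blk(ag.Tensor(x))
    np.testing.assert_allclose(y1.data, x, atol=1e-4)


def test_ghost_bottleneck_shortcut_passes_input_through_zero_branch(rng):
    blk = nb.GhostBottleneck(16, 16).eval()
    for p in blk.parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(1, 16, 5, 5)).astype(np.float32)
    y = blk(ag.Tensor(x))
    np.testing.assert_allclose(y.data, x, atol=1e-6)


@pytest.mark.parametrize(
    "blk,stride",
    [
        (nb.Conv(8, 8, 3, 2), 2),
        (nb.GhostConv(8, 16, 3, 2), 2),
        (nb.C3Ghost(16, 16, 1), 1),
        (nb.SPPF(16, 16, 5), 1),
        (nb.CoordAttention(16), 1),
    ],
    ids=["conv", "ghost", "c3ghost", "sppf", "cam"],
)
def test_spatial_covariance(blk, stride, rng):
    blk.eval()
    c_in = blk.c1 if hasattr(blk, "c1") else blk.c
    x1 = rng.normal(size=(1, c_in, 8, 8)).astype(np.float32)
    x2 = rng.normal(size=(1, c_in, 16, 16)).astype(np.float32)
    y1, y2 = blk(ag.Tensor(x1)), blk(ag.Tensor(x2))
    assert y2.shape[2] == 2 * y1.shape[2] == 16 // stride
    assert y2.shape[3] == 2 * y1.shape[3]


def test_sppf_internal_concat_width():
    blk = nb.SPPF(512, 512, 5)
    assert blk.cv2.c1 == 1024  # 4 x 256
    with pytest.raises(ValueError):
        nb.SPPF(64, 64, 4)
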