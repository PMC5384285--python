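"""Co-localization mask and remyelination index."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restage.errors import ComputationError, ValidationError
from restage.remyelination_imaging import (
    ColocParams,
    ImageStack,
    coloc_mask,
    condition_index,
    layer_remyelination_index,
    read_stack,
    split_channels,
    stack_index,
    write_stack,
)
from restage.synthetic_data import StackSimParams, simulate_confocal_stack

FIXED = ColocParams(green_threshold=100, red_threshold=100)


def brute_force_mask(green, red, gt, rt):
    h, w = green.shape
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            mask[i, j] = green[i, j] > gt and red[i, j] > rt
    return mask


class TestSplitChannels:
    def test_two_channel_split(self):
        stack = ImageStack(np.zeros((5, 8, 8, 2), dtype=np.uint8))
        green, red = split_channels(stack)
        assert green.shape == red.shape == (5, 8, 8)

    def test_rgb_blue_ignored(self):
        voxels = np.zeros((2, 4, 4, 3), dtype=np.uint8)
        voxels[..., 2] = 255
        green, red = split_channels(ImageStack(voxels))
        assert green.max() == 0 and red.max() == 0

    def test_single_channel_rejected(self):
        with pytest.raises(ValidationError):
            split_channels(ImageStack(np.zeros((2, 4, 4, 1)), channels={"green": 0, "red": 0}))

    def test_missing_role_rejected(self):
        with pytest.raises(ValidationError, match="red"):
            split_channels(ImageStack(np.zeros((2, 4, 4, 2)), channels={"green": 1}))


class TestColocMask:
    def test_no_green_empty_mask(self):
        green = np.zeros((8, 8))
        red = np.full((8, 8), 200.0)
        assert not coloc_mask(green, red, FIXED).any()

    def test_saturated_full_mask(self):
        sat = np.full((8, 8), 255.0)
        assert coloc_mask(sat, sat, FIXED).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            coloc_mask(np.zeros((4, 4)), np.zeros((5, 5)), FIXED)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            green = rng.integers(0, 256, (16, 16)).astype(float)
            red = rng.integers(0, 256, (16, 16)).astype(float)
            expected = brute_force_mask(green, red, 100, 100)
            np.testing.assert_array_equal(coloc_mask(green, red, FIXED), expected)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_mask_subset_of_channel_masks(self, seed):
        rng = np.random.default_rng(seed)
        green = rng.integers(0, 256, (16, 16)).astype(float)
        red = rng.integers(0, 256, (16, 16)).astype(float)
        mask = coloc_mask(green, red, FIXED)
        assert not (mask & ~(green > 100)).any()
        assert not (mask & ~(red > 100)).any()


class TestLayerIndex:
    def test_full_coloc_gives_one(self):
        red = np.zeros((8, 8))
        red[2:6, 2:6] = 200
        lc = layer_remyelination_index(red.copy(), red, FIXED)
        assert lc.index == pytest.approx(1.0)

    def test_no_green_gives_zero(self):
        red = np.full((8, 8), 200.0)
        lc = layer_remyelination_index(np.zeros((8, 8)), red, FIXED)
        assert lc.index == 0.0 and lc.nfh_pixels == 64

    def test_no_red_undefined(self):
        lc = layer_remyelination_index(np.full((8, 8), 200.0), np.zeros((8, 8)), FIXED)
        assert lc.index is None

    def test_index_invariant_to_joint_monotone_rescale(self):
        rng = np.random.default_rng(5)
        green = rng.integers(0, 256, (16, 16)).astype(float)
        red = rng.integers(0, 256, (16, 16)).astype(float)
        base = layer_remyelination_index(green, red, FIXED)
        scaled = layer_remyelination_index(
            2 * green + 10,
            2 * red + 10,
            ColocParams(green_threshold=210, red_threshold=210),
        )
        assert scaled.index == base.index
        assert scaled.coloc_pixels == base.coloc_pixels


class TestStackIndex:
    def _stack(self, layer_fracs):
        """Stack whose layer l has exactly frac of a 10x10 axon block green."""
        layers = []
        for f in layer_fracs:
            vox = np.zeros((10, 10, 2))
            vox[..., 0] = 200  # red everywhere
            n = int(round(f * 100))
            vox.reshape(100, 2)[:n, 1] = 200
            layers.append(vox)
        return ImageStack(np.stack(layers).astype(np.uint8))

    def test_mean_over_layers(self):
        si = stack_index(self._stack([0.2, 0.4]), FIXED)
        assert si.stack_index == pytest.approx(0.3)
        assert si.n_layers_used == 2

    def test_single_layer(self):
        si = stack_index(self._stack([0.7]), FIXED)
        assert si.stack_index == pytest.approx(0.7)

    def test_undefined_layers_excluded(self):
        stack = self._stack([0.2, 0.4])
        stack.voxels[1, ..., 0] = 0  # kill red in layer 1
        si = stack_index(stack, FIXED)
        assert si.n_layers_used == 1
        assert si.stack_index == pytest.approx(0.2)

    def test_all_undefined_raises(self):
        stack = ImageStack(np.zeros((3, 8, 8, 2), dtype=np.uint8))
        with pytest.raises(ComputationError):
            stack_index(stack, FIXED)

    @pytest.mark.parametrize("f", [0.0, 0.4, 1.0])
    def test_synthetic_fraction_recovery(self, f):
        stack, truth = simulate_confocal_stack(
            StackSimParams(height=128, width=128, myelin_fraction=f, seed=21)
        )
        si = stack_index(stack, FIXED)
        assert si.stack_index == pytest.approx(f, abs=0.02)

    def test_otsu_mode_recovers_fraction(self):
        stack, _ = simulate_confocal_stack(
            StackSimParams(height=128, width=128, myelin_fraction=0.4, seed=21)
        )
        si = stack_index(stack, ColocParams(threshold_mode="otsu_per_channel"))
        assert si.stack_index == pytest.approx(0.4, abs=0.05)


class TestConditionIndex:
    def test_mean_sem(self):
        ci = condition_index("drug", [0.3, 0.3, 0.3])
        assert (ci.mean, ci.sem) == (pytest.approx(0.3), pytest.approx(0.0))

    def test_relative_index(self):
        control = condition_index("control", [0.2, 0.2])
        drug = condition_index("drug", [0.4, 0.4], control=control)
        assert drug.relative_index == pytest.approx(2.0)

    def test_zero_control_mean_flagged(self):
        control = condition_index("control", [0.0, 0.0])
        drug = condition_index("drug", [0.4], control=control)
        assert drug.relative_index is None

    def test_empty_condition_raises(self):
        with pytest.raises(ComputationError):
            condition_index("drug", [])


def test_tiff_roundtrip(tmp_path):
    stack, _ = simulate_confocal_stack(
        StackSimParams(layers=3, height=32, width=32, myelin_fraction=0.5, seed=9)
    )
    path = tmp_path / "stack.tif"
    write_stack(stack, path)
    loaded = read_stack(path, green_channel=1, red_channel=0)
    np.testing.assert_array_equal(loaded.voxels, stack.voxels)
    assert stack_index(loaded, FIXED).stack_index == stack_index(stack, FIXED).stack_index
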