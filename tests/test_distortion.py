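import numpy as np
import pytest
from scipy import ndimage

from t1234.distortion import (
    DisplacementField,
    apply_field,
    estimate_field,
    load_field,
    save_field,
    scale_field,
    synthesize_matched,
    warp_1d,
)


@pytest.fixture(scope="module")
def blob_image():
    """Smooth synthetic test image (48^3) with internal structure."""
    n = 48
    x, y, z = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
    c = (n - 1) / 2
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    img = np.clip(1.0 - (r / (0.42 * n)) ** 2, 0.0, None)
    img += 0.5 * np.exp(-((x - 0.62 * n) ** 2 + (y - 0.4 * n) ** 2 + (z - 0.55 * n) ** 2) / 30)
    return ndimage.gaussian_filter(img, 1.0)


@pytest.fixture(scope="module")
def known_field(blob_image):
    n = blob_image.shape[0]
    x, y, z = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
    d = 2.0 * np.exp(-((x - 0.45 * n) ** 2 + (y - 0.55 * n) ** 2 + (z - 0.45 * n) ** 2) / (2 * (0.14 * n) ** 2))
    return d


@pytest.fixture(scope="module")
def distorted_pair(blob_image, known_field):
    pos = warp_1d(blob_image, +known_field, 1, jacobian=True)
    neg = warp_1d(blob_image, -known_field, 1, jacobian=True)
    return pos, neg


class TestWarp:
    def test_zero_field_is_identity(self, blob_image):
        f = DisplacementField(np.zeros_like(blob_image), pe_axis=1, eff_esp=1.0)
        np.testing.assert_array_equal(apply_field(blob_image, f), blob_image)

    def test_constant_field_is_edge_padded_shift(self):
        img = np.arange(4 * 8 * 4, dtype=float).reshape(4, 8, 4)
        f = DisplacementField(np.full(img.shape, 3.0), pe_axis=1, eff_esp=1.0)
        out = apply_field(img, f, jacobian=False)
        np.testing.assert_array_equal(out[:, :5, :], img[:, 3:, :])
        # edge padding repeats the boundary value
        np.testing.assert_array_equal(out[:, 5:, :], np.repeat(img[:, -1:, :], 3, axis=1))

    def test_forward_backward_round_trip(self, blob_image, known_field):
        warped = warp_1d(blob_image, +known_field, 1)
        back = warp_1d(warped, -known_field, 1)
        rmse = np.sqrt(np.mean((back - blob_image) ** 2))
        assert rmse < 0.01 * (blob_image.max() - blob_image.min())


class TestScaleField:
    def test_identity_zero_and_group_property(self):
        d = np.random.default_rng(0).normal(size=(6, 6, 6))
        f = DisplacementField(d.copy(), pe_axis=1, eff_esp=0.5)
        assert np.array_equal(scale_field(f, 1.0).d, d)
        assert np.all(scale_field(f, 0.0).d == 0)
        np.testing.assert_array_equal(scale_field(scale_field(f, 2.0), 0.5).d, d)
        assert scale_field(f, 2.0).eff_esp == 1.0

    def test_non_finite_factor_rejected(self):
        f = DisplacementField(np.zeros((4, 4, 4)), pe_axis=1, eff_esp=0.5)
        with pytest.raises(ValueError):
            scale_field(f, np.inf)


class TestEstimateField:
    def test_identical_images_give_null_field(self, blob_image):
        f = estimate_field(blob_image, blob_image, pe_axis=1)
        assert np.max(np.abs(f.d)) < 0.05

    def test_recovers_known_field(self, blob_image, known_field, distorted_pair):
        pos, neg = distorted_pair
        f = estimate_field(pos, neg, pe_axis=1)
        mask = blob_image > 0.05
        rmse = np.sqrt(np.mean((f.d[mask] - known_field[mask]) ** 2))
        assert rmse < 0.3

    def test_swapping_inputs_negates_the_field(self, distorted_pair):
        pos, neg = distorted_pair
        f1 = estimate_field(pos, neg, pe_axis=1)
        f2 = estimate_field(neg, pos, pe_axis=1)
        assert np.max(np.abs(f1.d + f2.d)) < 0.05

    def test_data_term_non_increasing_within_each_level(self, distorted_pair):
        pos, neg = distorted_pair
        f = estimate_field(pos, neg, pe_axis=1)
        for level in f.ssd_history:
            assert np.all(np.diff(level) <= 1e-15)

    def test_equivariant_under_perpendicular_translation(self, blob_image, known_field):
        # shifting both inputs along a non-PE axis shifts the field with them
        pos = warp_1d(blob_image, +known_field, 1)
        neg = warp_1d(blob_image, -known_field, 1)
        shift = 4
        f0 = estimate_field(pos, neg, pe_axis=1)
        fs = estimate_field(np.roll(pos, shift, axis=0), np.roll(neg, shift, axis=0), pe_axis=1)
        mask = np.roll(blob_image > 0.05, shift, axis=0)
        diff = np.abs(fs.d - np.roll(f0.d, shift, axis=0))[mask]
        # the spline lattice is fixed in space, so equivariance holds at the
        # accuracy level of the estimate rather than voxel-exactly
        assert np.median(diff) < 0.1
        rmse = np.sqrt(np.mean((fs.d - np.roll(known_field, shift, axis=0))[mask] ** 2))
        assert rmse < 0.3


class TestSynthesizeMatched:
    def test_zero_target_returns_input(self, blob_image):
        f = DisplacementField(np.random.default_rng(1).normal(size=blob_image.shape),
                              pe_axis=1, eff_esp=0.5)
        out = synthesize_matched(blob_image, f, 0.0)
        np.testing.assert_array_equal(out, blob_image)

    def test_source_target_reproduces_distorted_input(self, blob_image, known_field, distorted_pair):
        pos, _ = distorted_pair
        f = DisplacementField(known_field.copy(), pe_axis=1, eff_esp=0.5)
        out = synthesize_matched(blob_image, f, 0.5)
        rmse = np.sqrt(np.mean((out - pos) ** 2))
        assert rmse < 0.02 * (pos.max() - pos.min())

    def test_double_target_matches_fresh_simulation(self, blob_image, known_field):
        f = DisplacementField(known_field.copy(), pe_axis=1, eff_esp=0.5)
        out = synthesize_matched(blob_image, f, 1.0)
        fresh = warp_1d(blob_image, 2.0 * known_field, 1, jacobian=True)
        rmse = np.sqrt(np.mean((out - fresh) ** 2))
        assert rmse < 0.03 * (fresh.max() - fresh.min())

    def test_zero_source_esp_rejected(self, blob_image):
        f = DisplacementField(np.zeros_like(blob_image), pe_axis=1, eff_esp=0.0)
        with pytest.raises(ValueError):
            synthesize_matched(blob_image, f, 0.35)


class TestFieldIO:
    def test_nifti_round_trip(self, tmp_path):
        d = np.random.default_rng(4).normal(size=(8, 8, 8)).astype(np.float32)
        f = DisplacementField(d.astype(float), pe_axis=1, eff_esp=0.075, smoothness=0.1)
        path = tmp_path / "field.nii"
        save_field(f, path)
        back = load_field(path)
        np.testing.assert_allclose(back.d, f.d, atol=1e-6)
        assert back.pe_axis == 1
        assert back.eff_esp == pytest.approx(0.075)
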