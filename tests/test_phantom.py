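import numpy as np
import pytest
from scipy import ndimage

from t1234.distortion import warp_1d
from t1234.phantom import (
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    acquire_full_session,
    ideal_signal_volume,
    make_phantom,
    simulate_acquisition,
    true_displacement,
)
from t1234.protocol import effective_echo_spacing


class TestMakePhantom:
    def test_deterministic_given_seed(self):
        a = make_phantom((40, 40, 40), seed=5)
        b = make_phantom((40, 40, 40), seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.b0_map, b.b0_map)
        assert np.array_equal(a.b1_map, b.b1_map)
        assert np.array_equal(a.depth_map, b.depth_map, equal_nan=True)

    def test_different_seeds_differ(self):
        a = make_phantom((40, 40, 40), seed=0)
        b = make_phantom((40, 40, 40), seed=1)
        assert not np.array_equal(a.b0_map, b.b0_map)

    def test_all_four_labels_present(self, phantom64):
        counts = np.bincount(phantom64.labels.ravel(), minlength=4)
        assert np.all(counts[[0, LABEL_CSF, LABEL_GM, LABEL_WM]] > 0)

    def test_ribbon_at_least_three_voxels_thick(self, phantom64):
        # central lines along each axis: every contiguous GM run must be >= 3
        gm = phantom64.labels == LABEL_GM
        cx, cy, cz = (n // 2 for n in gm.shape)
        lines = [gm[:, cy, cz], gm[cx, :, cz], gm[cx, cy, :]]
        run_lengths = []
        for line in lines:
            padded = np.concatenate([[0], line.astype(int), [0]])
            edges = np.diff(padded)
            starts, stops = np.where(edges == 1)[0], np.where(edges == -1)[0]
            run_lengths.extend(stops - starts)
        assert run_lengths and min(run_lengths) >= 3

    def test_depth_map_normalized_on_ribbon_only(self, phantom64):
        gm = phantom64.labels == LABEL_GM
        assert np.nanmin(phantom64.depth_map[gm]) == 0.0
        assert np.nanmax(phantom64.depth_map[gm]) == 1.0
        assert np.all(np.isnan(phantom64.depth_map[~gm]))

    def test_b1_field_in_stated_range(self, phantom64):
        assert phantom64.b1_map.min() >= 0.7 - 1e-12
        assert phantom64.b1_map.max() <= 1.3 + 1e-12

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((16, 64, 64))


class TestSimulateAcquisition:
    def test_artifact_free_limit_equals_ideal(self, phantom64, retro):
        ideal = ideal_signal_volume(phantom64, retro, 1)
        zero_b0 = make_phantom((64, 64, 64), seed=0, b0_blob_amplitude_hz=0.0)
        zero_b0.b0_map[:] = 0.0
        ideal0 = ideal_signal_volume(zero_b0, retro, 1)
        for read_pol in (1, -1):
            for phase_pol in (1, -1):
                v = simulate_acquisition(
                    zero_b0, retro, read_pol, phase_pol, which_ti=1,
                    noise_sigma=0.0, ghost_amp=0.0, ripple_amp=0.0,
                )
                np.testing.assert_array_equal(v.data.real, ideal0)
                np.testing.assert_array_equal(v.data.imag, 0.0)
        assert ideal.shape == ideal0.shape

    def test_opposite_phase_polarities_have_opposite_displacement(self, phantom64, retro):
        # oracle: the analytic displacement field from the known B0 map
        esp = 1.0
        ideal = ideal_signal_volume(phantom64, retro, 2)
        vp = simulate_acquisition(phantom64, retro, 1, 1, which_ti=2,
                                  ghost_amp=0.0, ripple_amp=0.0, eff_esp_ms=esp)
        vn = simulate_acquisition(phantom64, retro, 1, -1, which_ti=2,
                                  ghost_amp=0.0, ripple_amp=0.0, eff_esp_ms=esp)
        d = true_displacement(phantom64, esp, pe_axis=1, phase_polarity=1)
        np.testing.assert_allclose(vp.data.real, warp_1d(ideal, +d, 1), atol=1e-12)
        np.testing.assert_allclose(vn.data.real, warp_1d(ideal, -d, 1), atol=1e-12)

    def test_deterministic_under_seed(self, phantom64, retro):
        a = simulate_acquisition(phantom64, retro, 1, 1, noise_sigma=0.01, seed=9)
        b = simulate_acquisition(phantom64, retro, 1, 1, noise_sigma=0.01, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_distortion_step_conserves_intensity(self, phantom64, retro):
        ideal = ideal_signal_volume(phantom64, retro, 2)
        d = true_displacement(phantom64, 1.0, pe_axis=1, phase_polarity=1)
        warped = warp_1d(ideal, d, 1, jacobian=True)
        rel = abs(np.sum(np.abs(warped)) - np.sum(np.abs(ideal))) / np.sum(np.abs(ideal))
        assert rel < 0.005

    def test_ghost_energy_scales_linearly_with_amplitude(self, phantom64, retro):
        brain = phantom64.brain_mask
        roi = np.roll(brain, brain.shape[1] // 2, axis=1) & ~ndimage.binary_dilation(brain, iterations=3)
        energies = []
        for amp in (0.02, 0.04, 0.08):
            v = simulate_acquisition(phantom64, retro, 1, 1, which_ti=2,
                                     ghost_amp=amp, ripple_amp=0.0)
            energies.append(np.sqrt(np.sum(np.abs(v.data[roi]) ** 2)))
        assert energies[1] == pytest.approx(2 * energies[0], rel=1e-6)
        assert energies[2] == pytest.approx(4 * energies[0], rel=1e-6)

    def test_invalid_polarity_rejected(self, phantom64, retro):
        with pytest.raises(ValueError):
            simulate_acquisition(phantom64, retro, 0, 1)


class TestFullSession:
    def test_eight_volumes_with_four_distinct_polarity_pairs(self, phantom64, retro):
        vols = acquire_full_session(phantom64, retro, ghost_amp=0.0, ripple_amp=0.0)
        assert len(vols) == 8
        pairs = {(v.read_polarity, v.phase_polarity) for v in vols}
        assert pairs == {(1, 1), (1, -1), (-1, 1), (-1, -1)}
        assert {v.which_ti for v in vols} == {1, 2}

    def test_sidecar_echo_spacing_matches_protocol(self, phantom64, retro):
        vols = acquire_full_session(phantom64, retro, ghost_amp=0.0, ripple_amp=0.0)
        for v in vols:
            assert v.sidecar()["eff_esp_ms"] == effective_echo_spacing(retro)

    def test_session_reproducible_with_noise(self, phantom64, retro):
        a = acquire_full_session(phantom64, retro, noise_sigma=0.005, seed=3)
        b = acquire_full_session(phantom64, retro, noise_sigma=0.005, seed=3)
        for va, vb in zip(a, b):
            assert np.array_equal(va.data, vb.data)
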