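import numpy as np
import pytest

from dsstream.isoi import (
    areal_response_strength,
    delay_corrected_retinotopy,
    detect_borders,
    fourier_component_map,
    neighbor_filter,
    phase_to_degrees,
    stimulus_frequency,
    threshold_and_clean,
    visual_field_sign,
    wrap_phase,
)
from dsstream.protocols import make_stimulus_protocol
from dsstream.simulate_imaging import (
    default_six_area_layout,
    layout_ground_truth,
    synthesize_isoi_grating_stack,
    synthesize_retinotopy_stack,
)


class TestFourierComponent:
    FR, F = 6.0, 0.1

    def _stack(self, phase0, amp=1.0, n_s=200):
        t = np.arange(int(n_s * self.FR)) / self.FR
        return amp * np.cos(2 * np.pi * self.F * t + phase0)[:, None, None]

    def test_cosine_phase_zero(self):
        phase, mag = fourier_component_map(self._stack(0.0), self.FR, self.F)
        assert phase[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert mag[0, 0] == pytest.approx(1.0, rel=1e-6)

    def test_quarter_cycle_lag(self):
        phase, _ = fourier_component_map(self._stack(-np.pi / 2), self.FR, self.F)
        assert phase[0, 0] == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_multifrequency_pixel_separates_components(self):
        t = np.arange(int(200 * self.FR)) / self.FR
        sig = (0.7 * np.cos(2 * np.pi * self.F * t + 0.3)
               + 1.5 * np.cos(2 * np.pi * 0.35 * t - 1.0))
        _, mag = fourier_component_map(sig[:, None, None], self.FR, self.F)
        assert mag[0, 0] == pytest.approx(0.7, rel=0.02)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fourier_component_map(self._stack(0.0), self.FR, 4.0)


class TestDelaySubtraction:
    def test_pure_delay(self):
        delta = 0.7
        pf = np.full((4, 4), delta)
        pr = np.full((4, 4), delta)
        retino, delay = delay_corrected_retinotopy(pf, pr)
        assert np.allclose(retino, 0.0, atol=1e-12)
        assert delay == pytest.approx(delta)

    def test_phase_plus_delay(self):
        theta = np.linspace(-3.0, 3.0, 64).reshape(8, 8)  # nearly full range
        delta = 0.4
        retino, delay = delay_corrected_retinotopy(
            wrap_phase(theta + delta), wrap_phase(-theta + delta))
        assert np.allclose(wrap_phase(retino - theta), 0.0, atol=1e-9)
        assert delay == pytest.approx(delta)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            delay_corrected_retinotopy(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPhaseToDegrees:
    def test_linear_mapping(self):
        assert phase_to_degrees(np.array(0.0), 134.46) == pytest.approx(0.0)
        assert phase_to_degrees(np.array(np.pi / 2), 134.46) == pytest.approx(33.615)
        ramp = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        deg = phase_to_degrees(ramp, 100.0)
        assert deg[0] == pytest.approx(-50.0)
        assert deg[-1] == pytest.approx(49.0)


class TestStimulusFrequency:
    @pytest.mark.parametrize("extent, speed, expected", [
        (134.46, 9.0, 0.067), (102.75, 9.0, 0.088), (10.0, 10.0, 1.0)])
    def test_printed_values(self, extent, speed, expected):
        assert stimulus_frequency(extent, speed) == pytest.approx(expected, abs=5e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            stimulus_frequency(0.0, 9.0)


class TestSignMap:
    def test_standard_orientation_positive(self):
        y, x = np.mgrid[0:40, 0:40].astype(float)
        sign = visual_field_sign(x, y, smooth_sigma=0.0)
        assert np.allclose(sign[5:-5, 5:-5], 1.0)

    def test_mirrored_azimuth_negative(self):
        y, x = np.mgrid[0:40, 0:40].astype(float)
        sign = visual_field_sign(-x, y, smooth_sigma=0.0)
        assert np.allclose(sign[5:-5, 5:-5], -1.0)

    def test_flat_map_gives_zero(self):
        sign = visual_field_sign(np.zeros((10, 10)), np.zeros((10, 10)),
                                 smooth_sigma=0.0)
        assert np.allclose(sign, 0.0)

    def test_threshold_keeps_strong_pixels_only(self):
        rng = np.random.default_rng(0)
        sign = rng.normal(0.0, 0.02, size=(40, 40))
        sign[5:15, 5:15] = 1.0
        sign[25:35, 25:35] = -1.0
        sm = threshold_and_clean(sign)
        assert sm.mask[8, 8] and sm.mask[30, 30]
        assert sm.signed_mask[8, 8] == 1 and sm.signed_mask[30, 30] == -1
        assert not sm.mask[20, 20]

    def test_constant_map_empty_mask(self):
        sm = threshold_and_clean(np.full((20, 20), 0.5))
        assert not sm.mask.any()


class TestNeighborFilter:
    def test_five_neighbors_kept_four_removed(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        m[1, 1:4] = True  # 3 neighbors
        m[3, 1:3] = True  # +2 -> 5 neighbors
        assert neighbor_filter(m)[2, 2]
        m[3, 2] = False  # down to 4 neighbors
        assert not neighbor_filter(m)[2, 2]

    def test_solid_block_interior_kept_and_hole_filled(self):
        m = np.ones((8, 8), bool)
        m[4, 4] = False  # interior hole
        out = neighbor_filter(m)
        assert out[3:6, 3:6].all()  # hole filled, interior kept


class TestDetectBorders:
    def test_single_block_geometry(self):
        m = np.zeros((30, 30), bool)
        m[10:20, 5:15] = True
        seg = detect_borders(m, pixel_size_mm=0.01)
        assert seg.area_mm2[0] == pytest.approx(100 * 0.01 ** 2)
        assert np.allclose(seg.centroids_px[0], (14.5, 9.5))

    def test_two_blocks_relative_coordinates(self):
        m = np.zeros((40, 40), bool)
        m[5:15, 5:15] = True       # 100 px
        m[25:38, 20:36] = True     # 208 px -> reference (largest)
        seg = detect_borders(m, pixel_size_mm=0.1)
        assert len(seg.area_mm2) == 2
        ref = np.argmax(seg.area_mm2)
        other = 1 - ref
        shift = seg.centroids_px[other] - seg.centroids_px[ref]
        assert np.allclose(seg.centroids_rel_mm[other], shift * 0.1)

    def test_translation_moves_centroid_not_size(self):
        m = np.zeros((40, 40), bool)
        m[5:15, 5:15] = True
        m2 = np.roll(m, (7, 3), axis=(0, 1))
        s1 = detect_borders(m)
        s2 = detect_borders(m2)
        assert s1.area_mm2[0] == pytest.approx(s2.area_mm2[0])
        assert np.allclose(s2.centroids_px[0] - s1.centroids_px[0], (7, 3))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_borders(np.zeros((5, 5), bool))


class TestArealResponse:
    FR = 6.0

    def _stack(self, amps):
        """(h, w) amplitude map -> stack with 10-s pre segment + 0.05 Hz."""
        t = np.arange(int(80 * self.FR)) / self.FR
        osc = 0.5 * (1 - np.cos(2 * np.pi * 0.05 * t))
        stack = np.ones((int(90 * self.FR),) + amps.shape)
        stack[int(10 * self.FR):] += amps * osc[:, None, None]
        return stack

    def test_power_ratio_of_amplitudes(self):
        """Parseval oracle: doubling the amplitude quadruples the power."""
        amps = np.zeros((4, 4))
        amps[0, 0], amps[2, 2] = 0.1, 0.2
        labels = np.zeros((4, 4), int)
        labels[0, 0], labels[2, 2] = 1, 2
        res = areal_response_strength(self._stack(amps), self.FR, labels)
        assert res.strengths[1] / res.strengths[0] == pytest.approx(4.0, rel=0.01)

    def test_silent_area_near_zero(self):
        amps = np.zeros((4, 4))
        amps[0, 0] = 0.2
        labels = np.ones((4, 4), int)
        labels[0, 0] = 2
        res = areal_response_strength(self._stack(amps), self.FR, labels)
        assert res.strengths[0] < 1e-12 * res.strengths[1]

    def test_gain_invariance(self):
        amps = np.zeros((3, 3))
        amps[1, 1] = 0.15
        labels = np.zeros((3, 3), int)
        labels[1, 1] = 1
        stack = self._stack(amps)
        r1 = areal_response_strength(stack, self.FR, labels)
        r2 = areal_response_strength(3.7 * stack, self.FR, labels)
        assert r1.strengths[0] == pytest.approx(r2.strengths[0], rel=1e-9)

    def test_missing_pre_segment_rejected(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            areal_response_strength(np.ones((10, 2, 2)), self.FR,
                                    np.ones((2, 2), int), pre_stim_s=10.0)


@pytest.fixture(scope="module")
def six_area_roundtrip():
    layout = default_six_area_layout()
    protocol = make_stimulus_protocol("retinotopy-bar")
    stacks, truth = synthesize_retinotopy_stack(layout, protocol, seed=0,
                                                delay_s=0.0)
    maps = {}
    mag = None
    for axis, st in stacks.items():
        pf, mf = fourier_component_map(st.forward, st.frame_rate, st.stim_freq_hz)
        pr, mr = fourier_component_map(st.reverse, st.frame_rate, st.stim_freq_hz)
        phase, _ = delay_corrected_retinotopy(pf, pr, weights=mf * mr)
        maps[axis] = phase_to_degrees(phase, st.extent_deg) + st.center_deg
        mag = mf * mr if mag is None else mag * mf * mr
    response_mask = mag > 0.05 * mag.max()
    return layout, truth, maps, response_mask


class TestRoundTrip:
    def test_retinotopy_recovered_noiselessly(self, six_area_roundtrip):
        _, truth, maps, _ = six_area_roundtrip
        for axis, gt in (("azimuth", truth.azimuth_deg),
                         ("elevation", truth.elevation_deg)):
            err = np.abs(maps[axis] - gt)[truth.mask]
            assert err.mean() < 2.0

    def test_sign_map_matches_mirror_polarity(self, six_area_roundtrip):
        _, truth, maps, response_mask = six_area_roundtrip
        sign = visual_field_sign(maps["azimuth"], maps["elevation"],
                                 response_mask=response_mask)
        for k, s in enumerate(truth.signs):
            area = truth.labels == k + 1
            interior = area & (np.abs(sign) > 0.9)
            assert np.sign(np.median(sign[interior])) == s

    def test_segmentation_recovers_all_areas(self, six_area_roundtrip):
        layout, truth, maps, response_mask = six_area_roundtrip
        sign = visual_field_sign(maps["azimuth"], maps["elevation"],
                                 response_mask=response_mask)
        sm = threshold_and_clean(sign)
        mask = neighbor_filter(sm.mask)
        seg = detect_borders(mask, sign=sm.sign)
        assert len(seg.area_mm2) == len(layout) == 6
        # match each recovered centroid to the nearest ground-truth centroid
        for c in seg.centroids_px:
            d = np.linalg.norm(truth.centroids_px - c, axis=1).min()
            assert d < 2.0
        # largest area (the reference) is V1
        ref_c = seg.centroids_px[np.argmax(seg.area_mm2)]
        assert np.linalg.norm(truth.centroids_px[0] - ref_c) < 2.0

    def test_delay_independence(self):
        """A 1-s hemodynamic delay leaves recovered maps unchanged (<1 deg)."""
        layout = default_six_area_layout()
        protocol = make_stimulus_protocol("retinotopy-bar")
        recovered = {}
        for delay in (0.0, 1.0):
            stacks, truth = synthesize_retinotopy_stack(layout, protocol, seed=0,
                                                        delay_s=delay)
            st = stacks["azimuth"]
            pf, mf = fourier_component_map(st.forward, st.frame_rate, st.stim_freq_hz)
            pr, mr = fourier_component_map(st.reverse, st.frame_rate, st.stim_freq_hz)
            phase, _ = delay_corrected_retinotopy(pf, pr, weights=mf * mr)
            recovered[delay] = phase_to_degrees(phase, st.extent_deg) + st.center_deg
        diff = np.abs(recovered[0.0] - recovered[1.0])[truth.mask]
        assert diff.max() < 1.0


class TestIsoiGratingStack:
    def test_spectral_peak_at_stimulus_frequency(self):
        layout = default_six_area_layout()
        protocol = make_stimulus_protocol("isoi-grating")
        stack, truth = synthesize_isoi_grating_stack(
            {"V1": 1.0}, layout, protocol, seed=0)
        pre = int(protocol.pre_s * protocol.frame_rate)
        v1_px = np.argwhere(truth.labels == 1)[0]
        sig = stack[pre:, v1_px[0], v1_px[1]]
        freqs = np.fft.rfftfreq(sig.size, d=1.0 / protocol.frame_rate)
        spec = np.abs(np.fft.rfft(sig - sig.mean()))
        assert freqs[np.argmax(spec)] == pytest.approx(0.05, abs=1e-3)

    def test_strength_ratio_recovered_linearly(self):
        layout = default_six_area_layout()
        protocol = make_stimulus_protocol("isoi-grating")
        stack, truth = synthesize_isoi_grating_stack(
            {"V1": 0.1, "RL": 0.2}, layout, protocol, seed=0)
        res = areal_response_strength(stack, protocol.frame_rate, truth.labels,
                                      pre_stim_s=protocol.pre_s)
        names = truth.names
        r = res.strengths[names.index("RL")] / res.strengths[names.index("V1")]
        assert r == pytest.approx(4.0, rel=0.02)  # power ratio of 2x amplitude
        for name in ("AM", "AL", "PM", "LM"):
            assert res.strengths[names.index(name)] < 1e-10

    def test_negative_strength_rejected(self):
        layout = default_six_area_layout()
        protocol = make_stimulus_protocol("isoi-grating")
        with pytest.raises(ValueError):
            synthesize_isoi_grating_stack({"V1": -1.0}, layout, protocol, seed=0)


class TestLayout:
    def test_overlapping_areas_rejected(self):
        from dsstream.simulate_imaging import AreaDef

        with pytest.raises(ValueError, match="overlap"):
            layout_ground_truth([
                AreaDef("a", (0, 10), (0, 10)),
                AreaDef("b", (5, 15), (5, 15)),
            ], (20, 20))

    def test_phase_encoding_is_affine_in_coordinate(self):
        """Generated phase is an affine function of the ground-truth
        coordinate with the configured delay offset."""
        layout = default_six_area_layout()
        protocol = make_stimulus_protocol("retinotopy-bar")
        stacks, truth = synthesize_retinotopy_stack(layout, protocol, seed=0,
                                                    delay_s=0.5)
        st = stacks["azimuth"]
        pf, _ = fourier_component_map(st.forward, st.frame_rate, st.stim_freq_hz)
        coord = truth.azimuth_deg[truth.mask]
        phase = pf[truth.mask]
        expected = wrap_phase(2 * np.pi * coord / st.extent_deg
                              - 2 * np.pi * st.stim_freq_hz * 0.5)
        assert np.allclose(wrap_phase(phase - expected), 0.0, atol=1e-6)
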