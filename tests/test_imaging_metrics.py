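"""Tuning analysis: dF/F, Z-scoring, detection, BF/threshold/Q20, d-prime."""

import numpy as np
import pytest

from synaptune.imaging import (
    TuningSurface,
    best_frequency,
    build_tuning_surface,
    compute_dff,
    detect_regions,
    detect_response,
    dprime,
    q20_bandwidth,
    quantify_tuning,
    response_threshold,
    select_top_fraction,
    widefield_map,
    zscore_trace,
)
from synaptune.imaging_sim import (
    ReceptiveFieldModel,
    simulate_roi_traces,
    simulate_widefield_movie,
)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        assert np.allclose(compute_dff(np.full(20, 100.0), 10, 5.0), 0.0)

    def test_ten_percent_rise(self):
        trace = np.full(20, 100.0)
        trace[10:] = 110.0
        assert compute_dff(trace, 10, 5.0)[12] == pytest.approx(0.10)

    def test_zero_baseline_flagged(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(np.zeros(20), 10, 5.0)

    def test_insufficient_pre_frames_rejected(self):
        with pytest.raises(ValueError, match="pre-onset"):
            compute_dff(np.ones(20), 2, 5.0)


class TestZscore:
    def test_output_standardized(self, rng):
        z = zscore_trace(rng.normal(5, 3, 500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_hand_computed_example(self):
        z = zscore_trace(np.array([0.0, 0.0, 0.0, 1.0]))
        np.testing.assert_allclose(z, [-0.5 / 0.8660254, -0.5 / 0.8660254,
                                       -0.5 / 0.8660254, 1.5 / 0.8660254],
                                   rtol=1e-6)
        # population sd of [0,0,0,1] is 0.4330
        np.testing.assert_allclose(z * 0.4330127, [-0.25, -0.25, -0.25, 0.75],
                                   rtol=1e-6)

    def test_constant_trace_flagged(self):
        with pytest.raises(ValueError, match="unscorable"):
            zscore_trace(np.full(10, 3.0))


class TestDetectResponse:
    def test_two_consecutive_frames_respond(self):
        z = np.array([0.0] * 5 + [0.7, 0.7, 0.0, 0.0, 0.0])
        responsive, peak = detect_response(z, 5, 5.0)
        assert responsive and peak == pytest.approx(0.7)

    def test_single_large_frame_not_enough(self):
        z = np.array([0.0] * 5 + [5.0, 0.0, 0.0, 0.0, 0.0])
        responsive, peak = detect_response(z, 5, 5.0)
        assert not responsive and np.isnan(peak)

    def test_all_subthreshold_not_responsive(self):
        z = np.full(10, 0.5)
        assert not detect_response(z, 5, 5.0)[0]

    def test_truncated_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_response(np.zeros(7), 5, 5.0)


@pytest.fixture(scope="module")
def analyzed(tone_block, clean_rf_model):
    trace, gt = simulate_roi_traces(clean_rf_model, tone_block, 5, seed=2)
    return build_tuning_surface(trace), gt


class TestNoiseFreePipeline:
    """Simulate -> analyze must reproduce the generator's ground truth."""

    def test_mask_recovered_exactly(self, analyzed):
        surface, gt = analyzed
        np.testing.assert_array_equal(surface.responsive, gt["mask"])

    def test_bf_threshold_q20_exact(self, analyzed):
        surface, gt = analyzed
        assert best_frequency(surface) == gt["bf_hz"]
        assert response_threshold(surface) == gt["threshold_db"]
        assert q20_bandwidth(surface) == gt["q20_oct"]

    def test_mask_recovered_at_any_subpeak_threshold(self, tone_block,
                                                     clean_rf_model):
        trace, gt = simulate_roi_traces(clean_rf_model, tone_block, 5, seed=2)
        for thresh in (0.3, 0.6, 1.0):
            surface = build_tuning_surface(trace, z_thresh=thresh)
            np.testing.assert_array_equal(surface.responsive, gt["mask"])

    def test_raising_threshold_never_grows_mask(self, tone_block):
        model = ReceptiveFieldModel()  # with noise
        trace, _ = simulate_roi_traces(model, tone_block, 5, seed=9)
        prev = None
        for thresh in (0.3, 0.6, 1.2, 2.4):
            mask = build_tuning_surface(trace, z_thresh=thresh).responsive
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_silent_neuron_empty_mask(self, tone_block):
        model = ReceptiveFieldModel(peak_dff=0.0, noise_sd=0.0,
                                    repeat_jitter_sd=0.0)
        trace, _ = simulate_roi_traces(model, tone_block, 5, seed=2)
        surface = build_tuning_surface(trace)
        assert not surface.responsive.any()
        assert best_frequency(surface) is None
        assert response_threshold(surface) is None


class TestSurfaceMetricsOnConstructedSurfaces:
    def _surface(self, responsive, peak_dff, freqs=None, levels=None):
        responsive = np.asarray(responsive, dtype=bool)
        peak = np.asarray(peak_dff, dtype=float)
        n_l, n_f = responsive.shape
        freqs = np.asarray(freqs if freqs is not None
                           else 5000.0 * 2 ** (np.arange(n_f) * 0.125))
        levels = np.asarray(levels if levels is not None
                            else 40.0 + 10.0 * np.arange(n_l))
        return TuningSurface(peak_z=peak.copy(), peak_dff=peak,
                             responsive=responsive, freqs_hz=freqs,
                             levels_db=levels, repeats_used=5)

    def test_bf_at_global_maximum(self):
        resp = np.zeros((5, 4), dtype=bool)
        peak = np.zeros((5, 4))
        resp[3, 2] = resp[1, 1] = True
        peak[3, 2], peak[1, 1] = 2.0, 1.0
        s = self._surface(resp, peak)
        assert best_frequency(s) == s.freqs_hz[2]

    def test_bf_tie_breaks_to_lower_frequency(self):
        resp = np.zeros((2, 4), dtype=bool)
        peak = np.zeros((2, 4))
        resp[0, 1] = resp[1, 3] = True
        peak[0, 1] = peak[1, 3] = 1.5
        s = self._surface(resp, peak)
        assert best_frequency(s) == s.freqs_hz[1]

    def test_threshold_is_lowest_responsive_level(self):
        resp = np.zeros((5, 4), dtype=bool)
        resp[2:, 1] = True  # responses at 60-80 dB only
        s = self._surface(resp, resp.astype(float))
        assert response_threshold(s) == 60.0

    def test_q20_spans(self):
        # responsive 10-20 kHz at threshold + 20 -> 1 octave
        freqs = np.array([5000.0, 10000.0, 20000.0, 40000.0])
        resp = np.zeros((5, 4), dtype=bool)
        resp[0, 1] = True              # threshold 40 dB
        resp[2, 1] = resp[2, 2] = True  # 60 dB row: 10 and 20 kHz
        s = self._surface(resp, resp.astype(float), freqs=freqs)
        assert q20_bandwidth(s) == pytest.approx(1.0)

    def test_q20_single_frequency_zero(self):
        resp = np.zeros((5, 4), dtype=bool)
        resp[0, 1] = resp[2, 1] = True
        s = self._surface(resp, resp.astype(float))
        assert q20_bandwidth(s) == 0.0

    def test_q20_undefined_when_level_not_tested(self):
        resp = np.zeros((5, 4), dtype=bool)
        resp[4, 1] = True  # threshold 80 dB; 100 dB untested
        s = self._surface(resp, resp.astype(float))
        assert q20_bandwidth(s) is None


class TestDprimeAndSelection:
    def test_identical_distributions_give_zero(self):
        s = TuningSurface(
            peak_z=np.ones((1, 1)), peak_dff=np.ones((1, 1)),
            responsive=np.ones((1, 1), dtype=bool),
            freqs_hz=np.array([1e4]), levels_db=np.array([60.0]),
            repeats_used=4,
            evoked_peaks=np.array([[[1.0, 2.0, 3.0, 4.0]]]),
            baseline_peaks=np.array([[[1.0, 2.0, 3.0, 4.0]]]),
        )
        assert dprime(s) == pytest.approx(0.0)

    def test_one_pooled_sd_shift_gives_unity(self):
        ev = np.array([1.0, 2.0, 3.0, 4.0])
        sd = ev.std(ddof=1)
        s = TuningSurface(
            peak_z=np.ones((1, 1)), peak_dff=np.ones((1, 1)),
            responsive=np.ones((1, 1), dtype=bool),
            freqs_hz=np.array([1e4]), levels_db=np.array([60.0]),
            repeats_used=4,
            evoked_peaks=(ev + sd)[None, None],
            baseline_peaks=ev[None, None],
        )
        assert dprime(s) == pytest.approx(1.0)

    def test_dprime_matches_brute_force_recomputation(self, tone_block):
        """Independent oracle: recompute d' from the raw trace directly."""
        model = ReceptiveFieldModel()
        trace, _ = simulate_roi_traces(model, tone_block, 5, seed=21)
        surface = build_tuning_surface(trace)
        d = dprime(surface)
        # brute force: per-repeat dF/F around the best stimulus
        vals = np.where(surface.responsive, surface.peak_dff, -np.inf)
        lv, fv = np.unravel_index(np.argmax(vals), vals.shape)
        stim = lv * trace.freqs_hz.size + fv
        ev, ba = [], []
        for r in range(trace.n_repeats):
            onset = trace.alignment[r, stim]
            seg = trace.values[r, onset - 5: onset + 5]
            f0 = seg[:5].mean()
            dff = seg / f0 - 1.0
            ev.append(dff[5:10].max())
            ba.append(dff[:5].max())
        ev, ba = np.array(ev), np.array(ba)
        expect = (ev.mean() - ba.mean()) / np.sqrt(
            (ev.var(ddof=1) + ba.var(ddof=1)) / 2)
        assert d == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("n, kept", [(10, 2), (100, 20), (3, 1), (1, 1)])
    def test_top_fraction_counts(self, n, kept, rng):
        idx = select_top_fraction(rng.normal(size=n), 0.20)
        assert idx.size == kept

    def test_top_fraction_keeps_largest(self):
        d = np.array([0.1, 3.0, 0.2, 2.0, 1.0])
        assert set(select_top_fraction(d, 0.4)) == {1, 3}

    def test_empty_input_empty_output(self):
        assert select_top_fraction(np.array([]), 0.2).size == 0


class TestWidefieldMap:
    def test_two_blob_map_recovers_centers_within_1px(self):
        specs = [{"center": (60, 50), "radius_px": 8, "amplitude": 0.15},
                 {"center": (80, 140), "radius_px": 8, "amplitude": 0.10}]
        movie = simulate_widefield_movie(specs, [2.0, 6.0], seed=0,
                                         noise_sd=0.3)
        rmap = widefield_map(movie)
        regions = detect_regions(rmap, z_thresh=2.0, min_area_px=10)
        assert len(regions) == 2
        found = sorted(r.centroid for r in regions)
        for (fr, fc), (tr, tc) in zip(found, sorted(s["center"]
                                                    for s in specs)):
            assert abs(fr - tr) <= 1.0 and abs(fc - tc) <= 1.0

    def test_stimulus_free_movie_has_no_regions(self):
        movie = simulate_widefield_movie(
            [{"center": (75, 100), "radius_px": 8, "amplitude": 0.0}],
            [2.0], seed=0, noise_sd=0.3)
        rmap = widefield_map(movie)
        assert detect_regions(rmap, z_thresh=4.0, min_area_px=10) == []

    def test_min_area_filters_small_blobs(self):
        movie = simulate_widefield_movie(
            [{"center": (75, 100), "radius_px": 3, "amplitude": 0.2}],
            [2.0], seed=0, noise_sd=0.0)
        rmap = widefield_map(movie)
        assert detect_regions(rmap, min_area_px=10_000) == []

    def test_too_short_movie_rejected(self):
        movie = simulate_widefield_movie(
            [{"center": (75, 100), "radius_px": 8, "amplitude": 0.1}],
            [2.0], seed=0, tail_s=0.2)
        with pytest.raises(ValueError, match="frames"):
            widefield_map(movie)


def test_quantify_tuning_flags(tone_block):
    # single responsive (frequency, level) combination, fully deterministic
    model = ReceptiveFieldModel(noise_sd=0.0, repeat_jitter_sd=0.0,
                                threshold_db=80.0, bw_at_threshold_oct=0.0,
                                widen_oct_per_10db=0.0)
    trace, gt = simulate_roi_traces(model, tone_block, 5, seed=2)
    surface = build_tuning_surface(trace)
    assert surface.responsive.sum() == 1
    tm = quantify_tuning(surface)
    assert tm.is_sound_responsive
    assert tm.bf_hz == gt["bf_hz"]
    assert tm.q20_oct is None and "q20_undefined" in tm.flags
    # identical repeats -> zero pooled variance -> d' undefined, flagged
    assert tm.dprime is None and "dprime_undefined" in tm.flags
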