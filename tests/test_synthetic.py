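"""Planted-truth generators: determinism, composition, trace construction."""

import numpy as np
import pytest

from seek2p import synth
from seek2p.behavior import summarize_session
from seek2p.imaging import extract_traces


def spec_small(**kw):
    base = dict(n_excited=3, n_nonresponding=4, n_inhibited=3, noise_sd=0.0,
                tonic_decline_frac=0.0, amp_jitter_cv=0.0)
    base.update(kw)
    return synth.EnsembleSpec(**base)


class TestEvents:
    def test_zero_rates_give_empty_log(self):
        cfg = synth.SessionConfig(press_rate_active=0, press_rate_inactive=0, duration_s=3600)
        assert len(synth.generate_events(cfg).events) == 0

    def test_deterministic_given_seed(self):
        cfg = synth.SessionConfig(seed=7)
        a, b = synth.generate_events(cfg), synth.generate_events(cfg)
        assert a.events.equals(b.events)

    def test_reward_cap_respected(self):
        cfg = synth.SessionConfig(press_rate_active=1.0, duration_s=3600, reward_cap=10, seed=3)
        assert summarize_session(synth.generate_events(cfg)).rewards_delivered <= 10

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            synth.SessionConfig(duration_s=0)

    def test_press_trials_fixed_count_and_separation(self):
        log = synth.generate_press_trials(40, duration_s=3600, min_sep_s=25, seed=5)
        t = log.active_press_times
        assert t.size == 40
        assert np.diff(t).min() >= 25
        assert t.min() >= 25 and t.max() <= 3600 - 25


class TestTraces:
    def test_noiseless_inhibited_dip_equals_amp(self):
        log = synth.generate_press_trials(1, duration_s=120, min_sep_s=30, seed=0)
        spec = spec_small(amp_inhibited=-0.5)
        traces, truth = synth.generate_traces(log, spec, frame_rate_hz=10, seed=0)
        inh = traces.data[truth.labels == "inhibited"]
        non = traces.data[truth.labels == "non_responding"]
        assert inh.min() == pytest.approx(1.0 - 0.5, abs=1e-9)
        assert np.allclose(non, 1.0)

    def test_planted_tonic_slope(self):
        cfg = synth.SessionConfig(press_rate_active=0, press_rate_inactive=0)
        log = synth.generate_events(cfg)
        spec = spec_small(tonic_decline_frac=0.3)
        traces, _ = synth.generate_traces(log, spec, frame_rate_hz=5, seed=0)
        ratio = traces.data[:, -1] / traces.data[:, 0]
        assert np.allclose(ratio, 0.7, atol=1e-12)

    def test_full_drug_attenuation_flattens_responders(self):
        log = synth.generate_press_trials(3, duration_s=300, min_sep_s=30, seed=1)
        spec = spec_small(drug_attenuation=1.0)
        traces, _ = synth.generate_traces(log, spec, frame_rate_hz=10, seed=0)
        assert np.allclose(traces.data, 1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            spec_small(noise_sd=-0.1)

    def test_shape_and_label_conservation(self):
        log = synth.generate_press_trials(2, duration_s=300, min_sep_s=30, seed=2)
        spec = spec_small()
        traces, truth = synth.generate_traces(log, spec, frame_rate_hz=10, seed=0)
        assert traces.data.shape == (10, int(np.floor(300 * 10)))
        assert truth.labels.size == spec.n_neurons
        counts = {c: int((truth.labels == c).sum()) for c in np.unique(truth.labels)}
        assert counts == {"excited": 3, "non_responding": 4, "inhibited": 3}

    def test_default_composition_scales_to_reference(self):
        assert synth.default_ensemble_counts(305) == (79, 153, 73)
        n = synth.default_ensemble_counts(100)
        assert sum(n) == 100 and n[1] > n[0] > 0 and n[2] > 0


class TestMovie:
    def test_uniform_disk_round_trip(self):
        log = synth.generate_press_trials(1, duration_s=60, min_sep_s=25, seed=0)
        traces, truth = synth.generate_traces(
            log, spec_small(), frame_rate_hz=5, seed=0
        )
        movie, rois = synth.generate_movie(traces, truth, frame_size_px=(64, 64), roi_radius_px=3)
        back = extract_traces(movie, rois)
        assert np.allclose(back.data, traces.data, atol=1e-9)

    def test_empty_population_gives_background_movie(self):
        from seek2p.imaging import TraceMatrix

        traces = TraceMatrix(np.zeros((0, 5)), frame_rate_hz=5)
        truth = synth.GroundTruth(
            labels=np.array([], dtype=object), tonic_slopes=np.array([]), event_times=np.array([])
        )
        movie, rois = synth.generate_movie(traces, truth, frame_size_px=(32, 32), background=2.0)
        assert np.allclose(movie.frames, 2.0)
        assert rois.n_rois == 0

    def test_overcrowded_layout_rejected(self):
        from seek2p.imaging import TraceMatrix

        traces = TraceMatrix(np.ones((500, 2)), frame_rate_hz=5)
        truth = synth.GroundTruth(
            labels=np.array(["non_responding"] * 500, dtype=object),
            tonic_slopes=np.zeros(500),
            event_times=np.array([]),
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            synth.generate_movie(traces, truth, frame_size_px=(32, 32), roi_radius_px=3)


class TestTrackedPair:
    def test_shared_cells_attenuated_in_session_b(self):
        spec_a = spec_small(n_excited=5, n_nonresponding=5, n_inhibited=5)
        spec_b = spec_small(n_excited=5, n_nonresponding=5, n_inhibited=5, drug_attenuation=0.8)
        # sparse pressing keeps planted transients from overlapping, so the
        # per-neuron peak deviation equals the planted amplitude exactly
        cfg = synth.SessionConfig(duration_s=600, press_rate_active=0.2, seed=0)
        (ev_a, tr_a, tu_a), (ev_b, tr_b, tu_b) = synth.generate_tracked_pair(
            spec_a, spec_b, overlap_n=6, seed=4, session_cfg=cfg, frame_rate_hz=10
        )
        # labels preserved through the identity map
        for ia, ib in tu_b.identity_map:
            assert tu_a.labels[ia] == tu_b.labels[ib]
        # session B responders deflect 80% less
        amp_a = np.abs(tr_a.data - 1).max()
        resp_b = [ib for ia, ib in tu_b.identity_map if tu_a.labels[ia] != "non_responding"]
        amp_b = np.abs(tr_b.data[resp_b] - 1).max()
        assert amp_b == pytest.approx(0.2 * amp_a, rel=0.05)

    def test_zero_overlap_and_zero_jitter(self):
        spec = spec_small()
        a, b = synth.generate_tracked_pair(spec, spec, overlap_n=0, seed=1)
        assert b[2].identity_map.shape == (0, 2)
        a2, b2 = synth.generate_tracked_pair(spec, spec, overlap_n=4, seed=1, centroid_jitter_px=0.0)
        for ia, ib in b2[2].identity_map:
            assert np.allclose(a2[2].roi_centroids[ia], b2[2].roi_centroids[ib])

    def test_excess_overlap_rejected(self):
        spec = spec_small()
        with pytest.raises(ValueError, match="overlap"):
            synth.generate_tracked_pair(spec, spec, overlap_n=99, seed=0)


class TestIVAndWash:
    def test_ohmic_currents(self):
        spec = synth.IVCurveSpec(conductance_nS=1.0, reversal_mV=0.0)
        curve = synth.generate_iv_curve(spec)
        assert curve.current_at(50) == pytest.approx(50.0)
        assert curve.current_at(-70) == pytest.approx(-70.0)

    def test_rectifying_positive_limb_scaled(self):
        spec = synth.IVCurveSpec(rectification_mode="inward_rectifying", positive_limb_scale=0.1)
        curve = synth.generate_iv_curve(spec)
        assert curve.current_at(50) == pytest.approx(5.0)
        assert curve.current_at(-70) == pytest.approx(-70.0)

    def test_seeded_noise_deterministic(self):
        spec = synth.IVCurveSpec(noise_sd_pA=2.0)
        c1 = synth.generate_iv_curve(spec, seed=9)
        c2 = synth.generate_iv_curve(spec, seed=9)
        assert np.array_equal(c1.currents_pA, c2.currents_pA)

    def test_empty_voltages_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_iv_curve(synth.IVCurveSpec(), voltages_mV=[])

    def test_wash_series_plateaus_at_post_fraction(self):
        series = synth.generate_wash_series(pre_amp_pA=100, post_frac=0.3, tau_s=60,
                                            duration_s=1500, drug_on_s=300)
        assert series.amplitude_pA[series.time_s < 300].max() == pytest.approx(100.0)
        assert series.amplitude_pA[-1] == pytest.approx(30.0, rel=0.01)
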