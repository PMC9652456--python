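"""Peri-event tensor alignment, scree knee, clustering, tonic bins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from seek2p import synth
from seek2p.behavior import ScheduleConfig, apply_schedule
from seek2p.ensembles import (
    build_peri_event_tensor,
    categorize_clusters,
    cluster_ensembles,
    pca_scores,
    select_n_components,
    tonic_bins,
)
from seek2p.imaging import TraceMatrix


def make_events(times, duration_s):
    return apply_schedule(times, [], ScheduleConfig(reward_cap=None), duration_s)


class TestPeriEventTensor:
    def test_30hz_window_is_690_timepoints(self):
        traces = TraceMatrix(np.random.default_rng(0).normal(size=(3, 30 * 60)), 30.0)
        tensor = build_peri_event_tensor(traces, make_events([30.0], 60.0))
        assert tensor.n_timepoints == 690
        assert tensor.press_index == 300

    def test_incomplete_window_excluded_and_counted(self):
        traces = TraceMatrix(np.random.default_rng(0).normal(size=(2, 600)), 10.0)
        tensor = build_peri_event_tensor(traces, make_events([5.0, 30.0], 60.0))
        assert tensor.n_trials == 1
        assert tensor.n_excluded == 1

    def test_no_usable_events_is_error(self):
        traces = TraceMatrix(np.zeros((2, 100)), 10.0)
        with pytest.raises(ValueError, match="window"):
            build_peri_event_tensor(traces, make_events([1.0], 10.0))

    def test_noiseless_inhibited_negative_after_press(self):
        log = synth.generate_press_trials(5, duration_s=600, min_sep_s=30, seed=0)
        spec = synth.EnsembleSpec(
            n_excited=2, n_nonresponding=2, n_inhibited=2, noise_sd=0.0,
            amp_jitter_cv=0.0, tonic_decline_frac=0.0,
        )
        traces, truth = synth.generate_traces(log, spec, frame_rate_hz=10, seed=0)
        tensor = build_peri_event_tensor(traces, log)
        resp = tensor.trial_average()[:, tensor.response_slice()].mean(axis=1)
        assert np.all(resp[truth.labels == "inhibited"] < 0)
        assert np.all(resp[truth.labels == "excited"] > 0)
        assert np.allclose(resp[truth.labels == "non_responding"], 0.0)

    @given(press_frame=st.integers(min_value=120, max_value=400))
    @settings(max_examples=20, deadline=None)
    def test_delta_function_lands_at_expected_index(self, press_frame):
        """A unit spike at a known frame appears at the aligned index."""
        fs = 10.0
        data = np.zeros((1, 600))
        spike_frame = press_frame + 7
        data[0, spike_frame] = 1.0
        traces = TraceMatrix(data, fs)
        tensor = build_peri_event_tensor(traces, make_events([press_frame / fs], 60.0))
        expected_idx = spike_frame - (press_frame - tensor.press_index)
        assert np.argmax(tensor.values[0, 0]) == expected_idx


class TestScreeKnee:
    def test_frozen_curve_knee_at_two(self):
        # enumerate second differences of [0.5,.3,.1,.05,.03] by hand:
        # diff2 = [0.0, 0.15, 0.03] -> maximal at the bend after component 2
        rng = np.random.default_rng(0)
        target = np.array([0.5, 0.3, 0.1, 0.05, 0.03])
        # build data whose PCA spectrum matches the target ratios exactly:
        # centered orthonormal scores scaled by sqrt(target variances)
        basis, _ = np.linalg.qr(rng.normal(size=(40, 5)))
        A = rng.normal(size=(200, 5))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = (Q * np.sqrt(target)) @ basis.T
        n, evr = select_n_components(X)
        assert np.allclose(evr[:5], target / target.sum(), atol=1e-9)
        assert n == 2

    def test_rank_bound_noiseless_3d(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(50, 3)) * [3.0, 2.0, 1.0]
        X = latent @ rng.normal(size=(3, 30))
        n, evr = select_n_components(X)
        assert n <= 3
        assert evr[3:].max() < 1e-9

    def test_isotropic_noise_falls_back_to_two(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="no clear"):
            n, _ = select_n_components(rng.normal(size=(100, 50)))
        assert n == 2

    def test_rank1_degenerate(self):
        X = np.outer(np.arange(10.0), np.ones(6))
        with pytest.warns(UserWarning, match="rank-1"):
            n, _ = select_n_components(X)
        assert n == 1

    def test_pca_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 12))
        pca = PCA().fit(X)
        assert np.allclose(pca.inverse_transform(pca.transform(X)), X, atol=1e-9)


class TestClustering:
    @staticmethod
    def _blobs(seed=0, n_per=20, sep=8.0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [sep, 0], [0, sep]])
        X = np.vstack([c + rng.normal(size=(n_per, 2)) for c in centers])
        labels = np.repeat([0, 1, 2], n_per)
        return X, labels

    def test_separated_blobs_ari_one(self):
        X, truth = self._blobs()
        got = cluster_ensembles(X, k=3, seed=0)
        assert adjusted_rand_score(truth, got.cluster_ids) == 1.0

    def test_k_one_rejected(self):
        X, _ = self._blobs()
        with pytest.raises(ValueError, match="k must be"):
            cluster_ensembles(X, k=1)

    def test_knn_must_be_smaller_than_population(self):
        X, _ = self._blobs(n_per=4)
        with pytest.raises(ValueError, match="knn"):
            cluster_ensembles(X, k=2, knn=12)

    def test_disconnected_graph_advises_larger_knn(self):
        X = np.vstack(
            [np.random.default_rng(0).normal(size=(10, 2)) + off
             for off in ([0, 0], [100, 0], [0, 100], [100, 100])]
        )
        with pytest.raises(ValueError, match="increase knn"):
            cluster_ensembles(X, k=2, knn=3, seed=0)

    def test_permutation_stability_up_to_relabel(self):
        X, _ = self._blobs(seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(X.shape[0])
        a = cluster_ensembles(X, k=3, seed=0).cluster_ids
        b = cluster_ensembles(X[perm], k=3, seed=0).cluster_ids
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_eigengap_auto_k_on_blobs(self):
        X, truth = self._blobs(sep=12.0)
        got = cluster_ensembles(X, k="auto", seed=0)
        assert got.k == 3

    def test_ari_degrades_with_noise_on_average(self):
        """Recovery degrades (on average) as trace noise grows."""
        from seek2p import pipeline

        aris = {}
        for noise in (0.2, 2.0):
            vals = [
                pipeline.ensemble_recovery(
                    seed=s, n_neurons=60, n_trials=15, frame_rate_hz=10,
                    duration_s=1200, noise_sd=noise,
                )["ari"]
                for s in range(3)
            ]
            aris[noise] = np.mean(vals)
        assert aris[2.0] < aris[0.2]


class TestCategorize:
    def _session_assignment(self, **spec_kw):
        spec = synth.EnsembleSpec(
            n_excited=4, n_nonresponding=4, n_inhibited=4, noise_sd=0.02,
            amp_jitter_cv=0.0, tonic_decline_frac=0.0, **spec_kw,
        )
        log = synth.generate_press_trials(8, duration_s=600, min_sep_s=30, seed=2)
        traces, truth = synth.generate_traces(log, spec, frame_rate_hz=10, seed=2)
        tensor = build_peri_event_tensor(traces, log)
        scores = pca_scores(tensor.trial_average(), 2)
        assignment = cluster_ensembles(scores, k=3, knn=4, seed=0)
        return tensor, assignment, truth

    def test_planted_categories_recovered(self):
        tensor, assignment, truth = self._session_assignment()
        categorize_clusters(assignment, tensor)
        assert np.array_equal(assignment.categories, truth.labels)

    def test_infinite_threshold_means_all_nonresponding(self):
        tensor, assignment, _ = self._session_assignment()
        categorize_clusters(assignment, tensor, theta=np.inf)
        assert set(assignment.categories) == {"non_responding"}

    def test_flat_cluster_nonresponding(self):
        traces = TraceMatrix(np.ones((6, 600)), 10.0)
        tensor = build_peri_event_tensor(traces, make_events([30.0], 60.0))
        scores = np.random.default_rng(0).normal(size=(6, 2))
        assignment = cluster_ensembles(scores, k=2, knn=2, seed=0)
        cats = categorize_clusters(assignment, tensor)
        assert set(cats.values()) == {"non_responding"}


class TestTonicBins:
    def test_constant_traces_all_ones(self):
        traces = TraceMatrix(np.full((3, 3600), 5.0), 1.0)
        binned = tonic_bins(traces, bin_s=180)
        assert np.allclose(binned.bin_means, 1.0)

    def test_planted_decline_last_over_first(self):
        cfg = synth.SessionConfig(press_rate_active=0, press_rate_inactive=0)
        log = synth.generate_events(cfg)
        spec = synth.EnsembleSpec(
            n_excited=0, n_nonresponding=5, n_inhibited=0,
            tonic_decline_frac=0.3, noise_sd=0.0,
        )
        traces, _ = synth.generate_traces(log, spec, frame_rate_hz=5, seed=0)
        binned = tonic_bins(traces)
        pairs = binned.first_last_pairs()
        # bin means sample the ramp at bin centers, so the ratio sits a hair
        # above the frame-level 0.70 (first-bin mean < 1, last-bin mean > 0.70)
        assert np.allclose(pairs[:, 1] / pairs[:, 0], 0.7, atol=0.02)

    def test_45min_session_gives_15_bins(self):
        traces = TraceMatrix(np.ones((2, 45 * 60 * 2)), 2.0)
        assert tonic_bins(traces, bin_s=180).n_bins == 15

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="2 bins"):
            tonic_bins(TraceMatrix(np.ones((2, 100)), 1.0), bin_s=180)

    def test_population_baseline_mode(self):
        data = np.vstack([np.full(720, 2.0), np.full(720, 4.0)])
        binned = tonic_bins(TraceMatrix(data, 1.0), bin_s=180, normalize="population_baseline")
        assert np.allclose(binned.bin_means[0], 2.0 / 3.0)
        assert np.allclose(binned.bin_means[1], 4.0 / 3.0)
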