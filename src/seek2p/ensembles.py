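"""Peri-event ensemble analysis.

Aligns fluorescence traces to active lever presses over a 23-s window (10 s
pre, 3 s press-to-reward, 10 s post), z-scores against a -10..-5 s pre-press
baseline, selects principal components at the scree knee, clusters neurons
with nearest-neighbor spectral clustering, labels the resulting clusters as
excited / non-responding / inhibited, and quantifies the within-session
tonic fluorescence trajectory in 3-min bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .behavior import EventLog
from .imaging import TraceMatrix

__all__ = [
    "PeriEventTensor",
    "EnsembleAssignment",
    "BinnedFluorescence",
    "build_peri_event_tensor",
    "select_n_components",
    "pca_scores",
    "cluster_ensembles",
    "categorize_clusters",
    "tonic_bins",
]

CATEGORIES = ("excited", "non_responding", "inhibited")


@dataclass
class PeriEventTensor:
    """Trial-aligned, baseline z-scored activity: neurons x trials x time.

    Time point 0 corresponds to -pre_s relative to the press; the press
    lands at index round(pre_s * frame_rate_hz).
    """

    values: np.ndarray
    pre_s: float
    mid_s: float
    post_s: float
    frame_rate_hz: float
    event_times: np.ndarray
    n_excluded: int = 0

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def press_index(self) -> int:
        return int(round(self.pre_s * self.frame_rate_hz))

    def response_slice(self) -> slice:
        """The press-to-reward segment (0..mid_s after the press)."""
        return slice(
            self.press_index, self.press_index + int(round(self.mid_s * self.frame_rate_hz))
        )

    def trial_average(self) -> np.ndarray:
        """Neuron x timepoint mean across trials."""
        return self.values.mean(axis=1)


def build_peri_event_tensor(
    traces: TraceMatrix,
    events: EventLog,
    pre_s: float = 10.0,
    mid_s: float = 3.0,
    post_s: float = 10.0,
    baseline_span_s: tuple[float, float] = (-10.0, -5.0),
) -> PeriEventTensor:
    """Align traces to active presses and z-score to the pre-press baseline.

    Each trial's own baseline mean (over ``baseline_span_s`` relative to the
    press) is subtracted, removing slow tonic drift; the divisor is the
    per-neuron standard deviation of the baseline segment pooled over trials
    (1.0 when that deviation is zero, as in noiseless fixtures). Trials
    whose window would run past either session edge are excluded and counted.
    """
    fs = traces.frame_rate_hz
    n_t = int(round((pre_s + mid_s + post_s) * fs))
    pre_frames = int(round(pre_s * fs))
    presses = events.active_press_times

    windows, used_times = [], []
    n_excluded = 0
    for t in presses:
        start = int(round(t * fs)) - pre_frames
        if start < 0 or start + n_t > traces.n_frames:
            n_excluded += 1
            continue
        windows.append(traces.data[:, start : start + n_t])
        used_times.append(t)
    if not windows:
        raise ValueError("no active press supports a complete peri-event window")
    raw = np.stack(windows, axis=1)  # neurons x trials x time

    b0 = int(round((pre_s + baseline_span_s[0]) * fs))
    b1 = int(round((pre_s + baseline_span_s[1]) * fs))
    base = raw[:, :, b0:b1]
    centered = raw - base.mean(axis=2, keepdims=True)
    sd = centered[:, :, b0:b1].std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return PeriEventTensor(
        values=centered / sd,
        pre_s=pre_s,
        mid_s=mid_s,
        post_s=post_s,
        frame_rate_hz=fs,
        event_times=np.asarray(used_times),
        n_excluded=n_excluded,
    )


def select_n_components(trial_avg_matrix: np.ndarray) -> tuple[int, np.ndarray]:
    """Pick the principal-component count at the scree-plot knee.

    PCA runs on the neuron x timepoint trial-averaged matrix with neurons as
    observations. The knee is the component index at the maximal discrete
    second difference of the explained-variance-ratio curve; a minimum of 2
    components is enforced except for rank-1 input, which returns 1 with a
    warning.
    """
    X = np.asarray(trial_avg_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 neurons for component selection")
    evr = PCA().fit(X).explained_variance_ratio_
    if evr.size < 2 or evr[1] < 1e-12:
        warnings.warn("degenerate (rank-1) input; using 1 component", stacklevel=2)
        return 1, evr
    if evr.size < 3:
        return 2, evr
    d2 = np.diff(evr, 2)
    if d2.max() < 0.01:  # flat curve: no bend stands out
        warnings.warn("no clear scree knee; falling back to 2 components", stacklevel=2)
        return 2, evr
    knee = int(np.argmax(d2)) + 1  # component index (1-based) at the bend
    return max(2, min(knee, evr.size)), evr


def pca_scores(trial_avg_matrix: np.ndarray, n_components: int) -> np.ndarray:
    """Neuron x component PCA score matrix for the clustering subspace."""
    return PCA(n_components=n_components).fit_transform(np.asarray(trial_avg_matrix))


@dataclass
class EnsembleAssignment:
    """Spectral-clustering result over the component-score subspace."""

    cluster_ids: np.ndarray  # per neuron, 1..k
    component_scores: np.ndarray
    n_components: int
    explained_variance: np.ndarray
    k: int
    categories: np.ndarray | None = None  # per neuron, set by categorize_clusters
    cluster_categories: dict[int, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "neuron_id": np.arange(self.cluster_ids.size),
                "cluster": self.cluster_ids,
                "category": self.categories
                if self.categories is not None
                else ["unassigned"] * self.cluster_ids.size,
            }
        )
        for j in range(self.component_scores.shape[1]):
            df[f"score_{j + 1}"] = self.component_scores[:, j]
        return df


def _eigengap_k(scores: np.ndarray, knn: int, max_k: int = 6) -> int:
    """Largest gap among the leading normalized-Laplacian eigenvalues."""
    A = kneighbors_graph(scores, n_neighbors=knn, include_self=False)
    A = 0.5 * (A + A.T)
    A = A.toarray()
    d = A.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    L = np.eye(A.shape[0]) - dinv[:, None] * A * dinv[None, :]
    w = np.sort(np.linalg.eigvalsh(L))[: max_k + 1]
    gaps = np.diff(w[: max_k + 1])
    return max(2, int(np.argmax(gaps[1:])) + 2)


def cluster_ensembles(
    component_scores: np.ndarray,
    k: int | str = 3,
    knn: int | None = None,
    seed: int = 0,
) -> EnsembleAssignment:
    """Spectral clustering on a symmetric k-NN connectivity graph.

    The default k = 3 mirrors the excited / non-responding / inhibited
    partition; ``k="auto"`` applies the eigengap heuristic over the first 6
    Laplacian eigenvalues. knn defaults to round(sqrt(n_neurons)). The
    embedded k-means runs 10 seeded restarts, so results are deterministic
    given (scores, seed).
    """
    X = np.asarray(component_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if knn is None:
        knn = max(2, int(round(np.sqrt(n))))
    if knn >= n:
        raise ValueError("knn must be smaller than the number of neurons")
    if k == "auto":
        k = _eigengap_k(X, knn)
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValueError("k must be an integer >= 2 (or 'auto')")

    graph = kneighbors_graph(X, n_neighbors=knn, include_self=False)
    graph = 0.5 * (graph + graph.T)
    n_comp, _ = connected_components(graph > 0, directed=False)
    if n_comp > k:
        raise ValueError(
            f"k-NN graph splits into {n_comp} components for k={k}; increase knn"
        )

    model = SpectralClustering(
        n_clusters=int(k),
        affinity="nearest_neighbors",
        n_neighbors=knn,
        assign_labels="kmeans",
        n_init=10,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not fully connected.*")
        labels = model.fit_predict(X)
    return EnsembleAssignment(
        cluster_ids=labels + 1,
        component_scores=X,
        n_components=X.shape[1],
        explained_variance=np.array([]),
        k=int(k),
    )


def categorize_clusters(
    assignment: EnsembleAssignment,
    tensor: PeriEventTensor,
    theta: float = 0.5,
) -> dict[int, str]:
    """Name each cluster by its mean response z-score after the press.

    The statistic is the trial-averaged z-score over the press-to-reward
    segment (0..mid_s), averaged over the cluster's neurons: above +theta is
    excited, below -theta inhibited, otherwise non-responding. Categories
    come from the data alone, never from planted truth.
    """
    resp = tensor.trial_average()[:, tensor.response_slice()].mean(axis=1)
    cluster_cats: dict[int, str] = {}
    for c in np.unique(assignment.cluster_ids):
        m = float(resp[assignment.cluster_ids == c].mean())
        if m > theta:
            cluster_cats[int(c)] = "excited"
        elif m < -theta:
            cluster_cats[int(c)] = "inhibited"
        else:
            cluster_cats[int(c)] = "non_responding"
    assignment.cluster_categories = cluster_cats
    assignment.categories = np.array(
        [cluster_cats[int(c)] for c in assignment.cluster_ids], dtype=object
    )
    return cluster_cats


@dataclass
class BinnedFluorescence:
    """Neuron x bin mean fluorescence with its normalization mode."""

    bin_means: np.ndarray
    bin_s: float
    normalization: str

    @property
    def n_bins(self) -> int:
        return self.bin_means.shape[1]

    def first_last_pairs(self) -> np.ndarray:
        return self.bin_means[:, [0, -1]]

    def population_mean(self) -> np.ndarray:
        return self.bin_means.mean(axis=0)


def tonic_bins(
    traces: TraceMatrix,
    bin_s: float = 180.0,
    normalize: str = "first_bin_per_neuron",
) -> BinnedFluorescence:
    """Within-session tonic fluorescence in 3-min bins.

    Bin means are normalized either per neuron to that neuron's first bin
    (``first_bin_per_neuron``) or to the first-bin mean averaged across
    neurons (``population_baseline``); sessions of variable length are
    compared via the first and last bin. Raises if the session is shorter
    than two bins.
    """
    frames_per_bin = int(round(bin_s * traces.frame_rate_hz))
    n_bins = traces.n_frames // frames_per_bin
    if n_bins < 2:
        raise ValueError("session shorter than 2 bins")
    trimmed = traces.data[:, : n_bins * frames_per_bin]
    means = trimmed.reshape(traces.n_neurons, n_bins, frames_per_bin).mean(axis=2)
    if normalize == "first_bin_per_neuron":
        f0 = means[:, :1]
        if np.any(f0 <= 0):
            raise ValueError("non-positive first-bin fluorescence")
        means = means / f0
    elif normalize == "population_baseline":
        f0 = means[:, 0].mean()
        if f0 <= 0:
            raise ValueError("non-positive population baseline")
        means = means / f0
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return BinnedFluorescence(bin_means=means, bin_s=bin_s, normalization=normalize)
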