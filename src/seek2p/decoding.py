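"""Binary decoding of upcoming lever presses with a shuffle null.

Features are 1-s mean-fluorescence epochs: one immediately before each
active press, and an equal number of random baseline epochs kept clear of a
[-10 s, +13 s] exclusion zone around every press (the modeled peri-event
window). A linear-discriminant classifier under stratified cross-validation
yields per-neuron and population accuracies; label-permutation shuffles give
the null, and reported scores are shuffle-subtracted within a grouping
(typically the neuron's ensemble).

The per-neuron path is a closed-form one-dimensional Gaussian LDA
(shared-variance threshold rule) vectorized across neurons and shuffles; it
is numerically equivalent to fitting sklearn's LinearDiscriminantAnalysis
to each single-feature column, which a test verifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .behavior import EventLog
from .imaging import TraceMatrix

__all__ = [
    "EpochFeatureSet",
    "DecodingResult",
    "build_epoch_features",
    "decode",
    "shuffle_null",
    "shuffle_subtracted_scores",
]

PRE_PRESS, BASELINE = 1, 0


@dataclass
class EpochFeatureSet:
    """Samples x neurons epoch-mean features with binary labels."""

    features: np.ndarray
    labels: np.ndarray  # 1 = pre-press epoch, 0 = baseline epoch
    epoch_starts: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("feature rows and labels must align")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.features.shape[1]


def build_epoch_features(
    traces: TraceMatrix,
    events: EventLog,
    seed: int = 0,
    epoch_s: float = 1.0,
    exclusion_s: tuple[float, float] = (-10.0, 13.0),
    min_presses: int = 5,
) -> EpochFeatureSet:
    """One pre-press epoch per usable press plus matched random baselines.

    The pre-press epoch covers [-epoch_s, 0) before press onset; presses too
    close to the session start are dropped. Baseline starts are drawn
    without replacement from a 1-s grid of epochs that do not intersect
    ``exclusion_s`` around any press, so baselines never overlap each other
    or any modeled response. Deterministic given the seed.
    """
    fs = traces.frame_rate_hz
    n_ep = int(round(epoch_s * fs))
    presses = events.active_press_times

    pre_starts = []
    for p in presses:
        i0 = int(round((p - epoch_s) * fs))
        if i0 >= 0 and i0 + n_ep <= traces.n_frames:
            pre_starts.append(i0)
    if len(pre_starts) < min_presses:
        raise ValueError(
            f"need >= {min_presses} usable presses, got {len(pre_starts)}"
        )
    n_press = len(pre_starts)

    grid = np.arange(0.0, traces.duration_s - epoch_s, epoch_s)
    allowed = np.ones(grid.size, dtype=bool)
    for p in presses:
        lo, hi = p + exclusion_s[0], p + exclusion_s[1]
        allowed &= (grid + epoch_s <= lo) | (grid >= hi)
    candidates = grid[allowed]
    if candidates.size < n_press:
        raise ValueError(
            "not enough press-free time for baseline epochs; use a longer session"
        )
    rng = np.random.default_rng(seed)
    base_times = rng.choice(candidates, size=n_press, replace=False)
    base_starts = [int(round(t * fs)) for t in base_times]

    starts = np.array(pre_starts + base_starts)
    labels = np.array([PRE_PRESS] * n_press + [BASELINE] * n_press)
    feats = np.stack(
        [traces.data[:, s : s + n_ep].mean(axis=1) for s in starts], axis=0
    )
    return EpochFeatureSet(features=feats, labels=labels, epoch_starts=starts / fs)


def _check_cv(labels: np.ndarray, cv_folds: int) -> None:
    counts = np.bincount(labels, minlength=2)
    if np.any(counts == 0):
        raise ValueError("decoding needs both classes present")
    if counts.min() < 2 * cv_folds:
        raise ValueError(
            f"need >= 2 samples per class per fold ({2 * cv_folds} per class), "
            f"got {counts.min()}"
        )


def _lda_1d_accuracy(
    X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Held-out accuracy of a shared-variance Gaussian LDA per feature column."""
    accs = np.zeros((len(folds), X.shape[1]))
    for f, (tr, te) in enumerate(folds):
        Xtr, ytr = X[tr], y[tr]
        n0, n1 = (ytr == 0).sum(), (ytr == 1).sum()
        m0 = Xtr[ytr == 0].mean(axis=0)
        m1 = Xtr[ytr == 1].mean(axis=0)
        s2 = (
            ((Xtr[ytr == 0] - m0) ** 2).sum(axis=0)
            + ((Xtr[ytr == 1] - m1) ** 2).sum(axis=0)
        ) / len(tr)
        s2[s2 == 0] = 1e-300  # separable column: threshold at the midpoint
        delta = m1 - m0
        thresh_term = delta * (m0 + m1) / (2.0 * s2)
        prior = np.log(n1 / n0)
        score = X[te] * (delta / s2)[None, :] - thresh_term[None, :] + prior
        pred = (score > 0).astype(int)
        accs[f] = (pred == y[te][:, None]).mean(axis=0)
    return accs.mean(axis=0)


def _folds(labels: np.ndarray, cv_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def decode(
    features: EpochFeatureSet,
    unit: str = "population",
    cv_folds: int = 5,
    seed: int = 0,
    classifier: str = "lda",
    labels: np.ndarray | None = None,
):
    """Mean held-out decoding accuracy under stratified cross-validation.

    ``unit="per_neuron"`` decodes from each neuron's single feature column
    independently and returns an accuracy per neuron; ``"population"`` uses
    all columns at once and returns a scalar. ``classifier`` can be "lda"
    (default, deterministic) or "svm" (linear SVC) for the population path.
    """
    y = features.labels if labels is None else np.asarray(labels, dtype=int)
    _check_cv(y, cv_folds)
    folds = _folds(y, cv_folds, seed)
    if unit == "per_neuron":
        return _lda_1d_accuracy(features.features, y, folds)
    if unit != "population":
        raise ValueError(f"unknown unit {unit!r}")
    if classifier == "lda":
        make = lambda: LinearDiscriminantAnalysis()
    elif classifier == "svm":
        make = lambda: LinearSVC()
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    accs = []
    for tr, te in folds:
        Xtr, Xte = features.features[tr], features.features[te]
        try:
            clf = make()
            clf.fit(Xtr, y[tr])
            pred = clf.predict(Xte)
        except (np.linalg.LinAlgError, IndexError, ValueError):
            # zero within-class scatter (noiseless separable fixture):
            # LDA degenerates to the nearest-class-mean rule
            m0 = Xtr[y[tr] == 0].mean(axis=0)
            m1 = Xtr[y[tr] == 1].mean(axis=0)
            d0 = ((Xte - m0) ** 2).sum(axis=1)
            d1 = ((Xte - m1) ** 2).sum(axis=1)
            pred = (d1 < d0).astype(int)
        accs.append(float((pred == y[te]).mean()))
    return float(np.mean(accs))


def shuffle_null(
    features: EpochFeatureSet,
    n_shuffles: int = 100,
    seed: int = 0,
    unit: str = "per_neuron",
    cv_folds: int = 5,
) -> np.ndarray:
    """Label-permutation null accuracy distribution.

    Labels (not time series) are permuted uniformly per shuffle and the
    decoder is re-run. Returns (n_shuffles, n_neurons) for ``per_neuron`` or
    (n_shuffles,) for ``population``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_shuffles):
        perm = rng.permutation(features.labels)
        out.append(
            decode(features, unit=unit, cv_folds=cv_folds, seed=seed + s + 1, labels=perm)
        )
    if unit == "per_neuron":
        if n_shuffles == 0:
            return np.zeros((0, features.n_neurons))
        return np.asarray(out).reshape(n_shuffles, -1)
    return np.asarray(out, dtype=float)


@dataclass
class DecodingResult:
    """Real and shuffled accuracies plus shuffle-subtracted scores."""

    per_neuron_accuracy: np.ndarray
    population_accuracy: float
    null_per_neuron: np.ndarray  # (n_shuffles, n_neurons)
    null_population: np.ndarray  # (n_shuffles,)
    cv_folds: int
    seed: int
    scores: np.ndarray | None = None


def shuffle_subtracted_scores(
    accuracies: np.ndarray,
    null_accuracies: np.ndarray,
    grouping: np.ndarray | None = None,
) -> np.ndarray:
    """score_i = accuracy_i - mean(null accuracies of neuron i's group).

    ``grouping`` assigns each neuron to a cell group (e.g. its ensemble); the
    null mean is pooled over that group's neurons and all shuffles. Without a
    grouping, all neurons form one group.
    """
    acc = np.asarray(accuracies, dtype=float)
    null = np.asarray(null_accuracies, dtype=float)
    if null.size == 0:
        raise ValueError("empty shuffle distribution; run shuffle_null first")
    if null.ndim == 1:
        null = null[:, None].repeat(acc.size, axis=1)
    if grouping is None:
        grouping = np.zeros(acc.size, dtype=int)
    grouping = np.asarray(grouping)
    if grouping.size != acc.size:
        raise ValueError("grouping must give one group per neuron")
    scores = np.empty_like(acc)
    for g in np.unique(grouping):
        m = grouping == g
        scores[m] = acc[m] - null[:, m].mean()
    return scores
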