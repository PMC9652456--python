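"""Synthetic session generator with planted ground truth.

Emulates the structure of a deep-brain two-photon dataset from a head-fixed
sucrose self-administration task: ~30 Hz fluorescence traces for 100-350
neurons per field of view carrying three planted response ensembles
(excited / non-responding / inhibited around active lever presses), a
within-session tonic fluorescence decline, lever-press event streams run
through the reinforcement schedule, movies with disk ROIs, cross-session
tracked cells with response adaptation (e.g. opioid attenuation), and
ohmic vs inwardly-rectifying I-V curves with drug-wash amplitude series.

Every generator is deterministic given its seed. Defaults mirror the study
conditions: 1 h sessions, 30 Hz frame rate, ensemble composition in the
proportions 79 excited / 153 non-responding / 73 inhibited per 305 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .behavior import EventLog, ScheduleConfig, apply_schedule
from .imaging import MovieStack, ROIMaskSet, TraceMatrix
from .ephys import IVCurve, WashSeries

__all__ = [
    "SessionConfig",
    "EnsembleSpec",
    "GroundTruth",
    "IVCurveSpec",
    "PHASES",
    "generate_events",
    "generate_press_trials",
    "generate_traces",
    "generate_movie",
    "generate_tracked_pair",
    "generate_iv_curve",
    "generate_wash_series",
    "default_ensemble_counts",
    "schedule_for_phase",
]

PHASES = (
    "acquisition",
    "suppression_TMT",
    "suppression_yohimbine",
    "extinction",
    "reinstatement",
)

#: reference ensemble composition (excited, non-responding, inhibited) of 305 cells
REFERENCE_COMPOSITION = (79, 153, 73)

CATEGORIES = ("excited", "non_responding", "inhibited")


@dataclass
class SessionConfig:
    """One behavioral session: phase, duration, press rates, reward cap."""

    phase: str = "acquisition"
    duration_s: float = 3600.0
    reward_cap: int | None = 40
    press_rate_active: float = 1.0  # presses/min
    press_rate_inactive: float = 0.2  # presses/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.press_rate_active < 0 or self.press_rate_inactive < 0:
            raise ValueError("press rates must be >= 0")


@dataclass
class EnsembleSpec:
    """Planted response-ensemble structure of one imaging session.

    Amplitudes are peak deviations in normalized-fluorescence units relative
    to a baseline of 1.0; the peri-press response is a boxcar over
    [response_onset_s, response_onset_s + response_dur_s] relative to the
    press, convolved with a single-exponential calcium kernel (tau_s) and
    scaled so its peak equals the planted amplitude. The default onset of
    -1 s plants anticipatory modulation beginning just before the press, as
    press-predictive activity requires. ``drug_attenuation`` shrinks both
    excited and inhibited amplitudes by that fraction (1.0 = fully flat),
    emulating an opioid-injection session. ``amp_jitter_cv`` is the
    trial-to-trial amplitude coefficient of variation.
    """

    n_excited: int = 79
    n_nonresponding: int = 153
    n_inhibited: int = 73
    amp_excited: float = 0.5
    amp_inhibited: float = -0.5
    response_onset_s: float = -1.0
    response_dur_s: float = 3.0
    tonic_decline_frac: float = 0.3
    noise_sd: float = 0.2
    drug_attenuation: float = 0.0
    amp_jitter_cv: float = 0.2
    tau_s: float = 0.6
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_excited, self.n_nonresponding, self.n_inhibited) < 0:
            raise ValueError("ensemble counts must be >= 0")
        if not 0.0 <= self.drug_attenuation <= 1.0:
            raise ValueError("drug_attenuation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amp_excited < 0 or self.amp_inhibited > 0:
            raise ValueError("amp_excited must be > 0 and amp_inhibited < 0")

    @property
    def n_neurons(self) -> int:
        return self.n_excited + self.n_nonresponding + self.n_inhibited

    def labels(self) -> np.ndarray:
        return np.repeat(
            np.array(CATEGORIES, dtype=object),
            [self.n_excited, self.n_nonresponding, self.n_inhibited],
        )


def default_ensemble_counts(n_total: int) -> tuple[int, int, int]:
    """Scale the reference 79/153/73-of-305 composition to ``n_total`` cells."""
    ref = np.array(REFERENCE_COMPOSITION, dtype=float)
    raw = ref / ref.sum() * n_total
    counts = np.floor(raw).astype(int)
    # distribute remainder by largest fractional part
    order = np.argsort(-(raw - counts))
    for i in range(n_total - counts.sum()):
        counts[order[i % 3]] += 1
    return tuple(int(c) for c in counts)


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated session."""

    labels: np.ndarray  # per-neuron category string
    tonic_slopes: np.ndarray  # per-neuron planted decline fraction
    event_times: np.ndarray  # active press times responses were planted on
    roi_centroids: np.ndarray | None = None  # (n, 2) row/col, set by generate_movie
    identity_map: np.ndarray | None = None  # (k, 2) [idxA, idxB] for tracked pairs

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.identity_map is not None:
            idx_b = np.asarray(self.identity_map)[:, 1]
            if np.unique(idx_b).size != idx_b.size:
                raise ValueError("identity map must be injective")


@dataclass
class IVCurveSpec:
    """Synthetic current-voltage relation of an optically evoked EPSC."""

    conductance_nS: float = 1.0
    reversal_mV: float = 0.0
    rectification_mode: str = "ohmic"  # or "inward_rectifying"
    positive_limb_scale: float = 0.1  # applied above reversal when rectifying
    noise_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        if self.conductance_nS <= 0:
            raise ValueError("conductance must be > 0")
        if self.rectification_mode not in ("ohmic", "inward_rectifying"):
            raise ValueError(f"unknown rectification_mode {self.rectification_mode!r}")


def schedule_for_phase(phase: str, reward_cap: int | None) -> ScheduleConfig:
    """Schedule switches per behavioral phase.

    Acquisition and the stressor-suppression sessions deliver cue + sucrose;
    extinction delivers neither; cue-induced reinstatement delivers the cue
    only (timeout from cue onset).
    """
    if phase == "extinction":
        return ScheduleConfig(deliver_cue=False, deliver_sucrose=False, reward_cap=None)
    if phase == "reinstatement":
        return ScheduleConfig(deliver_cue=True, deliver_sucrose=False, reward_cap=None)
    return ScheduleConfig(deliver_cue=True, deliver_sucrose=True, reward_cap=reward_cap)


def generate_events(cfg: SessionConfig) -> EventLog:
    """Poisson press candidates passed through the reinforcement schedule."""
    rng = np.random.default_rng(cfg.seed)
    times = {}
    for lever, rate_per_min in (
        ("active", cfg.press_rate_active),
        ("inactive", cfg.press_rate_inactive),
    ):
        n = rng.poisson(rate_per_min / 60.0 * cfg.duration_s)
        times[lever] = np.sort(rng.uniform(0.0, cfg.duration_s, size=n))
    sched = schedule_for_phase(cfg.phase, cfg.reward_cap)
    return apply_schedule(
        times["active"], times["inactive"], sched, cfg.duration_s, phase=cfg.phase
    )


def generate_press_trials(
    n_trials: int,
    duration_s: float = 3600.0,
    min_sep_s: float = 25.0,
    seed: int = 0,
    phase: str = "acquisition",
) -> EventLog:
    """Event log with exactly ``n_trials`` active presses, all windowable.

    Press times are drawn uniformly but kept at least ``min_sep_s`` apart and
    clear of the session edges, so every press supports a full peri-event
    window. Used for fixed-trial-count simulations.
    """
    rng = np.random.default_rng(seed)
    margin = min_sep_s
    span = duration_s - 2 * margin - (n_trials - 1) * min_sep_s
    if span <= 0:
        raise ValueError("session too short for the requested trial count/separation")
    gaps = rng.uniform(0, 1, size=n_trials)
    gaps = gaps / gaps.sum() * span
    times = margin + np.cumsum(gaps) + min_sep_s * np.arange(n_trials)
    sched = schedule_for_phase(phase, None)
    return apply_schedule(times, [], sched, duration_s, phase=phase)


def _response_kernel(spec: EnsembleSpec, frame_rate_hz: float) -> np.ndarray:
    """Boxcar response convolved with a calcium kernel, peak-normalized to 1."""
    dt = 1.0 / frame_rate_hz
    n_box = max(1, int(round(spec.response_dur_s * frame_rate_hz)))
    box = np.ones(n_box)
    t = np.arange(0, 5 * spec.tau_s + dt, dt)
    kernel = np.exp(-t / spec.tau_s)
    shape = np.convolve(box, kernel)
    return shape / shape.max()


def generate_traces(
    events: EventLog,
    spec: EnsembleSpec,
    frame_rate_hz: float = 30.0,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> tuple[TraceMatrix, GroundTruth]:
    """Planted-ensemble fluorescence traces for one session.

    trace_i(t) = baseline * (1 - tonic_decline_frac * u(t)) + ensemble
    transient around each active press + Gaussian noise, with u(t) running
    linearly 0 -> 1 across the session (last/first frame ratio is exactly
    1 - tonic_decline_frac for a noiseless non-responder).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = spec.labels()
    else:
        labels = np.asarray(labels, dtype=object)
    n = labels.size
    n_frames = int(np.floor(events.duration_s * frame_rate_hz))
    press_times = events.active_press_times
    if press_times.size and press_times.max() > events.duration_s:
        raise ValueError("press times exceed the session duration")

    u = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.zeros(n_frames)
    data = np.tile(spec.baseline * (1.0 - spec.tonic_decline_frac * u), (n, 1))

    atten = 1.0 - spec.drug_attenuation
    amps = np.zeros(n)
    amps[labels == "excited"] = spec.amp_excited * atten
    amps[labels == "inhibited"] = spec.amp_inhibited * atten

    shape = _response_kernel(spec, frame_rate_hz)
    L = shape.size
    onset = spec.response_onset_s
    for p in press_times:
        start = int(round((p + onset) * frame_rate_hz))
        head = 0
        if start < 0:  # response truncated by the session start
            head, start = -start, 0
        if start >= n_frames or head >= L:
            continue
        stop = min(start + L - head, n_frames)
        if spec.amp_jitter_cv > 0:
            jit = np.clip(rng.normal(1.0, spec.amp_jitter_cv, size=n), 0.0, None)
        else:
            jit = np.ones(n)
        data[:, start:stop] += np.outer(amps * jit, shape[head : head + stop - start])

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    truth = GroundTruth(
        labels=labels,
        tonic_slopes=np.full(n, spec.tonic_decline_frac),
        event_times=press_times,
    )
    return TraceMatrix(data, frame_rate_hz), truth


def _grid_centroids(n: int, frame_size_px: tuple[int, int], roi_radius_px: int) -> np.ndarray:
    """Non-overlapping disk centers on a regular grid inside the frame."""
    h, w = frame_size_px
    pitch = 2 * roi_radius_px + 2
    rows = np.arange(roi_radius_px + 1, h - roi_radius_px, pitch)
    cols = np.arange(roi_radius_px + 1, w - roi_radius_px, pitch)
    if rows.size * cols.size < n:
        raise ValueError(
            f"cannot place {n} non-overlapping ROIs of radius {roi_radius_px} "
            f"in a {h}x{w} frame"
        )
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel()[:n], cc.ravel()[:n]], axis=1).astype(float)


def generate_movie(
    traces: TraceMatrix,
    truth: GroundTruth,
    frame_size_px: tuple[int, int] = (128, 128),
    roi_radius_px: int = 3,
    seed: int = 0,
    background: float = 0.0,
    drift_px: tuple[int, int] | None = None,
    drift_from_frame: int | None = None,
) -> tuple[MovieStack, ROIMaskSet]:
    """Render traces into a movie of uniform disks, with optional planted drift.

    Each frame is ``background`` plus, per ROI, a disk at that neuron's trace
    value. If ``drift_px`` is given, frames from ``drift_from_frame`` onward
    are rigidly shifted by (drow, dcol) pixels. ROI centroids are assigned on
    a non-overlapping grid and recorded into ``truth.roi_centroids``.
    """
    n, n_frames = traces.n_neurons, traces.n_frames
    h, w = frame_size_px
    if truth.roi_centroids is None:
        centroids = _grid_centroids(n, frame_size_px, roi_radius_px)
        truth.roi_centroids = centroids
    else:
        centroids = np.asarray(truth.roi_centroids, dtype=float)

    labels_img = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (r, c) in enumerate(centroids, start=1):
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= roi_radius_px**2
        if np.any(labels_img[disk] != 0):
            raise ValueError(f"ROI {i} overlaps a previously placed ROI")
        if not disk.any():
            raise ValueError(f"ROI {i} falls outside the frame")
        labels_img[disk] = i
    rois = ROIMaskSet(labels_img)

    frames = np.full((n_frames, h, w), background, dtype=float)
    for i in range(1, n + 1):
        mask = labels_img == i
        frames[:, mask] = background + traces.data[i - 1][:, None]

    if drift_px is not None:
        k = 0 if drift_from_frame is None else int(drift_from_frame)
        dr, dc = int(drift_px[0]), int(drift_px[1])
        for t in range(k, n_frames):
            frames[t] = np.roll(np.roll(frames[t], dr, axis=0), dc, axis=1)

    return MovieStack(frames, traces.frame_rate_hz), rois


def generate_tracked_pair(
    specA: EnsembleSpec,
    specB: EnsembleSpec,
    overlap_n: int,
    seed: int = 0,
    session_cfg: SessionConfig | None = None,
    frame_rate_hz: float = 30.0,
    centroid_jitter_px: float = 1.0,
    frame_size_px: tuple[int, int] = (256, 256),
    roi_radius_px: int = 3,
):
    """Two sessions sharing ``overlap_n`` tracked cells.

    Shared cells keep their ensemble labels and centroids (plus Gaussian
    jitter of ``centroid_jitter_px``) across sessions; session B applies
    specB's amplitudes/attenuation to them. Session B's cell order is
    permuted so the identity map is non-trivial. Returns
    ((eventsA, tracesA, truthA), (eventsB, tracesB, truthB)) with
    ``truthB.identity_map`` holding [indexA, indexB] pairs.
    """
    if overlap_n > min(specA.n_neurons, specB.n_neurons):
        raise ValueError("overlap_n exceeds a session's population size")
    rng = np.random.default_rng(seed)
    cfg = session_cfg or SessionConfig()

    eventsA = generate_events(replace(cfg, seed=int(rng.integers(2**31))))
    eventsB = generate_events(replace(cfg, seed=int(rng.integers(2**31))))

    labelsA = specA.labels()
    tracesA, truthA = generate_traces(
        eventsA, specA, frame_rate_hz, seed=int(rng.integers(2**31))
    )
    n_a, n_b = specA.n_neurons, specB.n_neurons
    n_fresh = n_b - overlap_n
    n_slots = n_a + max(0, n_fresh - (n_a - overlap_n))
    grid = _grid_centroids(n_slots, frame_size_px, roi_radius_px)
    centroidsA = grid[:n_a]
    truthA.roi_centroids = centroidsA

    # session B: shared cells carry A's labels; the rest follow specB's counts
    shared_idx_a = np.sort(rng.choice(n_a, size=overlap_n, replace=False))
    rest = specB.labels()[:n_fresh]
    labelsB_ordered = np.concatenate([labelsA[shared_idx_a], rest])
    perm = rng.permutation(n_b)
    labelsB = labelsB_ordered[perm]
    tracesB, truthB = generate_traces(
        eventsB, specB, frame_rate_hz, seed=int(rng.integers(2**31)), labels=labelsB
    )

    # Shared cells keep A's positions (plus jitter). Fresh B cells sit a
    # half-pitch diagonal away from the NON-shared A positions (and any extra
    # grid slots), so every unshared cell on both sides has a distinct
    # just-beyond-threshold neighbor and the planted correspondence is the
    # unique optimal assignment rather than one end of a degenerate cascade.
    nonshared_a = np.setdiff1d(np.arange(n_a), shared_idx_a)
    fresh_src = np.concatenate([grid[nonshared_a], grid[n_a:]], axis=0)[:n_fresh]
    centroidsB_ordered = np.concatenate(
        [centroidsA[shared_idx_a], fresh_src + float(roi_radius_px + 1)], axis=0
    )
    if centroid_jitter_px > 0:
        centroidsB_ordered[:overlap_n] += rng.normal(
            0.0, centroid_jitter_px, size=(overlap_n, 2)
        )
    truthB.roi_centroids = centroidsB_ordered[perm]

    pos_in_b = np.argsort(perm)  # ordered index -> position after permutation
    identity = np.stack([shared_idx_a, pos_in_b[:overlap_n]], axis=1)
    truthB.identity_map = identity
    return (eventsA, tracesA, truthA), (eventsB, tracesB, truthB)


def generate_iv_curve(
    spec: IVCurveSpec,
    voltages_mV=(-80, -70, -50, -30, -10, 10, 30, 50),
    seed: int = 0,
) -> IVCurve:
    """Synthetic peak-current I-V relation.

    Ohmic mode: I(V) = g (V - Vrev). Inward-rectifying mode scales the limb
    above the reversal potential by ``positive_limb_scale`` (< 1), the
    signature of calcium-permeable AMPA receptors.
    """
    v = np.asarray(voltages_mV, dtype=float)
    if v.size == 0:
        raise ValueError("voltage list must be non-empty")
    i = spec.conductance_nS * (v - spec.reversal_mV)
    if spec.rectification_mode == "inward_rectifying":
        i = np.where(v > spec.reversal_mV, i * spec.positive_limb_scale, i)
    if spec.noise_sd_pA > 0:
        i = i + np.random.default_rng(seed).normal(0.0, spec.noise_sd_pA, size=v.size)
    return IVCurve(voltages_mV=v, currents_pA=i)


def generate_wash_series(
    pre_amp_pA: float = 100.0,
    post_frac: float = 0.3,
    tau_s: float = 300.0,
    duration_s: float = 1500.0,
    drug_on_s: float = 300.0,
    interval_s: float = 12.5,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
) -> WashSeries:
    """EPSC-amplitude time series with an exponential rundown after drug-on.

    Amplitude is ``pre_amp_pA`` before ``drug_on_s`` and decays exponentially
    toward ``post_frac * pre_amp_pA`` with time constant ``tau_s`` afterwards,
    emulating a 25-min bath-application experiment sampled one sweep per
    ``interval_s``.
    """
    t = np.arange(0.0, duration_s, interval_s)
    amp = np.full(t.size, float(pre_amp_pA))
    after = t >= drug_on_s
    amp[after] = pre_amp_pA * (
        post_frac + (1 - post_frac) * np.exp(-(t[after] - drug_on_s) / tau_s)
    )
    if noise_sd_pA > 0:
        amp = amp + np.random.default_rng(seed).normal(0.0, noise_sd_pA, size=t.size)
    return WashSeries(time_s=t, amplitude_pA=amp, drug_on_s=drug_on_s)
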