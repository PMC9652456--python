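"""Movie-to-trace extraction: rigid registration, ROI means, normalization.

The study's raw data path (motion correction, manual ROI polygons, trace
extraction) is reduced to its testable essentials: integer-pixel rigid
registration by cross-correlation, mean-over-ROI trace extraction from a
labeled mask image, and two fluorescence normalizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "MovieStack",
    "ROIMaskSet",
    "TraceMatrix",
    "register_movie",
    "extract_traces",
    "deltaf_normalize",
]


@dataclass
class TraceMatrix:
    """Neurons x frames fluorescence with its acquisition frame rate."""

    data: np.ndarray  # (n_neurons, n_frames), float
    frame_rate_hz: float
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (neurons x frames)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("traces", data=self.data)
            d.attrs["frame_rate_hz"] = self.frame_rate_hz
            f.create_dataset("neuron_ids", data=np.asarray(self.neuron_ids))

    @classmethod
    def from_hdf5(cls, path) -> "TraceMatrix":
        with h5py.File(path, "r") as f:
            d = f["traces"]
            ids = f["neuron_ids"][...] if "neuron_ids" in f else None
            return cls(d[...], float(d.attrs["frame_rate_hz"]), ids)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.data, index=pd.Index(self.neuron_ids, name="neuron_id"))
        df.insert(0, "frame_rate_hz", self.frame_rate_hz)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TraceMatrix":
        df = pd.read_csv(path, index_col=0)
        rate = float(df.pop("frame_rate_hz").iloc[0])
        return cls(df.to_numpy(dtype=float), rate, df.index.to_numpy())


@dataclass
class MovieStack:
    """3-D intensity stack (frame x row x col) plus frame rate."""

    frames: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("movie must be a 3-D stack with >= 1 frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, frame_rate_hz: float) -> "MovieStack":
        return cls(tifffile.imread(path), frame_rate_hz)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("movie", data=self.frames)
            d.attrs["frame_rate_hz"] = self.frame_rate_hz

    @classmethod
    def from_hdf5(cls, path) -> "MovieStack":
        with h5py.File(path, "r") as f:
            d = f["movie"]
            return cls(d[...], float(d.attrs["frame_rate_hz"]))


@dataclass
class ROIMaskSet:
    """Labeled mask image: integer per pixel, 0 = background, ROIs 1..N."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be a 2-D label image")
        ids = self.roi_ids
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("ROI labels must be contiguous 1..N")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)

    def centroids(self) -> np.ndarray:
        """(N, 2) array of (row, col) centroids in label order."""
        if self.n_rois == 0:
            return np.zeros((0, 2))
        return np.asarray(
            ndimage.center_of_mass(np.ones_like(self.labels), self.labels, self.roi_ids)
        )

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.int32))

    @classmethod
    def from_tiff(cls, path) -> "ROIMaskSet":
        return cls(tifffile.imread(path))


def register_movie(
    movie: MovieStack, reference: str = "mean_frame"
) -> tuple[MovieStack, np.ndarray]:
    """Rigid integer-pixel registration by cross-correlation.

    Each frame's translation relative to the reference (``mean_frame`` or
    ``first_frame``) is estimated with phase cross-correlation and inverted;
    the returned shifts are the corrections applied to each frame.
    Out-of-frame pixels are filled with the frame median. All-flat frames
    trigger a degenerate-registration warning and zero shifts.
    """
    if movie.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    if reference == "mean_frame":
        ref = movie.frames.mean(axis=0)
    elif reference == "first_frame":
        ref = movie.frames[0]
    else:
        raise ValueError(f"unknown reference {reference!r}")

    n = movie.n_frames
    shifts = np.zeros((n, 2), dtype=int)
    out = np.empty_like(movie.frames)
    for i in range(n):
        frame = movie.frames[i]
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn("registration degenerate: flat frame; zero shift", stacklevel=2)
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        shift = np.round(shift).astype(int)
        shifts[i] = shift
        if np.any(shift):
            out[i] = ndimage.shift(frame, shift, order=0, cval=float(np.median(frame)))
        else:
            out[i] = frame
    return MovieStack(out, movie.frame_rate_hz), shifts


def extract_traces(movie: MovieStack, rois: ROIMaskSet) -> TraceMatrix:
    """trace[i, t] = mean intensity over ROI i's pixels at frame t."""
    if rois.labels.shape != movie.frame_shape:
        raise ValueError(
            f"mask shape {rois.labels.shape} != frame shape {movie.frame_shape}"
        )
    ids = rois.roi_ids
    empty = [int(i) for i in range(1, rois.n_rois + 1) if not np.any(rois.labels == i)]
    if empty:
        raise ValueError(f"empty ROI(s): {empty}")
    flat_labels = rois.labels.ravel()
    n_frames = movie.n_frames
    data = np.empty((ids.size, n_frames))
    # sum per label via bincount; constant pixel counts across frames
    counts = np.bincount(flat_labels, minlength=ids.size + 1)[1:]
    for t in range(n_frames):
        sums = np.bincount(flat_labels, weights=movie.frames[t].ravel(), minlength=ids.size + 1)[1:]
        data[:, t] = sums / counts
    return TraceMatrix(data, movie.frame_rate_hz, neuron_ids=ids)


def deltaf_normalize(
    traces: TraceMatrix,
    method: str = "percentile_baseline",
    percentile: float = 10.0,
    first_bin_s: float = 180.0,
) -> TraceMatrix:
    """Normalize fluorescence traces.

    ``percentile_baseline``: (F - F0)/F0 with F0 the per-neuron session
    percentile (default 10th). ``first_bin``: F divided by the per-neuron
    mean over the session's first ``first_bin_s`` seconds. Non-positive
    baselines are an error naming the offending neurons.
    """
    F = traces.data
    if method == "percentile_baseline":
        f0 = np.percentile(F, percentile, axis=1, keepdims=True)
    elif method == "first_bin":
        n_first = max(1, int(round(first_bin_s * traces.frame_rate_hz)))
        f0 = F[:, :n_first].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    bad = np.where(f0.ravel() <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive baseline for neuron(s): {bad.tolist()}")
    out = (F - f0) / f0 if method == "percentile_baseline" else F / f0
    return TraceMatrix(out, traces.frame_rate_hz, traces.neuron_ids)
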