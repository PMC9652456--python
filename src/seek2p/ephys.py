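"""Slice-electrophysiology metrics for optically evoked EPSCs.

AMPA rectification index (I at +50 mV over -I at -70 mV; values well below
the ohmic ratio indicate calcium-permeable AMPA receptors), normalization of
I-V curves to the -80 mV peak, drug-wash window means (first vs last 5 min
of a bath-application recording), and evoked-spike change ratios.

Inputs are per-sweep peak amplitudes, not raw sweeps; inward currents are
negative by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IVCurve",
    "WashSeries",
    "SpikeCounts",
    "normalize_iv",
    "rectification_index",
    "wash_effect",
    "spike_change_ratio",
]


@dataclass
class IVCurve:
    """Peak EPSC current per holding voltage (sweep-averaged)."""

    voltages_mV: np.ndarray
    currents_pA: np.ndarray

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        if self.voltages_mV.shape != self.currents_pA.shape:
            raise ValueError("voltages and currents must have equal length")
        if np.unique(self.voltages_mV).size != self.voltages_mV.size:
            raise ValueError("voltages must be unique")

    def current_at(self, v: float) -> float:
        idx = np.where(np.isclose(self.voltages_mV, v))[0]
        if idx.size == 0:
            raise ValueError(f"curve has no sample at {v} mV")
        return float(self.currents_pA[idx[0]])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"voltage_mV": self.voltages_mV, "current_pA": self.currents_pA}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IVCurve":
        df = pd.read_csv(path)
        return cls(df["voltage_mV"].to_numpy(), df["current_pA"].to_numpy())


@dataclass
class WashSeries:
    """EPSC peak amplitudes across a bath-application recording."""

    time_s: np.ndarray
    amplitude_pA: np.ndarray
    drug_on_s: float
    window_s: float = 300.0  # 5-min analysis windows

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.amplitude_pA = np.asarray(self.amplitude_pA, dtype=float)
        if self.time_s.shape != self.amplitude_pA.shape:
            raise ValueError("time and amplitude must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.time_s, "amplitude_pA": self.amplitude_pA})
        df["drug_on_s"] = self.drug_on_s
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WashSeries":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["amplitude_pA"].to_numpy(),
            float(df["drug_on_s"].iloc[0]),
        )


@dataclass
class SpikeCounts:
    """Per-sweep evoked spike counts before and after a drug wash."""

    baseline: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if np.any(self.baseline < 0) or np.any(self.post < 0):
            raise ValueError("spike counts must be >= 0")


def normalize_iv(curve: IVCurve) -> IVCurve:
    """Divide every current by |I(-80 mV)|, preserving signs."""
    ref = curve.current_at(-80.0)
    if ref == 0:
        raise ValueError("cannot normalize: I(-80 mV) is zero")
    return IVCurve(curve.voltages_mV.copy(), curve.currents_pA / abs(ref))


def rectification_index(curve: IVCurve) -> float:
    """RI = I(+50 mV) / (-I(-70 mV)); requires inward (negative) I(-70)."""
    i_pos = curve.current_at(50.0)
    i_neg = curve.current_at(-70.0)
    if i_neg >= 0:
        raise ValueError(
            f"I(-70 mV) must be negative (inward); got {i_neg} pA — check sign convention"
        )
    return i_pos / (-i_neg)


def wash_effect(series: WashSeries, min_samples: int = 3) -> tuple[float, float, float]:
    """Mean amplitude over the first and last 5 min, plus percent change.

    Windows are taken from the start and end of the recording itself (the
    pre-drug baseline occupies the first window by design). Returns
    (pre_mean, post_mean, percent_change) with percent_change =
    100 * (post - pre) / pre.
    """
    t = series.time_s
    if t.size == 0:
        raise ValueError("empty series")
    pre_mask = t <= t[0] + series.window_s
    post_mask = t >= t[-1] - series.window_s
    if pre_mask.sum() < min_samples or post_mask.sum() < min_samples:
        raise ValueError(
            f"need >= {min_samples} amplitudes in each 5-min window "
            f"(got {int(pre_mask.sum())} pre, {int(post_mask.sum())} post)"
        )
    pre = float(series.amplitude_pA[pre_mask].mean())
    post = float(series.amplitude_pA[post_mask].mean())
    return pre, post, 100.0 * (post - pre) / pre


def spike_change_ratio(counts: SpikeCounts) -> float:
    """Post-wash spiking normalized to the mean baseline spike count."""
    base = counts.baseline.mean()
    if base <= 0:
        raise ValueError("baseline mean spike count must be > 0")
    return float(counts.post.mean() / base)
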