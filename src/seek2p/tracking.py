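"""Cross-session cell tracking and response adaptation.

Cells are matched across two imaging sessions by optimal one-to-one
assignment on ROI centroid distance (a stand-in for the manual
structure-and-position identification used with real fields of view);
matched cells' peri-event responses are then compared across sessions,
per ensemble, including Pearson correlation of per-cell responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .ensembles import PeriEventTensor

__all__ = ["CellMatch", "AdaptationResult", "match_rois", "response_adaptation"]


@dataclass
class CellMatch:
    """One-to-one centroid matching between two sessions."""

    pairs: np.ndarray  # (k, 2) of (idA, idB)
    distances: np.ndarray  # per-pair centroid distance, px
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray

    @property
    def n_matched(self) -> int:
        return self.pairs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_a": self.pairs[:, 0],
                "id_b": self.pairs[:, 1],
                "distance_px": self.distances,
            }
        )


def match_rois(centroids_a, centroids_b, max_dist_px: float = 3.0) -> CellMatch:
    """Optimal assignment minimizing total centroid distance.

    Pairs whose distance exceeds ``max_dist_px`` are dropped after the
    assignment. Empty inputs yield an empty match.
    """
    A = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    B = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if A.size == 0 or B.size == 0:
        return CellMatch(
            pairs=np.zeros((0, 2), dtype=int),
            distances=np.zeros(0),
            unmatched_a=np.arange(A.shape[0] if A.size else 0),
            unmatched_b=np.arange(B.shape[0] if B.size else 0),
        )
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("centroids must be finite")
    D = cdist(A, B)
    rows, cols = linear_sum_assignment(D)
    keep = D[rows, cols] <= max_dist_px
    pairs = np.stack([rows[keep], cols[keep]], axis=1)
    dists = D[rows[keep], cols[keep]]
    return CellMatch(
        pairs=pairs,
        distances=dists,
        unmatched_a=np.setdiff1d(np.arange(A.shape[0]), pairs[:, 0]),
        unmatched_b=np.setdiff1d(np.arange(B.shape[0]), pairs[:, 1]),
    )


@dataclass
class AdaptationResult:
    """Per-tracked-cell responses in each session plus aggregates."""

    response_a: np.ndarray  # matched cells, session A mean response z
    response_b: np.ndarray
    delta: np.ndarray  # B - A per matched cell
    ensemble_labels: np.ndarray | None
    per_ensemble: pd.DataFrame | None
    pearson_r: float
    pearson_p: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "response_a": self.response_a,
                "response_b": self.response_b,
                "delta": self.delta,
            }
        )
        if self.ensemble_labels is not None:
            df["ensemble"] = self.ensemble_labels
        return df


def response_adaptation(
    tensor_a: PeriEventTensor,
    tensor_b: PeriEventTensor,
    match: CellMatch,
    ensembles=None,
) -> AdaptationResult:
    """Compare matched cells' mean post-press responses across two sessions.

    The per-cell statistic is the trial-averaged z-score over the
    press-to-reward segment in each session; ``delta = B - A``. With an
    ``ensembles`` label per session-A cell, per-ensemble aggregates are
    added. Pearson r quantifies the linear association of per-cell
    responses across sessions.
    """
    if match.n_matched == 0:
        raise ValueError("empty match: no tracked cells to compare")
    if (tensor_a.pre_s, tensor_a.mid_s, tensor_a.post_s) != (
        tensor_b.pre_s,
        tensor_b.mid_s,
        tensor_b.post_s,
    ):
        raise ValueError("tensors must share the peri-event window spec")
    resp_a_all = tensor_a.trial_average()[:, tensor_a.response_slice()].mean(axis=1)
    resp_b_all = tensor_b.trial_average()[:, tensor_b.response_slice()].mean(axis=1)
    ia, ib = match.pairs[:, 0], match.pairs[:, 1]
    ra, rb = resp_a_all[ia], resp_b_all[ib]
    delta = rb - ra

    labels = None
    per_ens = None
    if ensembles is not None:
        labels = np.asarray(ensembles, dtype=object)[ia]
        per_ens = (
            pd.DataFrame({"ensemble": labels, "a": ra, "b": rb, "delta": delta})
            .groupby("ensemble")
            .mean()
        )
    if np.std(ra) == 0 or np.std(rb) == 0 or match.n_matched < 3:
        r, p = np.nan, np.nan
    else:
        r, p = pearsonr(ra, rb)
    return AdaptationResult(
        response_a=ra,
        response_b=rb,
        delta=delta,
        ensemble_labels=labels,
        per_ensemble=per_ens,
        pearson_r=float(r),
        pearson_p=float(p),
    )
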