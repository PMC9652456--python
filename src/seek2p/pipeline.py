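"""End-to-end drivers tying the generator to the analysis stages.

These are the entry points the analysis scripts and the validation suite
share: simulate a planted session, recover ensembles from it, and run the
press-decoding analysis, returning plain dictionaries of the quantities a
session report needs.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import decoding as dec
from . import ensembles as ens
from . import synth
from .behavior import EventLog
from .imaging import TraceMatrix

__all__ = [
    "simulate_planted_session",
    "discover_ensembles",
    "ensemble_recovery",
    "decoding_analysis",
]


def simulate_planted_session(
    n_neurons: int = 305,
    n_trials: int = 40,
    seed: int = 0,
    frame_rate_hz: float = 30.0,
    duration_s: float = 3600.0,
    **spec_overrides,
):
    """One imaging session with planted ensembles and a fixed trial count.

    The default composition scales the reference 79/153/73-of-305 ensemble
    proportions to ``n_neurons``. Returns (events, traces, truth).
    """
    n_exc, n_non, n_inh = synth.default_ensemble_counts(n_neurons)
    spec = synth.EnsembleSpec(
        n_excited=n_exc, n_nonresponding=n_non, n_inhibited=n_inh, **spec_overrides
    )
    events = synth.generate_press_trials(
        n_trials=n_trials, duration_s=duration_s, seed=seed
    )
    traces, truth = synth.generate_traces(
        events, spec, frame_rate_hz=frame_rate_hz, seed=seed + 1
    )
    return events, traces, truth


def discover_ensembles(
    traces: TraceMatrix,
    events: EventLog,
    k: int | str = 3,
    seed: int = 0,
    theta: float = 0.5,
):
    """Tensor -> PCA/scree -> spectral clustering -> categorization.

    Returns (tensor, assignment) with per-neuron cluster ids and
    data-derived excited / non-responding / inhibited categories.
    """
    tensor = ens.build_peri_event_tensor(traces, events)
    trial_avg = tensor.trial_average()
    n_comp, evr = ens.select_n_components(trial_avg)
    scores = ens.pca_scores(trial_avg, n_comp)
    assignment = ens.cluster_ensembles(scores, k=k, seed=seed)
    assignment.n_components = n_comp
    assignment.explained_variance = evr
    ens.categorize_clusters(assignment, tensor, theta=theta)
    return tensor, assignment


def ensemble_recovery(seed: int = 0, **session_kwargs) -> dict:
    """Run the full ensemble pipeline on a planted session and score it.

    Returns the adjusted Rand index between recovered clusters and planted
    labels, the per-neuron category accuracy against the planted categories,
    and whether all three category names were recovered.
    """
    events, traces, truth = simulate_planted_session(seed=seed, **session_kwargs)
    tensor, assignment = discover_ensembles(traces, events, seed=seed)
    ari = adjusted_rand_score(truth.labels, assignment.cluster_ids)
    cat_acc = float(np.mean(assignment.categories == truth.labels))
    names_ok = set(assignment.cluster_categories.values()) == {
        "excited",
        "non_responding",
        "inhibited",
    }
    return {
        "ari": float(ari),
        "category_accuracy": cat_acc,
        "category_names_correct": bool(names_ok),
        "n_components": assignment.n_components,
        "tensor": tensor,
        "assignment": assignment,
        "truth": truth,
        "events": events,
        "traces": traces,
    }


def decoding_analysis(
    traces: TraceMatrix,
    events: EventLog,
    grouping: np.ndarray,
    seed: int = 0,
    n_shuffles: int = 100,
) -> dict:
    """Per-neuron press decoding with a shuffle null, grouped scores.

    ``grouping`` assigns each neuron to the cell group (ensemble) whose
    pooled shuffle mean is subtracted from its real accuracy. Returns group
    mean scores, the overall null mean accuracy, and the population
    accuracy.
    """
    feats = dec.build_epoch_features(traces, events, seed=seed)
    acc = dec.decode(feats, unit="per_neuron", seed=seed)
    null = dec.shuffle_null(feats, n_shuffles=n_shuffles, seed=seed, unit="per_neuron")
    scores = dec.shuffle_subtracted_scores(acc, null, grouping=grouping)
    pop_acc = dec.decode(feats, unit="population", seed=seed)
    groups = np.unique(np.asarray(grouping, dtype=object))
    group_scores = {str(g): float(scores[np.asarray(grouping) == g].mean()) for g in groups}
    return {
        "per_neuron_accuracy": acc,
        "scores": scores,
        "group_mean_scores": group_scores,
        "null_mean": float(null.mean()),
        "population_accuracy": float(pop_acc),
    }
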