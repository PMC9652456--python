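import numpy as np
import pytest

from seek2p import pipeline, synth
from seek2p.behavior import ScheduleConfig, apply_schedule


@pytest.fixture(scope="session")
def planted_runs():
    """Full pipeline over 20 seeds at study-scale conditions.

    305 neurons in the reference 79/153/73 proportions, 40 press trials,
    peak amplitudes +/-0.5, noise SD 0.2. Shared by the ensemble-recovery
    and decoding checks.
    """
    runs = []
    for seed in range(20):
        res = pipeline.ensemble_recovery(
            seed=seed, n_neurons=305, n_trials=40, noise_sd=0.2
        )
        dec = pipeline.decoding_analysis(
            res["traces"], res["events"], res["truth"].labels, seed=seed, n_shuffles=100
        )
        runs.append(
            {
                "ari": res["ari"],
                "names_ok": res["category_names_correct"],
                "category_accuracy": res["category_accuracy"],
                "group_scores": dec["group_mean_scores"],
                "null_mean": dec["null_mean"],
            }
        )
    return runs


@pytest.fixture()
def small_session():
    """Quick 10 Hz session with planted ensembles for unit-level checks."""
    events, traces, truth = pipeline.simulate_planted_session(
        n_neurons=60, n_trials=15, seed=11, frame_rate_hz=10.0, duration_s=1200.0
    )
    return events, traces, truth


def schedule_oracle_1ms(active_ms, cfg: ScheduleConfig, duration_ms: int):
    """Brute-force schedule walker on a 1-ms grid.

    Steps every millisecond, tracking the timeout end and reward tally, and
    returns the indices of reinforced presses. Independent of apply_schedule:
    integer-millisecond state machine instead of event-driven float logic.
    """
    press_at = {}
    for idx, t in enumerate(active_ms):
        press_at.setdefault(int(t), []).append(idx)
    timeout_end = -1
    rewards_triggered = 0  # consumes the cap at press time
    rewards_delivered = 0  # delivery lands within the session
    reinforced = []
    any_consequence = cfg.deliver_cue or cfg.deliver_sucrose
    timeout_ms = int(round(cfg.timeout_s * 1000))
    delay_ms = int(round(cfg.sucrose_delay_s * 1000))
    for ms in range(duration_ms + 1):
        if ms not in press_at:
            continue
        for idx in press_at[ms]:
            cap_ok = (
                (not cfg.deliver_sucrose)
                or (cfg.reward_cap is None)
                or rewards_triggered < cfg.reward_cap
            )
            if any_consequence and ms >= timeout_end and cap_ok:
                reinforced.append(idx)
                if cfg.deliver_sucrose:
                    rewards_triggered += 1
                    if ms + delay_ms <= duration_ms:
                        rewards_delivered += 1
                timeout_end = ms + timeout_ms
    return reinforced, rewards_delivered


@pytest.fixture()
def oracle_1ms():
    return schedule_oracle_1ms
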