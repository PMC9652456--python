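"""Simulate the head-fixed operant protocol end to end.

Generates the acquisition ladder (daily 1-h sessions with reward caps
10/10/20/20/40...), the two stressor-suppression tests (45-min uncapped
sessions at reduced press rates), extinction days until the a-priori
criterion is met, and a cue-induced reinstatement test; writes per-session
summaries and the extinction-criterion audit to results/.
"""

from pathlib import Path

import pandas as pd

from seek2p import synth
from seek2p.behavior import extinction_met, summarize_session

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1

rows = []

# acquisition: caps 10 (days 1-2), 20 (days 3-4), 40 (days 5-14)
acq_counts = []
for day in range(1, 15):
    cap = 10 if day <= 2 else 20 if day <= 4 else 40
    rate = min(0.3 + 0.15 * day, 1.5)  # pressing builds across learning
    cfg = synth.SessionConfig(
        phase="acquisition", duration_s=3600, reward_cap=cap,
        press_rate_active=rate, press_rate_inactive=0.2, seed=SEED + day,
    )
    s = summarize_session(synth.generate_events(cfg))
    acq_counts.append(s.active_presses)
    rows.append({"phase": "acquisition", "day": day, "cap": cap, **s.__dict__})

# stressor suppression: 45-min uncapped sessions, pressing largely abolished
for phase in ("suppression_TMT", "suppression_yohimbine"):
    cfg = synth.SessionConfig(
        phase=phase, duration_s=2700, reward_cap=None,
        press_rate_active=0.1, press_rate_inactive=0.2, seed=SEED + 100,
    )
    s = summarize_session(synth.generate_events(cfg))
    rows.append({"phase": phase, "day": 1, "cap": None, **s.__dict__})

# extinction: pressing decays day by day until the criterion is met
ext_counts = []
day = 0
while True:
    day += 1
    rate = max(1.5 * 0.7 ** (day - 1), 0.02)
    cfg = synth.SessionConfig(
        phase="extinction", duration_s=3600, reward_cap=None,
        press_rate_active=rate, press_rate_inactive=0.2, seed=SEED + 200 + day,
    )
    s = summarize_session(synth.generate_events(cfg))
    ext_counts.append(s.active_presses)
    rows.append({"phase": "extinction", "day": day, "cap": None, **s.__dict__})
    met, reasons = extinction_met(ext_counts, acq_counts[-2:])
    if met or day >= 25:
        break

# cue-induced reinstatement: cue restored, pressing recovers
cfg = synth.SessionConfig(
    phase="reinstatement", duration_s=3600, reward_cap=None,
    press_rate_active=0.8, press_rate_inactive=0.2, seed=SEED + 300,
)
s = summarize_session(synth.generate_events(cfg))
rows.append({"phase": "reinstatement", "day": 1, "cap": None, **s.__dict__})

RESULTS.mkdir(exist_ok=True)
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "behavior_sessions.csv", index=False)

print(f"wrote {len(df)} session summaries to results/behavior_sessions.csv")
print(f"acquisition last-2-day active presses: {acq_counts[-2:]}")
print(
    f"extinction met after {day} days "
    f"(threshold {reasons['threshold']:.1f} presses, last 3 days {reasons['last3']})"
)
print(f"reinstatement active presses: {s.active_presses}")
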