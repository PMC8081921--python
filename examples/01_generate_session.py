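"""Generate one synthetic sleep-wake session and inspect its ground truth.

The default scenario emulates a striatal-disinhibition recording: a quiet-
waking block with ~65 tics/min of mean intensity ~119 deg/s (peak-to-peak),
a falling-asleep transition with decaying tic amplitude, and a sleep block
where tics all but disappear while LFP spikes persist at ~60/min.
"""

import numpy as np

from ticstate import synth

cfg = synth.paper_default()
session, truth = synth.generate_session(cfg, seed_or_rng=1, session_id="demo")

print(f"session duration: {session.duration_s:.0f} s")
for start, end, label in session.states.intervals[:4]:
    print(f"  [{start:7.1f}, {end:7.1f})  {label}")
print("  ...")

for label in ("quiet_waking", "transition", "sleep"):
    minutes = session.states.duration_of(label) / 60
    tic = truth.tic_state == label
    lfp = truth.lfp_state == label
    tic_amp = truth.tic_p2p[tic].mean() if tic.any() else float("nan")
    print(f"{label:13s} injected tics {tic.sum() / minutes:5.1f}/min "
          f"(mean p2p {tic_amp:6.1f} deg/s), "
          f"LFP spikes {lfp.sum() / minutes:5.1f}/min")

paired = (truth.tic_lfp_index >= 0).sum()
print(f"paired tics: {paired}/{truth.tic_onset_s.size} "
      "(each lags its LFP spike onset by "
      f"{cfg.tic_lag_s * 1000:.0f} ms)")
# Rates and amplitudes carry per-session jitter around the group means, so a
# single session lands near -- not exactly on -- the configured values.
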