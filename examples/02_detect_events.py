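"""Detect tics and LFP spikes in a generated session and tabulate per-state
statistics.

Tics are threshold events on the low-passed gyroscope x-axis (robust
median/MAD threshold, baseline from quiet-waking + sleep samples); LFP
spikes are threshold events on the <100 Hz field potential.  The printed
rates and peak-to-peak amplitudes should track the injected per-state
values: tic expression collapses in sleep, LFP spikes do not.
"""

from ticstate import detect, synth

cfg = synth.paper_default()
session, truth = synth.generate_session(cfg, seed_or_rng=1, session_id="demo")

tics = detect.detect_tics(session.gyro[:, 0], session.gyro_fs, session.states)
lfp = detect.detect_lfp_spikes(session.lfp[0], session.lfp_fs,
                               states=session.states)

print(f"detected {len(tics)} tics (injected {truth.tic_onset_s.size}), "
      f"{len(lfp)} LFP spikes (injected {truth.lfp_onset_s.size})\n")
print("tic statistics per state:")
print(detect.event_stats_by_state(tics, session.states).round(2))
print("\nLFP-spike statistics per state:")
print(detect.event_stats_by_state(lfp, session.states).round(2))

mat, dropped = detect.event_waveforms(session.gyro[:, 0], session.gyro_fs,
                                      tics.in_state("quiet_waking"))
stability = detect.shape_stability(mat)
print(f"\nquiet-waking tic shape stability (mean correlation between "
      f"chronological thirds): {stability['summary']:.3f}")
# A stable stereotyped movement gives a correlation near 1.
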