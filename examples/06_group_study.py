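"""Group-level study: generate several sessions, run the full pipeline, and
test the wake-vs-sleep comparisons across sessions.

This is a scaled-down version of the default 18-session study (6 sessions
here, so it runs in a few seconds).  The paired t across sessions rejects
wake = sleep for the tic rate but not for the LFP-spike rate -- the
state-dependent dissociation at the group level.
"""

from ticstate import report, synth

cfg = synth.paper_default()
cfg.n_sessions = 6
rep = report.run_pipeline(cfg, seed=1, include_units=False)

cols = ["tic_rate_quiet_waking", "tic_rate_sleep",
        "lfp_rate_quiet_waking", "lfp_rate_sleep",
        "co_occurrence_quiet_waking"]
print(rep.sessions[cols].round(2).to_string(index=False))
print()
for name in ("tic_rate_wake_vs_sleep", "lfp_rate_wake_vs_sleep"):
    res = rep.tests[name]
    print(f"{name:24s} {res['test']}: statistic = "
          f"{res.get('t', res.get('W')):.2f}, p = {res['p']:.3g} (n = {res['n']})")
r2 = rep.across_session["magnitude_r2_quiet"]
print(f"across-session magnitude relation (quiet): r^2 = {r2['r2']:.2f}")
# With all 18 sessions the same pipeline reproduces the full group panel;
# see scripts/acceptance.py.
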