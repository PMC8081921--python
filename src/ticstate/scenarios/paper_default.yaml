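seed: 0
n_sessions: 18
quiet_s: 600.0
transition_s: 240.0
sleep_s: 600.0
n_awakenings: 2
awakening_s: 10.0
transition_micro_s: 30.0
gyro_fs: 1000.0
lfp_fs: 1000.0
wideband_fs: 10000.0
render_wideband: false
n_electrodes: 1
lfp_rate_per_min:
  quiet_waking: 68.0
  transition: 68.0
  sleep: 60.0
  other: 68.0
lfp_p2p_mean:
  quiet_waking: 1054.0
  transition: 1054.0
  sleep: 932.0
  other: 1054.0
lfp_p2p_cv:
  quiet_waking: 0.24
  transition: 0.24
  sleep: 0.26
  other: 0.24
lfp_kernel_s: 0.54
lfp_kernel_latency_s: 0.075
refractory_s: 0.5
tic_rate_per_min:
  quiet_waking: 65.0
  transition: 62.0
  sleep: 3.0
  other: 65.0
pairing_prob:
  quiet_waking: 0.9
  transition: 0.85
  sleep: 0.0
  other: 0.9
tic_amp_mean:
  quiet_waking: 119.0
  sleep: 5.0
  other: 80.0
tic_amp_cv:
  quiet_waking: 0.45
  transition: 0.45
  sleep: 0.49
  other: 0.45
sleep_tic_session_prob: 0.3888888888888889
sleep_tic_rate_cv: 0.7
tic_lag_s: 0.072
gyro_kernel_s: 0.35
gyro_kernel_latency_s: 0.075
rate_session_cv:
  quiet_waking: 0.29
  sleep: 0.35
amp_gain_shared_ln_sd: 0.48
amp_gain_tic_ln_sd: 0.26
amp_gain_lfp_ln_sd: 0.15
gyro_noise_sd: 0.15
lfp_noise_sd: 25.0
mua_noise_sd: 5.0
mua_gain:
  quiet_waking: 4.6
  transition: 3.0
  sleep: 1.25
  other: 4.6
mua_kernel_latency_s: 0.028
mua_kernel_ln_sd: 0.65
n_spn: 2
n_fsi: 3
spn_rate:
  quiet_waking: 2.25
  transition: 2.25
  sleep: 2.3
  other: 2.25
fsi_rate:
  quiet_waking: 13.12
  transition: 13.12
  sleep: 7.72
  other: 13.12
unit_rate_ln_sd: 0.6
spn_lock_mag:
  quiet_waking: 30.0
  transition: 30.0
  sleep: 6.4
  other: 30.0
fsi_lock_mag:
  quiet_waking: 52.6
  transition: 52.6
  sleep: 19.9
  other: 52.6
unit_mag_cv: 0.6
unit_kernel_sd_s: 0.02
unit_kernel_latency_s: 0.046
lock_lost_prob:
  SPN: 0.39
  FSI: 0.48
lock_pattern_change_prob: 0.3
waveform_fs: 30000.0
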