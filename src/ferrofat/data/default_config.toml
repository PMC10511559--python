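# Default acquisition, fitting, threshold and statistics parameters.
# Any key can be overridden by a user config file; unknown keys are rejected.

[spectrum]
# Six-peak fat spectrum: chemical-shift offsets from water (ppm) with
# relative amplitudes (normalized to sum to 1 at load time).
field_strength_t = 1.5
ppm_offsets = [0.60, -0.39, -1.94, -2.60, -3.40, -3.80]
relative_amplitudes = [0.048, 0.039, 0.004, 0.128, 0.693, 0.087]

[protocols.pancreas]
first_te_ms = 1.0
delta_te_ms = 1.6
n_echoes = 12

[protocols.liver]
first_te_ms = 1.0
delta_te_ms = 1.6
n_echoes = 12

[protocols.heart]
first_te_ms = 2.0
delta_te_ms = 2.2
n_echoes = 10

[fit]
t2star_min_ms = 0.1
t2star_max_ms = 1000.0
ff_starts = [0.05, 0.25, 0.45, 0.65]
truncation_snr_factor = 2.0
with_offset = false

[thresholds]
pancreas_t2s_normal_ms = 26.0
ff_upper_limit_pct = 6.6
lic_significant_mg_g = 3.0
heart_t2s_normal_ms = 20.0
jet_velocity_ph_m_s = 3.2
fpg_ifg_mg_dl = 100.0
fpg_dm_mg_dl = 126.0
glucose2h_igt_mg_dl = 140.0
glucose2h_dm_mg_dl = 200.0

[lic_calibration]
slope_mg_g_per_hz = 0.0254
intercept_mg_g = 0.202

[stats]
alpha = 0.05
stepwise_entry_p = 0.05
stepwise_removal_p = 0.10
vif_max = 5.0
tolerance_min = 0.20
normative_epsilon_pct = 0.1
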