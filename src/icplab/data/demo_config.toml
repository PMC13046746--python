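# Demo pipeline: every stage on synthetic inputs at reduced resolution.
# Run with:  icplab run --config src/icplab/data/demo_config.toml --out runs/demo --seed 1

[run]
stages = ["simulate", "coverage", "sar", "qualification", "icp"]
seed = 1
out_dir = "runs/demo"
log_level = "INFO"

[head]
shape = "ellipsoid"
semi_axes_mm = [70.0, 90.0, 80.0]
mesh_resolution_mm = 8.0

[coverage]
n_poses = 48
spacing_mm = 4.0
threshold_ut = 28.0
standoff_mm = 5.0
amp_turns = 11.0

[drift]
n_implants = 8
duration_weeks = 52.0
true_drift_rate_mmhg_per_year = 0.5
noise_sd_mmhg = 0.1
limit_mmhg = 2.0

[aging]
working_c = 39.0
elevated_c = 85.0
q10 = 2.0
accelerated_weeks = 22.0

[icp]
n_readings = 36
duration_days = 90.0
heart_rate_bpm = 70.0
pulse_amp_mmhg = 2.0
noise_sd_mmhg = 0.2
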