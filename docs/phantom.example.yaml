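# Example benchmark configuration (all fields optional; defaults shown for
# the fields most runs change).  Pass with:
#   reirrad-benchmark run --config phantom.yaml --out run_dir --seed 1
n_cases: 7
n_centres: 6
include_stress: true          # generate the last case as the atelectasis-like stress case
size: [96, 96, 64]
spacing: [2.0, 2.0, 3.0]      # mm
deform_amplitude_mm: 10.0     # max ground-truth displacement (random part)
deform_smoothness_mm: 30.0
sigma_rir_mm: 3.0             # rigid residual, RMS displacement
sigma_dir_mm: 1.0             # deformable residual, RMS displacement
roi_jitter_mm: 10.0           # per-centre jitter of the rigid-fit ROI anchor
dose_threshold_Gy: 2.0        # cranio-caudal EQD2 restriction level
sdsc_tau_mm: 3.0
hd_percentile: 98.0
constraint_volume_cm3: 0.3
dvh_bin_Gy: 0.1
staple_threshold: 0.5
exclusion_gate_msd_mm: 10.0
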