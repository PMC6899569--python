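# Male WT-like vs KO-like osteoblast spectra. The KO group is dominated by a
# large increase in immature amorphous calcium phosphate (ACP), a small OCP
# decrease and CAP increase, and a modest mineral-to-matrix decrease
# (amide I increases).
kind: raman_phantom
n_spectra_per_group: 50
wavenumber_step_cm1: 0.5
noise_sigma_rel: 0.01
area_jitter_cv: 0.05
cosmic_spike_count: 1
baseline_coeffs: [5.0, 1.5, -0.8, 0.3]
shared_bands:
  PHE: {center: 1004.0, area: 1.0, sigma: 2.5}
  CH2: {center: 1450.0, area: 0.8, sigma: 4.0}
  amide3: {center: 1280.0, area: 0.6, sigma: 10.0}
groups:
  wt:
    bands:
      ACP: {center: 948.0, area: 0.05, sigma: 2.0, gaussian_fraction: 0.85}
      OCP: {center: 955.0, area: 0.45, sigma: 2.0, gaussian_fraction: 0.85}
      CAP: {center: 962.0, area: 0.50, sigma: 2.0, gaussian_fraction: 0.85}
      amide1: {center: 1660.0, area: 0.90, sigma: 8.0}
  ko:
    bands:
      ACP: {center: 948.0, area: 1.18, sigma: 2.0, gaussian_fraction: 0.85}
      OCP: {center: 955.0, area: 0.3846, sigma: 2.0, gaussian_fraction: 0.85}
      CAP: {center: 962.0, area: 0.62, sigma: 2.0, gaussian_fraction: 0.85}
      amide1: {center: 1660.0, area: 2.615, sigma: 8.0}
true_folds: {ACP: 23.6, OCP: -1.17, CAP: 1.24, mineral_matrix: -1.33}
seed: 22
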