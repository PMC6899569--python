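# Female WT-like vs KO-like osteoblast spectra. The KO group carries a large
# increase in the mature carbonated-apatite (CAP) sub-band and in the
# mineral-to-matrix ratio (amide I decreases), with small ACP/OCP increases.
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
      ACP: {center: 948.0, area: 0.30, sigma: 2.0, gaussian_fraction: 0.85}
      OCP: {center: 955.0, area: 0.30, sigma: 2.0, gaussian_fraction: 0.85}
      CAP: {center: 962.0, area: 0.40, sigma: 2.0, gaussian_fraction: 0.85}
      amide1: {center: 1660.0, area: 1.0, sigma: 8.0}
  ko:
    bands:
      ACP: {center: 948.0, area: 0.531, sigma: 2.0, gaussian_fraction: 0.85}
      OCP: {center: 955.0, area: 0.363, sigma: 2.0, gaussian_fraction: 0.85}
      CAP: {center: 962.0, area: 4.20, sigma: 2.0, gaussian_fraction: 0.85}
      amide1: {center: 1660.0, area: 0.4281, sigma: 8.0}
true_folds: {ACP: 1.77, OCP: 1.21, CAP: 10.5, mineral_matrix: 11.9}
seed: 21
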