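# Methods

This note documents the models, parameter choices and known limitations of
the package. Everything quantitative here is computed by the test suite or
the analysis scripts; nothing is asserted that the code does not reproduce.

## Cortex phantom

The CT substrate is a hollow-cylinder cortex: an annulus (default outer
radius 120 µm, inner radius 71 µm, 300 slices at 0.65 µm isotropic voxels —
a sub-micron-CT-scale window of mouse tibial cortex) containing three pore
populations:

- **Lacunae** — ellipsoids with truncated log-normal volumes (log10 mean 2.4
  → median ≈ 250 µm³, matching a lacunar population dominated by volumes
  above 200 µm³; sd 0.18; truncation 50–1500 µm³), random orientation, axis
  ratios ≤ 2.5 so the population never satisfies the canal shape criterion.
  An optional second log-normal mode makes the population bimodal.
- **Canals** — capsules (cylinder plus hemispherical caps), radius 3.5–5 µm
  (5–8 µm for the KO-male-like fixture's enlarged canals), length 90–180 µm,
  orientation within 12° of the stack axis. Their length/radius gives
  elongation well above 3 and extent well above 30 µm, and their minimum
  volume (~2500 µm³) clears the largest lacuna (1500 µm³), so the
  shape-then-volume classification rule is exact by construction.
- **Specks** — 2×2×1-voxel debris below the 8-voxel noise floor, supplying
  the small unclassified remainder that real segmentations report.

Pores are placed by rejection sampling with two invariants: every pore voxel
lies strictly inside the annulus (2-voxel margin from both surfaces), and no
two pores are 26-adjacent, so connected-component labelling reproduces the
generator's pore list exactly and ground-truth classes are unambiguous.
Merged lacuna–canal composites, which occur in real tissue, are deliberately
excluded; the classification accuracy measured here therefore does not bound
accuracy on real data with touching pores.

**Composition targeting.** Fixtures state a target lacuna/canal/noise
partition of total pore volume. Lacunae are sampled first; canals are then
added until their rasterised voxel count reaches the implied target (the
last canal's length is tuned in voxel steps, and small lacunae are topped up
afterwards to restore the exact ratio — canal volumes are coarse, ~50 µm³
lacunae are fine-grained); finally the speck count is set from the realised
totals. The ground-truth partition lands within ~0.1 percentage point of the
target, so parameter-recovery tolerances are spent on the pipeline, not the
generator.

**Intensity model.** 8-bit by default: bone 180, background 30, additive
Gaussian noise σ = 5, so the fixed binarisation threshold of 80 sits 16–30
noise deviations from either class and misclassified voxels are vanishingly
rare at these volume sizes. Optional osteoid halos (enabled in the
KO-male-like fixture) put a 2-µm shell at 0.6× bone intensity around pores —
above threshold, so they model visual contrast, not segmentation difficulty.
No X-ray physics (beam hardening, rings, phase contrast) is simulated.

## Porosity extraction

"Keep largest region, close, AND with inverted bone": the largest
26-connected bone component is closed with a ball structuring element
(default radius 15 voxels at the sub-micron scale) implemented by exact
Euclidean distance transforms — dilation is EDT(background) ≤ r, erosion is
EDT(mask) > r. This is exact discrete morphology with the Euclidean ball, so
the closing is idempotent (tested), and it is far faster at ~5·10⁷ voxels
than an explicit 31³ structuring element. The mask is padded by r+2 voxels
before closing so the element never runs against the array border. Closing
is the implementation of "eroded and dilated": erosion-first would destroy
thin cortices; the order is configurable. The marrow cavity (radius ≫ r)
survives the closing and is excluded automatically; intracortical pores with
inscribed radius < r are filled and recovered. On noise-free-classification
phantoms the recovered porosity equals the ground-truth pore mask voxel for
voxel (tested).

Pores touching the first/last slice are retained by default (a fixed axial
window is analysed); a flag drops them.

## Morphometry

Per-pore descriptors come from the voxel cloud: the covariance matrix gets
+1/12 on the diagonal (each voxel treated as a unit cube), which regularises
single-voxel and planar pores; elongation is √(λmax/λmin), extent is the
range of projections onto the principal axis plus one voxel. The
lacuna/canal threshold is (1 − 0.01) × the smallest canal-candidate volume
(candidates: elongation ≥ 3 and extent ≥ 30 µm; the criterion values are
package defaults, declared approximations to scanner-software internals, and
configurable). The threshold is computed per specimen, never pooled.
Densities normalise to the cortical solid volume (the closed mask); a
bone-volume denominator is available via the mask the caller passes.

## Volume distributions

KDE on log10 volumes (linear axis by flag), Gaussian kernel, bandwidth
0.9·min(sd, IQR/1.34)·n^(−1/5) — the classic reference rule, recorded in the
output for provenance. 2048 grid points spanning the data range ± 3
bandwidths; the trapezoid integral is 1 within 10⁻³ for realistic samples
(tested). Modes require prominence ≥ 5% of the peak density; smaller ripples
are estimation artifacts. The split is the density minimum between the two
highest modes; the small-population proportion is the fraction of volumes
strictly below it. Distributions are estimated per specimen; group summaries
compare proportions, never pooled volumes.

## Cross-sectional geometry

Slices are taken perpendicular to the stack axis; bone length is the span of
slices containing bone and positions are percentages of that span. Second
moments are computed about the section centroid from pixel centres plus the
per-pixel self-moment a⁴/12; I_min/I_max are the eigenvalues of the 2×2 area
moment tensor. Ellipticity is defined as √(I_max/I_min) — the axis ratio of
the moment-equivalent ellipse — and cortical thickness as twice the mean
medial-axis distance of the section; both are pinned package definitions
where scanner software leaves the operational definition unstated. Analytic
benchmarks (circular and elliptical annuli) agree within 1% at 1 µm pixels,
and the error halves with pixel size (tested). BMD calibration is an affine
least-squares map through ≥ 2 hydroxyapatite phantom points (exact through
2); negative mapped densities clamp to zero with a logged warning.

## Raman pipeline

The synthetic spectrum is baseline (polynomial of degree ≤ 9 in a [−1, 1]
scaled domain) + area-parameterised pseudo-Voigt bands + Gaussian noise +
optional one-point cosmic spikes. Band areas jitter per spectrum (log-normal,
CV 5%) to emulate cell-to-cell variability. Noise σ is 1% of the
phenylalanine peak height — the natural reference since all spectra are
normalised to that band, and it models constant instrument noise across
groups whose strongest mineral band differs. The two group fixtures encode
the study contrasts through band-area ratios: ACP/OCP/CAP sub-bands at
948/955/962 cm⁻¹ (σ = 2 cm⁻¹ half-widths, 85% Gaussian), phenylalanine 1004,
amide III 1280, CH₂ 1450, amide I 1660 cm⁻¹; the amide I area is set from
the encoded mineral-to-matrix fold once the phosphate folds are fixed.

Preprocessing: (1) despiking removes samples exceeding both neighbours by
8 noise deviations — a one-point criterion that cannot clip smooth band
apexes; (2) BayesShrink per-level soft wavelet thresholding (sym8, 5
levels), chosen over the universal threshold because it shrinks genuine band
coefficients far less; (3) the 9th-order polynomial baseline is fitted
iteratively with points more than 2σ above the current fit excluded from the
next fit — exclusion (rather than value-clipping) keeps the polynomial from
riding up under the band cluster, leaving baseline error an order of
magnitude below band heights (tested: recovered heights within 5% at 1%
noise). Re-running `preprocess` is a no-op: the spectrum records its
processing state in flags and completed stages are skipped.

Deconvolution fits pseudo-Voigt sub-bands (lmfit) plus a constant offset
over 940–975 cm⁻¹; centers are bounded to ±1 cm⁻¹ windows and half-widths to
1.8–2.2 cm⁻¹ around the package's nominal band model — with three strongly
overlapping sub-bands, looser bounds let neighbouring bands exchange area
and bias small-band folds. These are configuration values, not code
constants, since sub-band assignments differ between instruments and
references. Matrix bands are fitted singly in their own windows. The
mineral-to-matrix ratio uses amide I as denominator (the usual choice where
the reporting convention is unstated). Fold changes use the signed
convention (+A/B, −B/A), which is antisymmetric and never in (−1, 1).

## Statistics

Type-II sums of squares for the sex × genotype ANOVA (robust to the mild
imbalance of littermate designs; the choice is recorded because no SS type
is canonical); zero-variance responses report p = 1 rather than an undefined
F. The null rejection rate at α = 0.05 is 5% ± 2% over 1000 simulated
designs (tested). Paired littermate tests are one-tailed on KO − WT
differences with the direction declared per endpoint; t = 0 reports p = 0.5.
No multiple-testing correction is applied across axial positions by default
(matching per-position reporting); a Benjamini–Hochberg flag exists.
ΔΔCt folds are 2^(−ΔΔCt) against a reference gene and calibrator-group mean
ΔCt, invariant to Ct offsets applied to both genes.

## Problem sizes

The test suite runs the CT fixtures at 378×378×150 voxels with 60–100
lacunae (the package's reduced-scale configuration; composition targets are
unchanged) and 12 spectra per Raman group; `scripts/acceptance.py` uses the
full 378×378×300 stacks with the fixtures' full populations and 50 spectra
per group. Recovery at the two scales is indistinguishable because the
composition targeting operates on rasterised voxel counts at either scale.

## Known limitations

- Phantoms have non-touching pores and noise far from the threshold;
  real SR CT data have merged pores, partial-volume surfaces and
  reconstruction artifacts the generator does not model.
- The canal shape criterion (elongation ≥ 3, extent ≥ 30 µm) and the
  ACP/OCP/CAP sub-band positions are declared package defaults, not values
  taken from any instrument protocol.
- No canal-network topology (branching, connectivity); only scalar indices.
- The per-group vs per-animal choice of the lacunar split volume is
  configurable; the default splits a per-group pooled density.
- `J = I_min + I_max` is a geometric index; no torsional stress prediction
  is implied.
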