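# Methods

This note documents the models and procedures implemented in `ramanid`,
the assumptions behind them, the defaults that matter, and the choices
made where the design was genuinely open.

## Data model

A spectrum is a pair of equal-length arrays — strictly increasing
wavenumbers (cm⁻¹) and finite intensities (arbitrary units) — with at
least 8 points, plus metadata (analyte label, excitation wavelength,
replicate id, source path). Files are two-column CSV/TSV with an optional
header; rows are sorted on read and duplicate wavenumbers are rejected
rather than averaged, so instrument-export bugs surface immediately
instead of being silently smoothed over. Spectra from different
instruments are aligned by linear interpolation onto a common grid before
any matrix analysis.

## Preprocessing pipeline

Stages run in a fixed order per spectrum: **crop → despike → IARPLS →
Savitzky–Golay → min–max**. Cropping to the fingerprint window (default
closed interval [400, 1700] cm⁻¹) comes first so edge artifacts outside
the analysis range never influence the robust statistics of the despiker.

### Whittaker–Hayes despiking

The modified z-score of the first-differenced intensities,
z = 0.6745·(∇y − median)/MAD, flags candidate spike points: an up-jump
z > τ implicates the next point, a down-jump z < −τ the previous one
(default τ = 6, the conventional cutoff for modified z-scores). A cosmic
spike is a *narrow* artifact entered by an up-jump and left by a
down-jump, so a run of candidates is confirmed only when it is at most
`despike_window` points wide (default 5) and contains both jump
directions; runs at the array edge need only the inward-facing jump.
Without this narrowness condition the steep flanks of genuine Raman
bands — whose large differences all share one sign over a wide run —
would be clipped on low-noise spectra. Confirmed points are replaced by
the mean of non-flagged neighbours within the window; all other points
are bit-identical to the input. If the MAD is zero (constant
differences) nothing is scorable and the spectrum is returned unchanged.

### IARPLS baseline correction

The baseline z minimizes Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)ᵢ², with a natural
(unpadded) second-difference penalty; the pentadiagonal system is solved
by a banded Cholesky-style solver, so a 1301-point spectrum costs
microseconds per iteration. Weights follow the improved asymmetrically
reweighted rule: with d = y − z and σ = std of the negative residuals,

    u = exp(t)·(d − 2σ)/σ,   w = ½(1 − u/√(1+u²)),

an asymmetric algebraic sigmoid centered at 2σ that sharpens with the
iteration count t, driving peak points to weight 0 and sub-baseline
points to weight 1. Iteration stops when ‖w_new − w‖/‖w‖ < `iarpls_tol`
(default 10⁻³) or after `iarpls_max_iter` (default 50) rounds;
non-convergence is reported in the result, not raised, because the last
iterate is still a usable baseline. Degenerate inputs are handled
explicitly: with no negative residuals (e.g. the all-zero spectrum or an
exact polynomial of degree ≤ 1) the current iterate is already the
baseline and iteration stops.

Default λ = 10⁵ on a ~1 cm⁻¹ grid. On a known synthetic truth (linear
baseline of slope 0.02 cm⁻¹ under three Lorentzians of heights
1.0/0.6/0.3, FWHM 10 cm⁻¹) this recovers the baseline with RMSE ≈ 4·10⁻⁴
of the unit peak height and peak heights to within a fraction of a
percent — the "preserve the peaks, smooth the non-peaked areas"
behaviour the pipeline is built around. The estimated baseline is
equivariant under constant offsets of the input to well below 0.1% RMS.

### Denoising and scaling

Savitzky–Golay smoothing (default 9-point window, cubic) preserves peak
shape better than moving averages and reproduces polynomials up to its
order exactly. Min–max scaling maps each spectrum to [0, 1]
*per spectrum*, not per dataset, so spectra from different instruments
and integration times are comparable; constant spectra are rejected as a
validation error. Whether scaling happens before or after replicate
averaging is exposed by composing the stages manually; the packaged
pipeline scales each replicate.

## Windowed peak features

Peaks are strict local maxima with topographic prominence ≥ 0.02 (on the
0–1 scale; standard lowest-saddle definition via
`scipy.signal.find_peaks`). The fingerprint range is cut into 200 cm⁻¹
windows [400,600), [600,800), …, [1400,1600) with the final window
truncated and closed at [1600,1700], so every datum belongs to exactly
one window. Per window the three *highest-intensity* detected peaks are
kept — "highest" means intensity, not prominence, which serves only as
the detection filter — ordered by descending intensity with
equal-intensity ties going to the lower wavenumber, and emitted as
(position, intensity) pairs; missing slots are zero-filled. The layout
(7×3×2 = 42 values) depends only on the windowing parameters, never on
the spectrum. Positions are fed to the classifier in raw cm⁻¹: the
model is tree-based, so no scale harmonisation between position
(~10²–10³) and intensity (~1) features is needed. Peak width and area
features are deliberately out of scope.

## Random-Forest evaluation

The evaluation protocol is three stratified random 70/30 train/test
iterations (Monte-Carlo cross-validation). A per-class shuffled order is
cut into disjoint per-iteration test blocks of round(0.3·n_c) samples
whenever 3 blocks fit in the class; otherwise blocks are redrawn
independently. This follows the stated 70%/30% fractions rather than
standard 3-fold partitioning (whose test folds would be 1/3); a
conventional stratified k-fold plan is available as an alternative. Test
predictions are pooled into a single C×C confusion matrix; accuracy is
its trace over its total, and precision/recall/F1 are macro-averaged
(labelled as such, since a single unqualified percentage is ambiguous).
The forest uses 100 trees, unlimited depth and √p feature subsampling —
ordinary defaults, stated here because nothing in the analysis depends
on tuning them. All randomness (splits, per-iteration forests) derives
from one seed; the report, serialized with sorted keys and no
timestamps, is byte-identical across reruns.

## PCA and hierarchical clustering

PCA is an SVD of the column-centered data without unit-variance scaling:
the input spectra are already min–max scaled, and centering alone keeps
eigenvalues interpretable as variances on that intensity scale.
Component signs are fixed (largest-magnitude loading entry positive) so
results are deterministic; eigenvalues use the n−1 denominator so they
sum exactly to the total column variance. The default input is the
per-class average spectrum — replicate-level PCA is a flag — because the
exploratory question is how the *compounds* relate, not the replicates.

HCA uses dᵢⱼ = 1 − Pearson(rowᵢ, rowⱼ) and Ward's minimum-variance
criterion implemented as the Lance–Williams recurrence applied directly
to those dissimilarities (the `ward.D` convention of R's hclust; an
option applies it to squared dissimilarities instead, and (1−r)/2
scaling is likewise exposed, since correlation-based Ward is defined
only up to these conventions). Ward on non-Euclidean dissimilarities is
formally improper but standard practice in spectral chemometrics; the
result records the convention used. Merges are deterministic with ties
broken by the smallest node-id pair; the implementation was verified
against R's `hclust(method="ward.D")` and against a from-scratch
centroid-form oracle. Cutting at k removes the k−1 highest merges;
single/complete/average linkage delegate to scipy.

## Synthetic data generator

The generator emulates replicate powder measurements of the 14 library
compounds: each class contributes one peak per library position with a
Lorentzian kernel h·γ²/((ν−ν₀)²+γ²) (Gaussian and pseudo-Voigt are
options), on a 400–1700 cm⁻¹ grid at 1 cm⁻¹ steps. Base heights are
drawn per class — U(0.6, 1.0) for major, U(0.1, 0.5) for minor peaks —
and FWHM per peak from U(8, 15) cm⁻¹, typical solid-state band widths.
Replicates add position jitter N(0, 1.5 cm⁻¹) and multiplicative height
jitter (CV 0.1), a smooth baseline (random cubic polynomial or decaying
exponential, amplitude U(0.2, 0.8) of the peak scale, one family drawn
per spectrum, mimicking fluorescence), white noise N(0, 0.02), and with
probability 0.3 a single one-point cosmic spike of 5–20× the maximum
peak height. The spiked-extract mode adds a sharp dominant 521 cm⁻¹
silicon band (FWHM 6 cm⁻¹, 1.5–3× the analyte scale) and a broad
Gaussian band centered at 950 cm⁻¹, as seen when dried extracts are
measured on Si wafers. No numeric replicate noise level is available
for the reference instrument, so these defaults are declared
assumptions chosen to look like published replicate SD bands; every one
is config-exposed.

Streams are keyed by crc32 hashes of (seed, class) for archetypes and
(seed, class, replicate) for replicates, so datasets are reproducible
spectrum-by-spectrum and adding a class never perturbs existing spectra.

**What passing tests do and do not show.** The generator produces
Lorentzian bands at exactly the library positions with independent white
noise and smooth baselines. Real spectra have correlated noise,
instrument response functions, band overlap and shape asymmetry,
polymorphism and matrix effects. Perfect synthetic classification
therefore demonstrates that the pipeline is a faithful, lossless path
from well-formed fingerprints to identities — not that real-world
accuracy is 100%. Conversely the oracle tests (baseline recovery, spike
recovery, jitter propagation) are exact because the ground truth is
known by construction.

## Fingerprint library and conversions

The packaged library transcribes the 14 reference records: identity
(name, CAS, agrochemical and chemical class), molecular formula, and
major/minor peak positions with vibrational assignments kept as inert
annotations. Range entries such as 1424–32 are stored at their midpoint
with the span noted in the annotation, since matching and simulation
need single positions. Molar masses are computed at load from the
formula against a packaged IUPAC-2021 atomic-weight table (conventional
values where IUPAC gives intervals), so the µM → ppm conversions —
ppm = conc·M/1000 under the dilute-aqueous mg/L ≡ ppm assumption — are
independent of any transcribed mass. One source-table defect is handled
explicitly: the cypermethrin entry reuses ametoctradin's systematic
name, so the record's identity is resolved from its CAS number
(52315-07-8, C₂₂H₁₉Cl₂NO₃) and annotated. Chlorpyrifos is listed as the
diethyl-d10 isotopologue; the non-deuterated formula is used for mass
and the discrepancy annotated.

Library matching scores a query peak list against each record as
(2·concordance(majors) + concordance(minors))/3, where concordance is
the greedy one-to-one matched fraction within ±5 cm⁻¹ (each query-side
peak claims its nearest unmatched counterpart). Ties rank
alphabetically. This is a deliberately simple complement to the
classifier for single-spectrum lookup, not a replacement for it.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full chain on 14
classes × 25 replicates (350 spectra, ~1300 points each), which the
banded IARPLS solver processes in a couple of seconds; smaller replicate
counts are used where a test only needs the mechanism, not the
statistics. Tolerances throughout are stated in the tests themselves:
baseline conservation holds to machine precision, determinism is checked
byte-for-byte on serialized reports, and Monte-Carlo checks (permutation
null, jitter SD) use pooled binomial or moment intervals at 95%.

## Known limitations

* Binary instrument formats (SPC/WDF/JCAMP-DX) and confocal maps are not
  read; export to two-column text first.
* IARPLS assumes a near-uniform grid; strongly non-uniform axes should
  be regridded first.
* The despiker targets positive, narrow spikes; broad detector artifacts
  or negative glitches are out of scope.
* Ward-on-correlation is a convention, not a metric-space guarantee;
  cluster memberships can change under (1−r)/2 scaling or squared
  updates, which is why those are exposed.
* The classifier is only as transferable as the features: spectra from
  instruments with large calibration offsets (> a few cm⁻¹) should be
  wavenumber-calibrated before classification.
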