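# Methods

## Scope and model

`phytoraman` analyses Raman spectra time series of microalgal cultures
undergoing nitrogen starvation. The pipeline treats each acquisition as a
vector of intensities on a shared wavenumber axis (300–3100 cm⁻¹ at a
2 cm⁻¹ grid step by default, finer than the 10 cm⁻¹ instrument resolution so
that smoothing windows are meaningful) and assumes the observed signal is

    spectrum = Σ_bands band_profile(day amplitude) · (1 + jitter)
               + fluorescence background + white noise.

The generator, the pre-processing chain, the QC layer, the band kinetics,
and the PCA/Kruskal–Wallis phase analysis all operate on this structure.
Because no real culture spectra ship with the package, the synthetic
generator *is* the reference data source: every recovery claim the tests
make is a claim about this generative model, not about any particular
instrument.

## Synthetic data generator

**Bands.** Thirteen vibrational bands cover the molecules tracked in
microalgal monitoring: carbohydrate 479, phospholipid 865, chlorophyll 988,
carotenoids 1157/1524, and lipid bands 1444, 1660, 1750, 2850, 2885, 2940,
2970, 3008 cm⁻¹. Profiles are Gaussian by default (Lorentzian selectable);
at 10 cm⁻¹ instrument resolution the observed line shape is dominated by
the instrument function, and a Gaussian keeps closed-form checks simple.
Widths are 16–34 cm⁻¹ FWHM — narrow, resolved bands in the fingerprint
region and broad, strongly overlapping bands in the C–H stretch massif, as
in real algal spectra.

**Trajectories.** Amplitudes follow piecewise-linear day trajectories with
one breakpoint at the nitrogen-depletion day: pigments rise then decline
(`rise_fall`), storage-lipid and unsaturation bands (1660, 1750, 2940,
3008 cm⁻¹) are flat then rise (`flat_rise`), structural C–H bands are
near-constant. The carotenoid pair 1157/1524 keeps a fixed 0.8 amplitude
ratio, modelling a stable carotenoid composition. Defaults place the
depletion day at 6 for the 36-day lab scenario and 8 for the 14-day pilot
scenario, matching the physiological timing the scenarios emulate
(pigments accumulate during the first growth week; the pilot culture is
switched to nitrogen-free medium on day 8). Amplitudes span 0.1–3 in
arbitrary intensity units with the resonance-enhanced carotenoid 1524 band
the strongest, as observed in pigment-rich green microalgae.

A second band set, `step_bands`, replaces the smooth trajectories with a
single step at the depletion day. It produces the idealised "two separated
clusters" structure in score space and is used wherever a test needs an
unambiguous two-phase ground truth (QC block structure, PC1 phase
separation, breakpoint detection). The smooth default produces a
*continuous* trajectory through score space — day means of PC1 rise and
fall with the pigment amplitude — which is the more realistic but less
separable condition.

**Background and noise.** The fluorescence background is a quadratic
polynomial in the normalised axis coordinate plus a decaying exponential
(amplitude 4, decay 0.002 cm, i.e. an e-fold every 500 cm⁻¹), totalling
2–6 intensity units: broad, smooth, and comparable in magnitude to the
strongest bands, like chlorophyll autofluorescence under 532 nm
excitation. Additive white Gaussian noise (default sd 0.02) models shot
and detector noise; multiplicative per-spectrum scale jitter (default
sd 0.05) models focus and density fluctuations and is exactly the effect
SNV normalisation exists to remove. The generator does **not** model
cosmic-ray spikes, wavenumber miscalibration, detector nonlinearity or the
exposure-time switching of real instruments; pipeline robustness to those
artefacts is therefore untested.

All sampling uses one `numpy` generator seeded from the configuration, so
equal configurations produce bit-identical spectra.

## Pre-processing chain

Stages run in the order crop → baseline → smoothing → SNV, the order in
which standard vendor software applies them.

**Crop** keeps the fingerprint (350–1800 cm⁻¹) and C–H stretch
(2800–3050 cm⁻¹) ranges with inclusive endpoints. The two retained
segments remain one concatenated vector; downstream stages re-split on the
axis gap (a step larger than 10× the median step) and treat segments
independently — a convex hull spanning a 1000 cm⁻¹ hole would be
meaningless.

**Concave rubberband baseline.** Per segment and per iteration (default
64°, 10 iterations):

1. bend the working spectrum by subtracting
   `tan(angle) · A · (x−x₀)(x₁−x) / ((x₁−x₀)/2)²`, where A is the working
   spectrum's intensity range — pulling the interior down convexifies broad
   concave backgrounds;
2. take the lower convex hull of the bent points (monotone-chain
   algorithm);
3. interpolate the **un-bent** working spectrum linearly through the hull
   touch points and subtract that estimate.

The bend only *selects* the support points; the estimate itself contains
no bending term. This makes the iteration idempotent on noiseless data
(once the spectrum touches zero at the support points, subsequent passes
remove nothing) and reduces exactly to the classic lower-hull rubberband
as the angle goes to zero, which is how the implementation is verified
against a brute-force O(n²) convex-envelope oracle. The returned baseline
is re-derived as `input − corrected` so that `corrected + baseline`
reconstructs the input at machine precision. Hull-based baselines ride the
lower envelope of the noise, so the recovered background is biased low by
roughly the noise amplitude; at the default noise level the pooled RMS
error against the programmed background is ~4% of the maximum peak
amplitude.

**Savitzky–Golay smoothing**: two passes of a 25-point window. The
polynomial order is not fixed by convention in this chain; order 2 is the
standard chemometrics default and is exposed as a parameter. Interior
points use the closed-form convolution coefficients; edge points re-fit
the polynomial on the truncated one-sided window (degree reduced if the
window is shorter than the order requires), so output length equals input
length and polynomials up to the fit order are reproduced exactly
everywhere.

**SNV** standardises each spectrum to zero mean and unit sample variance
(n−1 denominator), computed jointly over all retained points rather than
per segment, so the fingerprint and C–H regions keep their relative
scale. Constant spectra are rejected as degenerate. After SNV all
intensities are dimensionless "SNV units" and may be negative; band ratios
remain meaningful because both bands share the per-spectrum scale.

## Quality control

Pearson correlations between all pairs of fully preprocessed spectra,
ordered by (day, session, replicate). Repeatability is the mean ± sd of
the m(m−1)/2 within-day pairwise correlations (self-pairs excluded — they
would bias the mean toward 1); similarity-to-reference is the mean ± sd of
cross-pairs against a chosen reference day (day 0 by default). For the
reference day itself the statistic reduces to its repeatability, making
the two series consistent. Sessions within a calendar day are pooled by
default (`pool_sessions=False` keeps them separate). Days with fewer than
two spectra report NaN rather than failing the aggregate. The map is
symmetrised and its diagonal pinned to exactly 1 so the symmetry and
unit-diagonal invariants hold at the bit level.

## Band kinetics

Band intensity is the maximum within ±8 cm⁻¹ of the assigned centre —
robust to calibration drift up to the half-window at 10 cm⁻¹ resolution;
trapezoidal area per cm⁻¹ over the window is available as an option.
Whether "intensity" means height or area is a genuine free choice in this
kind of chain; height was chosen as the default because it is exact on
noiseless isolated peaks, which gives the tests sharp oracles. Ratios
(unsaturation index 1660/1444, carotenoid ratio 1157/1524) are computed
per spectrum and then averaged per day, so per-spectrum common factors
cancel before aggregation; a zero denominator yields NaN, never a silent
infinity. Kinetic series report day mean ± sd with day counts.

## PCA and Kruskal–Wallis

PCA is a singular value decomposition of the column-mean-centred matrix —
centring only, since SNV already standardises rows. Explained fractions
are σᵢ²/Σσ² over all components; signs follow the convention that each
loading's largest-magnitude element is positive, making scores
reproducible across row permutations. Any component triple can be plotted;
the package does not privilege a particular 3-D view.

The Kruskal–Wallis statistic uses midranks for ties and the standard tie
correction `1 − Σ(t³−t)/(N³−N)`, with a χ²(k−1) upper-tail p-value. It is
applied to the first PC score with culture days as groups, over all
spectra rather than day summaries. The post-hoc procedure is a Dunn-type
z-test on mean-rank differences with the same tie term, Bonferroni-
corrected over the pairs actually compared — adjacent days by default
(the day-boundary scan, 13 pairs for 14 days), all pairs optionally. The
χ² approximation makes the test slightly conservative at 20 observations
per group; the Monte-Carlo calibration check accepts type-I error in
[0.03, 0.07] at α = 0.05 accordingly.

## Quantification

Pigment concentrations follow the standard methanol-extract formulas with
coefficients (−8.0962, 16.5169) for chlorophyll a, (27.4405, −12.1688) for
chlorophyll b and 4·A480 for total carotenoids, scaled by
extract volume / biomass volume (default 1.5 mL methanol). Turbidity
(A750) is subtracted from all three analytical channels, which makes the
outputs exactly invariant to a common absorbance offset. Negative outputs
(possible when absorbance ratios leave the formulas' domain) are returned
with a warning rather than rejected, since rejecting them would hide a
data-quality problem. Optical densities at or above 0.8 are outside the
spectrophotometer's linear range and flagged, not refused.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down schedules —
typically 14 days × 4 sessions × 10 spectra (560 spectra) instead of the
full 2800, and 200 spectra for baseline-recovery statistics — chosen so
the whole validation completes in a few minutes on one CPU while keeping
every statistic comfortably away from its threshold. Tolerances: SNV
standardisation and PCA orthonormality to 1e-12/1e-9, baseline
reconstruction exact at the float level, Savitzky–Golay polynomial
reproduction to 1e-9 relative, Monte-Carlo bands as stated above. Spectra
files store values with 12 significant digits, so read∘write round-trips
to ~1e-11 relative and metadata exactly.

## Known limitations

* The concave-rubberband iteration is a published-literature reconstruction
  of a proprietary vendor algorithm; parameter values (64°, 10 iterations)
  map to the bend-angle/iteration-count of this reconstruction, not
  necessarily to the vendor's internal scaling.
* Hull baselines under heavily overlapping band clusters (the C–H massif)
  interpolate across the cluster and can clip shared tails; peak fitting
  would do better there and is deliberately out of scope.
* Band intensities on SNV spectra are relative, not concentrations; no
  calibration against reference chemistry is attempted.
* The generator's two-phase physiology is a minimal piecewise-linear
  model; real cultures show smoother transitions, session-scale drift and
  occasional outlier spectra, none of which are emulated.
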