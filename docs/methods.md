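# Methods

## The screening problem

A liquid vaccine in a sealed glass vial is authenticated by the Raman
fingerprint of its excipients: the active ingredient is far too dilute to
observe, but the dominant excipients — sucrose, ethanol at ~880 cm⁻¹, and
the water matrix band at ~1640 cm⁻¹ — form a reproducible signature.
Falsified products are benign liquids (saline, glucose, mannitol solutions,
antibiotic injections, hyaluronic-acid serums) whose content spectra differ.
Sodium chloride contributes nothing: dissolved as Na⁺/Cl⁻ it has no
intramolecular vibrations, so a saline surrogate is spectroscopically
water-only.

The obstacle is the container.  Glass fluorescence, peaking near
675 cm⁻¹, dwarfs the content signal in a conventional backscatter
measurement.  Spatially offset Raman spectroscopy (SORS) acquires a second
spectrum with the collection zone displaced from the illumination spot;
photons collected there have, on average, travelled deeper, so the
offset acquisition carries a higher content-to-wall signal ratio.

## Two-layer forward model (synthetic data)

The generator treats each acquisition as a linear two-layer mixture:

    zero_offset = α_s·S + α_c·C + ε,      offset = β_s·S + β_c·C + ε',

where `S` is the wall (surface) signal, `C` the content signal, and the
SORS contrast is the invariant `β_c/β_s > α_c/α_s`.  Defaults are
α_s = 1, α_c = 0.2, β_s = 0.4, β_c = 0.3.  This is deliberately not a
photon-transport simulation: the linear mixing contract is exactly the
assumption the scaled-subtraction separation relies on, so it is the right
level of realism for validating that separation and everything downstream.

Component models:

* **Glass fluorescence** `S`: a wide Gaussian (FWHM 300 cm⁻¹, amplitude
  1000) centred at 675 cm⁻¹ plus a gentle linear tilt (10⁻⁵ of the
  amplitude per cm⁻¹, anchored at a fixed 2200 cm⁻¹ pivot so the profile is
  independent of the grid extent).  The tilt's slope is far below the
  Gaussian curvature at the peak (it moves the analytic maximum by
  ≈0.16 cm⁻¹), so the argmax stays at 675 on the 1 cm⁻¹ grid and the
  profile remains unimodal over the default 200–2000 cm⁻¹ range.
* **Content** `C`: sum of Gaussian bands per substance (Lorentzian
  available).  Water: one broad band, 1640 cm⁻¹, FWHM 90.  Ethanol:
  880 cm⁻¹, FWHM 20.  Sucrose: five bands at 835/1065/1130/1340/1460 cm⁻¹.
  L-histidine: two weak bands (it is essentially invisible through the
  vial).  Surrogate classes (glucose, mannitol, hyaluronic acid, amikacin,
  gentamicin) use literature-typical positions; saline and PBS are
  water-only.  **Band amplitudes are free parameters**: true formulation
  concentrations are not public, so the defaults were chosen once so that
  separated band heights sit clearly above the default noise floor — they
  encode no measured concentrations.
* **Noise**: channel-wise Gaussian with sd `σ·sqrt(max(signal, 1))`,
  σ = 0.2 by default — a shot-noise approximation appropriate for high
  photon counts and much simpler than Poisson sampling.
* **Replicate/batch structure**: six measurements per vial share one
  content realisation (multiplicative log-normal concentration jitter,
  sd 2%, drawn once per vial per substance) and differ only by noise;
  genuine vials cycle through six batch tags (emulating five batches from
  one production site plus one from a second), surrogates carry one tag.
  Batch tags never enter the signal model, which is what makes the
  batch-invariance null test meaningful.

All randomness flows from one explicit seed through a `SeedSequence`; there
is no hidden global state.

What the generator does **not** emulate: wavelength-dependent detector
response, cosmic-ray artefacts (except via the explicit outlier injector),
temperature drift, real excipient band shapes and relative intensities, or
any difference between production batches.  Passing tests therefore
demonstrate that the pipeline's algebra, statistics and bookkeeping are
correct under the stated model — not that real falsified products will be
detected at these rates.  On real data the 100% figures should be read as
"achievable when the content signatures differ clearly", as the synthetic
classes do by construction.

## Separation

`k` is estimated by least squares over the nulling window W = 650–700 cm⁻¹
(symmetric about the 675 cm⁻¹ fluorescence maximum):
`k = Σ_W o·z / Σ_W z²`.  Windowed least squares was preferred to the
point ratio at 675 cm⁻¹ because it is robust to noise (the point-ratio mode
is retained as an option, and an explicit `k` can be supplied to mimic
manual nulling).  When the content vanishes on W — true for every default
class, whose nearest band is the sucrose 835 cm⁻¹ line, >12 half-widths
away — the estimate equals the surface ratio β_s/α_s exactly, and the
subtracted spectrum is `(β_c − k·α_c)·C`, pure content up to a positive
factor.  Non-positive estimates are reported with a warning rather than
clipped: they indicate a mismatched or unphysical pair and should fail
loudly downstream, not be silently repaired.

The residual smooth background left by imperfect cancellation is removed by
a 5th-order polynomial inside the separation routine; background removal is
applied *again* after truncation in the preprocessing chain.  Both
applications are independently switchable (`poly_order=0` disables either).

## Preprocessing

Fixed order: truncate → polynomial detrend (per spectrum) → SNV (per
spectrum) → mean-centre (columns).  The order is enforced because SNV and
centering do not commute.  Details:

* Truncation bounds 760 and 1720 cm⁻¹, inclusive on both ends.
* Polynomial detrending defaults to the iterative modified-polyfit scheme:
  fit an order-5 polynomial, clip the working spectrum to
  `min(spectrum, fit)`, repeat until the maximum change falls below 10⁻⁶ of
  the input scale (cap 100 iterations).  The clipping stops genuine peaks
  from dragging the baseline upward, so band heights survive (recovered
  within 5% in the calibration test); plain least-squares subtraction is
  retained as a mode because it is the literal reading of "polynomial
  subtraction", and both modes annihilate an exact 5th-order polynomial.
  Fits use numpy's scaled/shifted polynomial basis (axis mapped to
  [−1, 1]) for conditioning; the contract is the least-squares fit, not
  the basis.
* SNV uses the n−1 standard-deviation denominator (stated so tests can be
  exact); a constant spectrum is a degenerate-input error, not a silent
  zero-division.
* Mean-centering is on by default; switching it off reproduces the variant
  used for single-population (e.g. degradation) inspections, where there is
  no second class to centre against.

## Chemometrics

**PCA** by SVD of the column-centered matrix; explained-variance ratios are
σ_i²/Σσ_j² over all singular values.  Each loading is oriented so its
largest-magnitude element is positive — an arbitrary but fixed sign
convention that makes score plots reproducible run to run.

**Confidence ellipses** in the PC1/PC2 plane use the sample mean and
covariance with the boundary at the χ² quantile with 2 degrees of freedom
(5.9915 at 95%, radius 2.4477 for unit covariance).  The population-χ² form
was chosen over the F-based Hotelling form because the difference is
negligible at the sample sizes screened here (tens of spectra per class);
the F form is available via `form="hotelling"` and is strictly wider at
small n.

**Outlier screening** fits a 3-component PCA model at 99% confidence
(screened on the genuine class before model building, mirroring the removal
of one anomalous spectrum from a reference set).  T² is the score
Mahalanobis distance with the F-distribution limit
`a(n−1)(n+1)/(n(n−a))·F_{a,n−a}`; Q is the squared reconstruction residual
with a moment-matched (Box) scaled-χ² limit computed from the discarded
eigenvalues.  A row is flagged iff either statistic exceeds its limit; on
clean multivariate-normal data the combined false-flag rate is the union of
two ~1% tests.

**PLS-DA** is NIPALS PLS1 on centered spectra against a centered 0/1 class
code (1 = falsified), with X and y deflation per component.  Components are
nested, so the k-component coefficient vector is recovered from one
max-component fit by solving the (P'W) triangular system — used to make the
inner model-size search cheap without changing any result (verified against
refits to 10⁻¹⁰).  At full rank the prediction equals ordinary least
squares.  The decision threshold is 0.5 on the predicted response; a
response exactly at threshold is called falsified — the conservative choice
for a screening tool, where a false alarm triggers confirmatory testing but
a miss releases a falsified product.

**Cross-validation** defaults to leave-one-vial-out: each fold holds out
all replicate measurements of one vial, so replicates never leak across the
train/test split (plain row-wise k-fold would overstate performance).
The number of latent variables, when not fixed, is chosen per outer fold by
an inner leave-one-vial-out search over 1–10 components minimising
misclassifications, ties resolved toward fewer components.  Sensitivity is
the percentage of falsified samples detected, specificity the percentage of
genuine samples passed.

A caveat on null experiments: leave-one-group-out estimates are biased
*below* chance under the null when groups are few, because holding out a
vial shifts the training class prevalence away from the held-out class.
The permutation-null check therefore uses stratified k-fold (prevalence
preserved in every fold), where chance-level means 50%; the batch-
invariance check keeps the vial grouping but uses a tolerant ±10-point
band.

## Problem sizes and numerical choices

The reference synthetic study is 10 vials × 6 replicates per class
(genuine vs one surrogate, 120 measurement pairs), matching the replicate
structure of a realistic vial survey at a size where the full pipeline —
separation, preprocessing, nested cross-validation — completes in well
under a minute; the nulls use 18 vials (batch) and 6 vials × 3 replicates ×
100 permutations.  Axes are matched across spectra by equality to
10⁻⁶ cm⁻¹; differing axes are linearly interpolated onto the first
spectrum's grid with a logged warning.  CSV round-trips write 17
significant digits and parse with the round-trip float parser, so matrices
survive write→read bit-identically.

## Known limitations

* The two-layer mixing weights are global constants per dataset; real
  instruments show vial-to-vial coupling variations that would spread the
  estimated k values more than the noise-only model does.
* Only one spatial offset is supported (pairwise subtraction); multi-offset
  inversion is out of scope.
* The JCAMP-DX reader covers the common AFFN `(X++(Y..Y))` and `(XY..XY)`
  tables only — no compressed (DIFDUP/SQZ) encodings.
* Chemical degradation of genuine product is not modelled; the
  no-centering preprocessing variant is provided, and the pipeline's null
  behaviour on a homogeneous set is tested, but detecting degradation is a
  different (and harder) problem than detecting substitution.
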