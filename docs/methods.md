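# Methods

## Contact mechanics and the fitting pipeline

A raw approach curve is a strictly increasing piezo ramp `z` (typically
2048 samples) with cantilever deflection `d`, in meters or in volts with a
mandatory unit flag (volts require a deflection sensitivity; the pipeline
never guesses units).  Internally everything is SI; kilopascals appear only
in reports.  Force is `F = k·d` and indentation past contact is
`δ = (z − z₀) − d`.

Two force laws are implemented, each linear in the Young's modulus E:

* Sneddon (pyramidal tip, half-angle α):
  `F = (2/π)·E/(1−ν²)·tan(α)·δ²`
* Hertz (spherical tip, radius R):
  `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`

The Sneddon prefactor is the canonical 2/π for a conical indenter; a
`prefactor_two_pi` switch preserves the literal 2π alternative for
sensitivity checks.  ν defaults to 0.3 everywhere and is overridable per
run.  The pyramidal half-angle defaults to 18°, typical of the sharp
silicon-nitride probe family used with 0.4 N/m levers; it is an explicit
configuration value, not a fitted quantity.

Per sample class the fit window and conventional hardware are:

| class        | model   | window | lever     | tip           |
|--------------|---------|--------|-----------|---------------|
| cell_2d      | Sneddon | 2 µm   | 0.4 N/m   | pyramid, 18°  |
| hsr_whole    | Hertz   | 5 µm   | 40 N/m    | sphere, 500 nm|
| cryosection  | Sneddon | 700 nm | 0.4 N/m   | pyramid, 18°  |

When the sample thickness is known and the deepest fitted indentation
exceeds a third of it, the fit is flagged `thickness_rule_violated` and
`apparent_modulus_Ea`: the number is then an apparent stiffness rather than
a strict elastic modulus.  With unknown thickness (whole-mount samples) the
fit carries an explicit "thickness unknown" note instead of a flag.

### Baseline, contact point and modulus estimation

1. **Baseline.** An OLS line through the first 30% of samples (the
   off-contact end) is subtracted from the deflection, recording the
   removed line in force units.  If the detected contact later implies that
   this window overlapped the contact region, the baseline is re-fitted on
   the region up to 90% of the detected contact and the estimation repeated
   once.

2. **Discrete contact search** (`find_contact_point`).  For each candidate
   index j the closed-form modulus `E = Σ F·g(δ) / Σ g(δ)²` (g the
   geometry term) is evaluated over the indentation window and the
   objective is the total squared force residual of {zero force before j}
   plus {model after j}.  Candidates run every 8th sample with exhaustive
   refinement within ±8 of the coarse optimum; ties break toward the
   smaller index, so the search is deterministic and reproducible against a
   brute-force enumeration of every index.

3. **Stiff-regime estimator.**  The discrete search minimises residuals in
   force versus *measured* indentation.  Because deflection noise enters
   the indentation axis (δ = z − z₀ − d), that residual's variance is
   inflated by (1 + E·g′/k)² wherever the contact stiffness E·g′ exceeds
   the lever stiffness k — the soft-lever-on-stiff-sample regime of
   cryosections, where the naive objective both misplaces the contact by
   hundreds of samples and biases E upward severalfold.  A second
   closed-form estimator therefore regresses z on d: past contact
   `z − d = z₀ + (k·d/(C·E))^{1/p}` is linear in `(z₀, E^{−1/p})` with
   noise amplification ≈ 1 in exactly that regime.  Samples qualify once
   their deflection clears 8 robust (MAD-based) SDs of the early-trace
   noise.

4. **Selection and polish.**  Both candidates are scored by the
   deflection-space residual — zero deflection before z₀, the
   forward-model deflection after — which is homoscedastic because the
   noise lives in the deflection channel.  The winner initialises a
   Nelder–Mead minimisation over continuous (z₀, log E); the forward model
   d(z; E) is evaluated by a vectorised Newton solve of
   `E·C·δ^p + k·δ = k·(z − z₀)` (convex and monotone, machine precision in
   a few steps, shared with the synthetic generator).  Exact fits
   (noiseless curves, relative SSR < 1e-26) skip the polish, so noiseless
   round-trips return the generating modulus to machine precision.  A
   deflection-space R² below 0.8 marks the pixel `poor_fit`; failed pixels
   are kept as invalid map entries, never dropped.

The polish and the stiff-regime estimator evaluate the model over the full
post-contact range rather than only inside the indentation window; the
window governs the discrete search, the reported diagnostics (deepest
indentation, point count, RMSE) and the thickness rule.  On homogeneous
synthetic samples the two ranges agree by construction; on layered real
samples the window is the guard against substrate contributions, which the
synthetic generator does not emulate (see limitations).

Contact-point precision is noise-limited, not algorithm-limited: at 2%
force noise on a soft-cell curve the deflection rises out of the noise
floor only tens of nanometers past contact, and the maximum-likelihood
contact scatters by roughly ±15 nm (≈ 10 samples at the default ramp)
around the truth with negligible bias.  The modulus is far less sensitive:
medians over ≥ 100 curves recover the generating value within ~3% in every
sample class.

## Calibration

Deflection sensitivity comes from a contact curve on a rigid substrate
(deflection in volts): sliding windows anchored at the pressed-in end are
fitted with lines, the longest window with R² ≥ 0.99 defines the contact
slope, and residual outliers (the kink at the contact point) are trimmed at
3 SD before inverting the slope into m/V.  The spring constant uses
time-domain equipartition, `k = β·k_B·T/var(d)` with β = 0.971, the
first-flexural-mode variance fraction of a rectangular cantilever; PSD
fitting, the Sader method and hydrodynamic corrections are out of scope.
Stiff levers shipped pre-calibrated bypass the thermal tune and take their
constant from metadata.

## Stiffness maps

A force volume (16×16 = 256 curves by convention, one per pixel) is fitted
pixel-wise into a modulus grid with a validity mask.  Region summaries
report median (headline statistic — robust to fit failures), mean and SD
over valid pixels; the even-count median is the mean of the central pair.
Rendering maps the per-image minimum to blue and maximum to red linearly
(a fixed range is available for cross-image comparability), paints invalid
pixels gray, and burns a scale bar sized from the pixel pitch into the
corner (its physical length is also stored in the PNG metadata).

## Morphometrics

Segmentation is Otsu or fixed thresholding, hole filling, 8-connected
labeling, and a minimum-area filter with relabeling to 1..K.  Descriptors
follow the Fiji conventions: area and perimeter in µm via the pixel size,
perimeter by the Crofton estimator (naive pixel-edge counting biases disk
circularity toward ~0.78), aspect ratio as the major/minor axis ratio of
the second-moment-matched ellipse, circularity = 4π·area/perimeter², and
solidity = area / convex-hull area.  Holes are filled before measuring
because margin undulation is an external-boundary concept.  Degenerate
objects (zero minor axis) are flagged, not fatal.  The tumor-area ratio is
|pigment ∧ body| / |body|.

## Two-group statistics

`compare_groups` runs Shapiro–Wilk on each group; if both pass at α = 0.05
it runs Levene (median-centered, the Brown–Forsythe variant and the R
default) and chooses the pooled-variance Student t-test, or Welch's t when
Levene rejects — the standard remedy, keeping the branch t-based since the
selection rule does not itself prescribe the heteroscedastic case.  If
either group fails normality the two-sided Wilcoxon rank-sum test is used:
exact null enumeration for tie-free samples with min(n) ≤ 12, otherwise
the normal approximation with continuity correction and midrank ties.
All tests are two-sided and unpaired (the compared conditions are
independent biological groups).  Stars: `***` p < 0.001, `**` p < 0.01,
`*` p < 0.05, `ns` otherwise, strict inequalities.  No multiple-testing
correction is applied across panels.

## Synthetic data

The generators define the study conditions and make every claim testable
against ground truth:

* **Curves/volumes** invert the forward model exactly (shared Newton
  solver), place contact exactly on a sample, overshoot the class window
  by 10% in depth, and add Gaussian force noise whose SD is a fraction of
  the peak force — default **0.02**, a free parameter of all recovery
  claims since no instrument noise floor is specified.  Optional linear
  baseline tilt and uniform contact-index jitter exercise the correction
  and search stages.  Scene truth maps and per-curve metadata make
  fixtures self-describing.
* **Thermal traces** are white Gaussian with variance β·k_B·T/k, so the
  β-corrected equipartition estimator recovers k in expectation.  Real
  thermal spectra are colored (Lorentzian modes); white noise is
  sufficient for a time-domain variance estimator and is the documented
  simplification.
* **Cell images** are non-overlapping moment-defined ellipses (optionally
  radius-perturbed by smooth Fourier modes scaled by a roughness knob in
  [0,1]) on a noisy background, with a truth table of area, aspect ratio,
  center and orientation.
* **Two-group samples** draw from normal, lognormal or exponential
  distributions reproducibly.

The packaged fixture `data/paper_moduli.yaml` pins the condition
stiffnesses used by the acceptance scenes: 4 kPa for normal melanocytes in
2D, 16,000/12,000 kPa for non-invasive/invasive skin-reconstruct sections,
and a two-fold 2D contrast whose absolute scale is arbitrary (1.5 kPa is
used for the invasive clone in the acceptance runs).

What passing tests show — and do not.  The generator emulates geometry,
noise level and stiffness contrasts, not instrument drift, adhesion,
viscoelastic creep, substrate stiffening under thin samples, or optical
artifacts in images.  Recovery within the stated tolerances therefore
validates the estimator chain under the stated noise model, not the
instrument-specific error budget of real measurements.

## Numerical choices and problem sizes

Deterministic throughout: fixed tie-breaks in the contact search,
seed-derived per-pixel RNG streams (SeedSequence spawning), derandomised
property tests.  Default test and acceptance problem sizes — 16×16 volumes
at 2048 samples/curve, 128-curve recovery batches, 2,000-replicate null
calibration, 100-cell image populations — were chosen as the smallest
sizes at which the Monte-Carlo error is comfortably below the tolerances
being asserted.

## Known limitations

* No viscoelastic, adhesive (JKR/DMT) or finite-thickness
  (Dimitriadis-type) corrections; the thickness rule only flags, it does
  not correct.
* The contact-point index is noise-limited on gently-rising curves (see
  above); downstream moduli are robust to this by design.
* Proprietary instrument formats are not parsed; data enter via the
  documented archive format.
* Morphometrics is 2D only; no stain deconvolution or colocalization.
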