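# Methods

This note records the models behind `protondqa`, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish about real measurements.

## Measurement model

A measurement is a 2D matrix of absorbed dose (Gy) in the beam's-eye-view
plane: +x left→right, +y in→out, origin on the beam axis at the grid's
geometric center. Pixels are uniform squares treated as point samples at
their centers; chamber-volume averaging is not modeled. The emulated
detector has a native pitch of 7.6 mm on a 32×32 lattice (extent
±117.8 mm); a 1 mm "vendor export" is produced by bilinear resampling
onto a symmetric lattice that always contains a pixel exactly at the
origin and never extrapolates beyond the outermost native centers.
Bilinear interpolation was chosen because it is exact on affine dose
fields and is the most conservative assumption about an unspecified
vendor export. Files use a plain ASCII dialect (`DQA-GRID v1`) with full
float precision, so write∘read is the identity.

## Test pattern and baselines

The daily plan delivers seven single-energy spots (80, 110, 140, 160,
180, 210, 240 MeV), a 10×10 cm² output square centered on the axis, and a
3×4 cm² range-check square, both sized at their 50% isodose lines. The
published description of this pattern fixes the energies and square
dimensions but not the spot coordinates, so the default layout here — a
row of spots at y = −80 mm spaced 30 mm apart, range square at
(−90, +60) mm — is a documented stand-in that keeps every element inside
the detector with ≥30 mm spot-to-square clearance. All geometry,
baselines and tolerances are overridable through one YAML config; the
packaged defaults are generated by code (`dqa config` writes them out).

Per-energy default spot sigmas fall from 6.5 mm (80 MeV) to 3.0 mm
(240 MeV), reflecting that higher-energy beams scatter less and arrive
sharper; these are simulator configuration, not physics claims. A
baseline is commissioned by measuring a session declared nominal and
copying its metrics (`baseline_from_session`), which makes every later
deviation a true constancy check: systematic sampling effects (penumbra
discretization, off-lattice spot centers) appear identically in baseline
and measurement and cancel.

## Metrics

* **Output**: mean dose over the central 3×3 cm² of the output square.
* **Range surrogate**: mean dose over a central 1×2 cm (x×y) window of the
  range square — chosen to stay well inside the 3×4 cm square's flat
  region; the averaging window is not fixed by any reference. The dose
  deviation (%) divides by the sensitivity *s* (default 12 %/mm,
  configurable; the value is a stated scale, not a calibration) to give an
  inferred range shift in mm, positive = range increase = dose increase.
  This linearization deliberately has no depth-dose model, and it cannot
  separate a true range shift from a simultaneous output change — the
  output check exists to disambiguate.
* **Flatness/symmetry**: evaluated on the two central-axis profiles over
  the central 80% of the nominal field size (penumbra excluded, the
  conventional flattened region). Symmetry takes the *worst* mirrored
  pair at 1 mm steps (linear interpolation), the conservative reading of
  "sampled doses"; both metrics are scale-invariant by construction.
  They are compared to baseline as signed differences (constancy), with
  the absolute-magnitude reading available via the tolerance config.
* **Field size**: distance between the two 50% crossings, each located by
  linear interpolation between the straddling samples. The reference
  level is half the dose at the sample nearest the field center — not
  half the profile maximum — so a noise spike cannot shrink the field.
  At 7.6 mm pitch with a 4 mm penumbra this locator lands within ~0.5 mm
  of truth (measured: 100.54 mm for the 100 mm square, 30.09 mm for the
  30 mm square), comfortably inside the ±2 mm clinical tolerance;
  sub-half-millimeter accuracy is not claimable at this pitch.

## Spot fitting

Each spot is cut out with an ROI of half-width max(3·baseline σ, 20 mm)
about its nominal position and fitted with the five-parameter Gaussian by
trust-region least squares (analytic Jacobian, σ bounded positive,
iteration cap 200, tolerances 1e−10; |σ| reported). Initialization uses
intensity-weighted moments. The model has no offset term; a constant
background is removed beforehand by subtracting the median of the four
ROI corner pixels. The corners sit ≥4σ from the spot where the Gaussian
is negligible, so a detector pedestal cancels without eating tail dose —
a border-wide median would include midpoints at ~3σ that still carry a
few percent of the amplitude and would bias σ̂ low by ~7% for the widest
spot. Solver trouble surfaces as `converged=False` with a reason, never
an exception; `rss` is reported so callers can gate on fit quality
(asymmetric or non-Gaussian spots are fitted anyway, with no skew model).

Fits run on the native-pitch samples. Resampling to 1 mm before fitting
is supported (`resample_to_mm=`) but off by default: bilinear
interpolation flattens the Gaussian's curvature between 7.6 mm samples
and inflates fitted σ by 10–20%, which would swamp the 10% spot-size
tolerance when compared against ground truth. (In a pure
baseline-relative workflow that bias cancels, which is why interpolated
exports are usable clinically; parameter recovery is what the default
optimizes.) Measured on the native grid, the 95th-percentile relative σ
error over 500 seeded replicates is ≈2% for a 6 mm spot under 2%
multiplicative noise and ≈0.4% for a 3 mm spot under 1% noise — both far
inside the 10% tolerance, confirming the pitch is adequate for daily
spot-size constancy.

## Classification and sessions

A deviation *d* with thresholds (warn, fail) classifies as pass if
|d| < warn, warning if warn ≤ |d| < fail, fail if |d| ≥ fail — boundaries
inclusive upward, so a tolerance quoted "±3%" passes strictly inside.
Defaults: output and range-dose surrogate 3%/5%; inferred range shift
1 mm; spot position 1.0/1.5 mm (the 1 mm/2 mm plotting zones seen in
trending figures are a looser alternative profile; the tolerance table is
normative); spot size 10%; flatness, symmetry 2%; field size 2 mm; the
redundant monitor-chamber reading (IC2) 2%. IC2 cannot be computed from
the dose grid (it is accelerator-internal) and is accepted as an
operator-entered percent deviation. A session bundles the
operator-entered safety/interlock and image-guidance booleans with the
computed checks; overall status is the worst check status, and any false
boolean forces fail. Per-metric computation errors become fail-status
checks carrying the reason, so a session never silently drops a check.
Reports serialize to deterministic JSON with input digest and config
digest for provenance.

## Trending

Deviations append to a CSV store keyed uniquely by (date, room, metric);
rows are immutable. Monthly summaries use quartiles by linear
interpolation of order statistics and whiskers drawn at the exact Tukey
fences q25 − 1.5·IQR and q75 + 1.5·IQR (a documented divergence from
plotting conventions that clip whiskers to the most extreme inlier);
values outside the fences are listed as outliers. Drift is ordinary least
squares of deviation against days since window start, scaled to percent
per month by 30.4375 days/month (mean Gregorian month — "per month" is
otherwise ambiguous), with standard error and 95% CI on n−2 degrees of
freedom (n ≥ 3 required). An alert needs both |slope| ≥ threshold and a
CI excluding zero, so a short noisy series cannot alarm on magnitude
alone.

## Simulator

The simulator is the package's test bed: the ideal pattern dose is the
sum of the seven Gaussians plus two squares modeled as separable products
of Gaussian-convolved step edges (edge width 4 mm), which puts exactly
half the plateau at the nominal edge — anchoring field-size recovery.
The squares are not built from individual scanned spots; the analysis
never needs intra-field spot structure. Injectable truth: a global output
scale (nominal 1.0), a range shift in mm applied to the range square as
1 + s·Δr/100, per-energy spot offsets and σ scales, a global setup shift
of the whole pattern, and multiplicative i.i.d. Gaussian noise (sd as %
of local dose, matching how array noise levels are quoted; no spatial
correlation). Sampling is seeded and reproducible; daily series derive
per-day substreams from one seed. Default spot amplitude is 0.5 Gy —
arbitrary, since absolute spot dose is never a metric.

The master property is pipeline closure: on noiseless simulations,
analysis recovers injected output scale within 0.5%, spot offsets within
0.2 mm, σ scales within 3%, and range shifts within 0.1 mm, with
deviations measured against a baseline commissioned from a nominal
simulation — exactly the clinical workflow.

What passing these tests does *not* show: real spots are slightly
asymmetric and non-Gaussian (a known source of one-sided position/size
bias), detector noise is spatially correlated and the chamber has finite
volume, low-energy spots scatter in air and detector, and the range-dose
relation is only locally linear. The simulator reproduces none of these;
it establishes that the analysis chain is correct, not that the machine
model is complete.

## Problem sizes and runtime

Defaults were chosen so everything runs in seconds on one CPU: one
session is a 32×32 grid and seven 5-parameter fits (~15 ms); the noise
studies use 500 replicates of a 9×9-pixel spot; trend demonstrations use
120–180 daily sessions; the regression-coverage property uses 500
replicates of 20-point series. These sizes are statements of what the
checks need, not of what the code can handle.
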