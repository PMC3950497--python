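# Methods

This note records the models, decision rules, numerical choices and
known limitations behind `srmpk`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from memory.

## The assay being modelled

A scheduled selected-reaction-monitoring (SRM) assay quantifies
stepharine in rabbit plasma by monitoring three transitions of the
protonated precursor (m/z 298.4 → 161.2, 192.1, 238.2) inside a
retention-time window of 11.6 ± 0.3 min. The m/z 161.2 fragment is the
most abundant and serves as quantifier; the other two confirm identity
through their area ratios to the quantifier. Calibration spans
0.1 ng/mL to 100 µg/mL (five orders of magnitude, seven standards in a
1:10 ladder). Canonical units throughout the package are minutes,
ng/mL and mg; all conversions happen at the I/O boundary.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
so that every downstream stage is testable without instrument data.

* **Chromatograms.** Each injection produces three traces on a shared
  grid (default 0.01 min sampling) spanning the scheduled window plus a
  0.3 min peak-free pad used for noise estimation. The elution profile
  is a symmetric Gaussian (σ = 0.05 min by default); peak shape is not
  dictated by the assay description, and an exponentially-modified
  Gaussian is available behind `peak_shape="emg"` for robustness
  testing, not as default. Before noise, the quantifier area equals
  `response_slope × concentration` (default 2000 area units per ng/mL)
  and qualifiers are scaled by the fixed transition fractions
  (1.0, 0.45, 0.25). Baseline noise is additive white Gaussian with
  configurable RMS (default 5); the retention time jitters run-to-run
  with SD 0.03 min.
* **Calibration series.** Replicate-to-replicate variation multiplies
  the effective concentration by a unit-mean lognormal factor with the
  configured CV, making the per-level area SD proportional to the mean —
  the heteroscedastic pattern that motivates 1/x weighting.
* **Plasma profiles.** The noiseless mean follows the piecewise
  first-order model C₀(1 − e^(−K₁t)) for t ≤ T_max and C₀e^(−K_el·t)
  for t > T_max, with multiplicative lognormal measurement noise
  (default CV 5%, matching the scale-proportional SDs of the study
  table). The piecewise form is generally *discontinuous* at T_max; the
  generator emits it exactly as defined, because the closed-form AUC
  below integrates exactly this form. A continuous (Bateman-type)
  alternative was deliberately not substituted.
* **Default study conditions.** Six animals sampled at 0, 15, 30, 60,
  90, 120, 180, 480, 720 and 1440 min after a 0.45–0.50 mg intramuscular
  dose; five parameter sets follow the published per-animal fits
  (K_el 0.005–0.007 min⁻¹, K₁ 0.01–0.025 min⁻¹, T_max 90 min, C₀
  10.6–22.5 ng/mL) and the animal whose terminal phase was never
  characterised in print is completed with mid-range values
  (K₁ = 0.02, K_el = 0.006, C₀ = 15) so a full batch can be generated.
* Every generator takes an explicit seed; batch generation derives one
  child seed per animal/stage via hashing, so runs are reproducible as
  a whole and component-wise.

What the generator does *not* emulate: ion-source physics, isotope
patterns, retention drift within a batch, co-eluting interferences,
carryover, or between-day response drift. Passing tests therefore show
the *data analysis* is correct under the assay's stated statistical
assumptions, not that any particular instrument meets them.

## Peak processing

Baseline and noise are estimated on a flanking, peak-free region: the
baseline is the median intensity (robust to single-point spikes) and
noise is the root-mean-square deviation about it, the "RMS algorithm"
convention for SNR. The apex is the maximum baseline-subtracted
intensity inside the scheduled window (ties break to the earliest
time); bounds extend from the apex to the first valley or baseline
crossing on each side; the area is the trapezoidal integral of the
baseline-subtracted signal between the bounds, floored at zero
point-wise. SNR = apex height / RMS noise; a zero-noise estimate with
signal present reports +inf with a warning rather than failing. Peaks
below 3×RMS are not reported — the assay's published rules give only
the SNR > 7 detection-limit criterion, so the 3×RMS reporting floor is
this package's choice (a conventional one). No smoothing is applied by
default: smoothing changes areas, and a scheduled window makes it
unnecessary. On noiseless simulated peaks sampled at ≥10 points per σ,
integration recovers the analytic Gaussian area within 2% (tested).

The exact placement of the vendor software's noise region is unknown;
the leading-flank convention here is explicit and configurable.

## Calibration

The response model is area = slope·conc + intercept, fitted by weighted
least squares (statsmodels WLS) with weights 1, 1/x or 1/x² (default
1/x). The curve is fitted to per-replicate points by default; a
level-means mode exists because the assay description is ambiguous
about aggregation. Published replicate counts vary between sections
(3, 5 and 10); the replicate count is therefore a configuration
parameter, defaulting to 5.

Acceptance rules: a level enters the fit only with mean SNR > 7.0
(strict, "more than") and replicate RSD < 15%; excluded levels are
recorded with reasons, and accepted + excluded always partitions the
input (tested). LOD is the lowest level passing the SNR rule alone —a
level too imprecise to *fit* can still set the detection limit — and
LLOQ additionally requires RSD ≤ 15% (boundary inclusive). RSD uses the
sample (n−1) standard deviation. Fed the published per-level summaries
(SNR 8 with RSD > 27% at 0.1 ng/mL; SNR 16.7 with RSD ≈ 2.4% at
1 ng/mL), the rule reproduces the published decision: detection at
0.1 ng/mL, quantitation at 1 ng/mL.

r² is reported as the weighted Pearson correlation squared on the
fitted model; an unweighted r² of back-calculated versus nominal
concentration is emitted alongside, since which definition the original
software printed is not stated. Heteroscedasticity is assessed by the
variance ratio of the highest to lowest calibrator with an F-test at
α = 0.05. Back-calculation is (area − intercept)/slope with flags
rather than errors: negative raw values report 0, values below LLOQ are
flagged `below-LLOQ`, below LOD `not-detected`.

## Validation metrics

* **Matrix factor** is implemented exactly as the printed formula
  f = 100·(A_add − A_end)/A_aq, which evaluates to ≈100 for a matrix
  with *no* effect. Because the stated acceptance ("15%") can only
  refer to deviation from unity, the accepted/rejected boolean always
  tests 100·((A_add − A_end) − A_aq)/A_aq, and a `mode` switch lets the
  report carry either scale, labelled. This is the one place where the
  printed formula and the printed acceptance rule cannot both be taken
  literally; the package keeps the formula and interprets the rule.
* **Recovery** is 100·C_m/C_a per spike level (3, 50, 100 ng/mL), with
  per-level means and a grand mean across levels, each level weighted
  equally.
* **Selectivity** compares the worst blank-matrix response against the
  summed LOD + LLOQ responses with a strict < 20% rule ("summarized
  response" is read as a sum); the conventional blank-vs-LLOQ-only mode
  is available and labelled as the non-default alternative.
* **Freeze–thaw stability** is percent loss versus fresh standards,
  accepted at loss ≤ 10%.

## Pharmacokinetics

C_max and T_max are the observed values (ties to the earliest time).
K_el is the negative slope of ln(conc) on time over the terminal
points; the default selection rule is *all points strictly after the
observed T_max with positive concentration, minimum 3*. The rule is
explicit and configurable because "final portion" admits many point
selections, and the published per-animal K_el values are not exactly
reproducible from the published concentrations under any obvious rule —
the package reports its rule rather than tuning toward printed values.
Zero concentrations (t = 0 and t = 1440 min) are excluded from the log
fit (log undefined) but retained for the trapezoidal AUC. With fewer
than 3 eligible points the result carries an
`insufficient-terminal-points` flag and no K_el, T_1/2, C₀ or model
AUC — matching how the sparsely sampled animal is reported in the study
(its post-peak phase has a single measurable point).

T_1/2 = ln 2/K_el. AUC uses the linear trapezoid over observed points,
extrapolated to infinity as C_last/K_el. The model AUC is the closed
form of the piecewise model integrated from t_start = 15 min (the first
post-dose sample) to infinity; it matches numerical quadrature of the
piecewise model to 10⁻⁶ relative error across a grid of K₁, K_el ∈
[10⁻³, 10⁻¹] min⁻¹ and T_max ∈ [30, 180] min (tested). Clearance is
dose/AUC with the mg→ng conversion applied inside that function only.

The absorption constant K₁ is estimated by profiling the rising-phase
plateau: for each candidate plateau Ĉ the through-origin regression of
ln(1 − conc/Ĉ) on time gives K₁ in closed form, and Ĉ is chosen to
minimise the concentration-space SSE with a bounded scalar search
(the original software's procedure for C₀ and K₁ is unstated, so this
estimator is the package's own). A labelled nonlinear polish
(`refine=True`) exists but is not default. On noiseless simulated
profiles all four parameters are recovered within 1%; at 5% measurement
CV the median relative K_el error over 100 seeds is below 15% and its
mean bias below 5% (both tested).

C₀ in reports is the terminal-fit extrapolated intercept by default;
externally fitted parameters (e.g. from other software) can be supplied
as overrides and then drive the closed-form AUC and clearance. Reports
store full precision; any rounding (integer minutes, one decimal on
AUC) is display-only.

Two printed rows of the study's parameter table are internally
inconsistent: one animal's AUC (2769) disagrees with the closed form
evaluated at its own printed parameters (≈2151), and the low end of the
printed clearance range disagrees with dose/AUC for the first animal.
The acceptance computations therefore cover the three self-consistent
animals only; the discrepant rows are carried in the data fixture
unchanged.

## Pipeline and reproducibility

`run_simulate` writes a complete batch (5 blanks, 7 × 5 calibrants, QC
at 3/50/100 ng/mL, 6 × 10 study samples) plus a truth table of
generating values; `run_full` executes quantify → calibrate → validate
→ quantitate → PK, writing one CSV per stage and a `summary.json` with
the seed, a SHA-256 config hash and validation verdicts. Strict mode
turns any failed validation rule into a failing exit status; permissive
mode (default) reports without aborting. Identical config + seed yields
byte-identical outputs (chromatogram CSVs are written with 17
significant digits and read with the round-trip float parser precisely
so this holds).

Problem sizes were chosen for desk-scale work: ~330 traces of ~120
points per batch and 100-seed recovery simulations, which keep the full
test suite and pipeline in the seconds-to-a-minute range on one CPU.

## Known limitations

* The piecewise PK model is discontinuous at T_max; its closed-form AUC
  is faithful to that form, not to a continuous absorption model.
* Peak detection assumes a single analyte peak inside the scheduled
  window; co-eluting peaks are not deconvolved and cross-run alignment
  is out of scope.
* mzML support is read-only and limited to chromatogram entries with
  isolation-window metadata (or Q1/Q3 encoded in the chromatogram id);
  spectra and vendor-raw formats are not handled.
* The matrix-effect scale ambiguity described above is resolved by
  policy, not by data; both scales are reported.
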