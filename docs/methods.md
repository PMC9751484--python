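# Methods

This note records the models, conventions and parameter choices behind
`teadtc`, in the order the pipeline runs them, together with what the
synthetic data generator does and does not emulate.

## Cube calibration and spectrum extraction

Reflectance is recovered per pixel and band as `R = (DN − dark)/(white −
dark)` from full-frame white-board and dark-background reference cubes, then
clipped to [0, 1]; raw pixels brighter than the white board are clipped, not
treated as errors, since the downstream analysis assumes reflectance in the
unit interval. A coincident white and dark value anywhere is a hard error
that names the offending (row, col, band).

Canopy segmentation is an NDVI threshold: a pixel is canopy iff
`(NIR − red)/(NIR + red) > 0.5` at the bands nearest 670 nm and 800 nm.
Wavelength lookup is nearest-band with equidistant ties resolved toward the
lower index; no spectral interpolation is performed. The manual, GUI-driven
masking that produced the original canopy masks is not reproducible in code;
a vegetation-index threshold is the standard automated replacement and its
accuracy against known masks is part of the test suite. The per-sample
spectrum is the unweighted per-band mean over canopy pixels.

ENVI I/O supports the classic ASCII `.hdr` + raw binary layout,
band-sequential interleave, little-endian, data types 4 (float32) and 12
(uint16). Cube dimensions are always taken from the header, never assumed.

## The drought tolerance coefficient

Indicator orientation is biology-given: MDA and SS rise with stress, TP
falls. Range normalization is computed jointly over **all** samples (not per
stage or cultivar), producing columns in [0, 1] oriented stress-positive.
CRITIC uses the sample (n−1) standard deviation as contrast and Pearson
correlation on the normalized columns for conflict; the canonical definitions
are used since the method is named but not printed in most applied reports.

One inconsistency deserves a note: with stress-positive orientation the
weighted composite *rises* with stress, yet applied reports habitually read
"higher composite = more tolerant" while simultaneously ranking cultivars by
counts of samples *below* the overall mean. Both cannot hold. This package
keeps the computation exactly as defined (stress-oriented), exposes
`tolerance_oriented=True` on `DroughtToleranceScorer` for the complement
`1 − DTC` (the CRITIC weights are invariant under flipping every column, so
the two conventions are exact complements), and documents ranking semantics
on `rank_varieties`: few samples beyond the overall mean ⇒ drought tolerant.

Percentages in the ranking table are rounded half-up to two decimals for
report parity. `relative_difference` exposes both denominator conventions
(divide by the smaller or the larger value) because published comparisons mix
them.

## Spectral pretreatments

* **SNV**: per-spectrum centring and scaling by the sample (m−1) standard
  deviation; constant spectra are an error.
* **MSC**: each spectrum is OLS-regressed on a reference spectrum; corrected
  = (x − intercept)/slope. The reference defaults to the *training-set* mean
  and is frozen at fit time, so held-out samples are corrected against the
  training reference — no leakage. |slope| < 1e−12 is a degenerate-fit error.
* **Savitzky–Golay**: polynomial order defaults to 2 (the classic choice);
  the first and last (window−1)/2 points pass through unchanged rather than
  being extrapolated, so the band count is preserved for downstream selection.
* **Derivatives**: forward first difference over Δλ (m−1 points, midpoint
  axis) and central second difference over Δλ² (m−2 points, trimmed axis).
  Physical nm spacing is used in the denominator; this is a pure rescaling
  that cannot change model rankings. Axis bookkeeping is explicit so selected
  bands always map back to nm.

Chains compose scatter → derivative → smoothing, at most one step of each,
written `[MSC|SNV|none]-[1D|2D|none]-[SG(w[,p])|none]`. The order follows the
convention of pretreatment tables in the applied literature; smoothing after
differencing is unusual in chemometrics but is the composition those tables
name, and the chain class makes the order explicit rather than silent.

## Wavelength selection

All three selectors share a mean-centred (never unit-scaled) SIMPLS engine
with the latent-variable count capped at 10 and chosen by minimum
cross-validated RMSE. Ties in |coefficient| or residual norm break toward the
lower band index, making runs reproducible; each selector is deterministic
under a fixed `random_state`.

* **UVE** appends an artificial noise block of the same width as X, uniform
  on [0, 1] scaled to 1e−10 of X's mean magnitude — small enough to leave the
  fit untouched while still yielding a stability distribution. Coefficient
  vectors are collected over leave-one-out folds; stability is mean/sd per
  variable; real bands survive iff |stability| exceeds `cutoff_factor` (default
  1.0) times the best noise stability. Raising the cutoff never enlarges the
  selection.
* **CARS** runs 50 Monte-Carlo iterations at 80% sampling. The retained
  fraction follows the exponentially decreasing function with endpoints 1 and
  2/p; each iteration forces removal to the top coefficients, thins by
  weighted resampling, and records a 5-fold RMSECV of the new pool. The pool
  is clamped at 2 bands minimum (recorded in diagnostics); the minimum-RMSECV
  pool wins.
* **SPA** tries every column as a chain start (restrictable via `starts`),
  growing each chain by the unselected column of maximal residual norm after
  projection onto the orthogonal complement of the chosen span — collinear
  bands therefore never co-occur; numerically rank-deficient chains truncate.
  Every (start, prefix) subset is scored by held-out RMSE of an
  intercept-plus-OLS fit on a 25% validation fraction; ties prefer fewer
  bands, then the lower start.

Selection runs on training rows only by default (`selection_scope='train'`),
with `'all'` available to mimic full-data selection.

## Modeling and evaluation

The 3:1 split is a uniformly random permutation (280 → 210/70); a
stratified-by-variety option is not currently needed by any consumer and was
left out. Hyperparameters are tuned by 5-fold CV on training rows only:
PLSR over 1..min(15, p, n−1) latent variables; SVR with RBF kernel,
C ∈ {0.1, 1, 10, 100}, gamma ∈ scale-heuristic × {0.1, 1, 10}, ε = 0.01;
random forest with 500 trees and max_features ∈ {√p, p/3}. All randomness
(split, folds, forests, selectors) flows from one pipeline seed through named
substreams.

R² is reported as 1 − SSres/SStot — the only form for which negative held-out
values are meaningful — with the explained-variance ratio form available via
`r2_form='explained'`. MAPE is reported in percent and is undefined when the
response contains zeros, which matters at exactly zero synthetic noise (the
least-stressed sample's composite is exactly 0 under joint range
normalization); recovery-limit analyses therefore scale noise by 1e−6 instead
of zeroing it. Grid failures are recorded as rows, not raised, so one
degenerate cell cannot kill a sweep; rows sort by descending test R², then
ascending RMSE and MAPE.

## The synthetic generator

The generator emulates the *statistical structure* the analysis assumes, not
tea optics. Each of 7 occasions carries a base stress level
(0.10, 0.30, 0.50, 0.75, 0.85 over the drought days, 0.45, 0.20 after
rehydration), mirrored by a soil-moisture trajectory (80 − 65·stress, %).
Cultivar tolerance τ ∈ [0, 1] attenuates experienced severity:
s = base·(1 − 0.5τ). Indicator means follow the field's trend shapes —
MDA/SS unimodal `baseline + amplitude·s·(1 − s⁶)` (peaking between the
day-13 and day-17 stress levels), TP linear `baseline·(1 − 0.65·s)` — with
baselines/amplitudes (8.8 + 22·f for MDA, 14 + 48·f for SS, 5.5 for TP)
and replicate noise sds (0.7, 1.5, 0.35) chosen so that ranges and standard
errors match published greenhouse magnitudes. The unimodal exponent 6 and the
0.85 stress ceiling were fixed by evaluating the closed-form means once at
design time so that (a) every cultivar's MDA/SS peak falls on the day-13 or
day-17 occasion and (b) the composite is strictly monotone in tolerance.

Spectra are a smooth vegetation template (visible plateau at 0.05, green bump
at 550 nm, red edge at 715 nm, NIR plateau at 0.45) plus a severity effect:
visible reflectance up to +0.10, NIR down to −0.12. Each sample is distorted
by a multiplicative gain ~ 1 + N(0, 0.15) and additive offset ~ N(0, 0.05) —
set strong enough that scatter correction demonstrably improves held-out
accuracy, which is the scenario the pretreatment stage exists for — plus
white noise (sd 0.004), then clipped to [0, 1]. A single integer seed expands
into independent substreams for physiology noise, scatter and spectral noise,
so toggling one source leaves the others' draws unchanged.

`generate_cube` embeds a known reflectance field (centred canopy blob with
the severity-dependent plant spectrum, flat 0.15 background) between known
white/dark references, so calibration, segmentation and averaging can be
tested against exact ground truth.

What this does **not** emulate: radiative transfer (no PROSPECT/SAIL), 3-D
canopy geometry, instrument smile/keystone, correlated (pink) spectral noise,
or indicator dynamics beyond the trend shapes. Consequently, passing tests
demonstrate that the pipeline recovers structure it is designed to recover —
they do not certify accuracy on real acquisitions. Two visible consequences:
the three synthetic indicators are more correlated than real assays (all are
driven by one latent severity), so their CRITIC information contents are
smaller than replicate-level published values even though the weight shares
remain comparable; and second-derivative chains, which performed well in the
published study, lose signal here because white noise at 1.667 nm spacing is
amplified by the 1/Δλ² second difference — which pretreatment chain wins is
data-dependent.

## Known limitations

* The published per-sample dataset is not deposited; validation against it is
  limited to worked arithmetic on the printed summary tables and a CRITIC/DTC
  recomputation from per-stage means, which agrees with the replicate-level
  values only to within ~10%.
* UVE stability with small fold counts is noisy; the default is leave-one-out,
  and k-fold UVE can eliminate every band (raised as an explicit error).
* SPA cost grows as starts × chain length × bands; on 360 bands with all
  starts it is seconds, but very wide matrices should restrict `starts`.
* Reported problem sizes in the test-suite recovery checks (compact grid
  menus, 10 seeds, 120-band designs in property tests) were chosen to keep
  the suite fast while exercising the full 280 × 360 layout where the claim
  depends on it (the full-grid and recovery criteria).
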