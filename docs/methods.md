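# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `atflow`, in the order data flows through the package.

## Dose-response model

The assay rests on the Heidelberger–Kendall precipitin picture: as antigen
concentration rises at fixed antibody load, the extent of particle
immunoagglutination increases (antibody excess), peaks at the equivalence
point, and falls again when excess antigen saturates binding sites and
prevents crosslinking (antigen excess / prozone). The package models the
relative agglutination extent as a **Gaussian in log₁₀ concentration**,

    E(c) = exp(−(log₁₀ c − log₁₀ c_eq)² / (2 s²)),  E(0) = 0,

a deliberately minimal two-parameter form (peak location `c_eq`, width `s`
in decades) that reproduces the qualitative increasing/plateau/decreasing
shape. The flow-velocity response is **piecewise semi-log**: below the
equivalence point `v(c) = b + m·log₁₀ c` (the empirically observed linear
range), above it the velocity declines at `decline_factor × m` per decade,
continuous at `c_eq`. The decline slope is not empirically constrained;
0.5 is a plausible default and only the *existence* of the decline is load-
bearing for the zone classifier.

Default ground truth: `m = 0.540` px/frame per decade, `b = 0.040` px/frame
(diluted-plasma assay), `c_eq = 19` ng/mL, `s = 1` decade, homoscedastic
replicate noise `σ_v = 0.02` px/frame. The PBS preset (`m = 0.136`,
`b = 0.575`) places `c_eq` at 100 ng/mL, far above its tested range, because
buffer-only series show no saturation. The bell width of one decade matches
a response that rises over roughly one decade of concentration before its
plateau; `σ_v = 0.02` gives replicate scatter small relative to the decade
step `m`, consistent with standard errors well below the group separation
at n = 8. The generator assumes equal variance at every concentration;
real data suggest inflated variance at blank (0 ng/mL), which the generator
deliberately does not emulate — passing recovery tests therefore say
nothing about blank-sample robustness.

## Synthetic videos and micrographs

Flow videos render a wet region (dry intensity 220, wet darker by
`wet_dry_contrast`, default 80) advancing from the entry line at constant
velocity after `idle_frames` of pre-flow; the front position is
`clamp(v·(f − idle), 0, L)` plus optional Gaussian positional jitter,
rounded to whole pixels (fronts are pixel-resolution objects in both the
generator and the detector). Corrupted frames render all-dry or all-wet,
emulating the acquisition glitches seen in practice as a zero or full-
length distance mid-flow. The returned ground-truth trace is the rendered
(rounded, pre-corruption) front, so round-trip tests compare like with
like. Because rendering and detection are pixel-exact, the noise-free
velocity round trip is exact (< 1e−9 px/frame) whenever `v·(f − f₀)` is an
integer; tests use v = 2 px/frame. The generator is phenomenological: no
Lucas–Washburn wicking dynamics, pore retention or surface-tension physics.

Micrographs plant connected blobs by seeded random growth: agglutinated
clusters with lognormal areas floored at the 50-px counting threshold
(log-mean 4.8 ≈ 120 px median, log-sd 0.4), free particles of 3–20 px.
Objects keep ≥ 1 px separation so 8-connected labeling recovers them
exactly; particle intensities (150–255) always clear the intensity
threshold, and default background noise (mean 30, sd 10, clipped) stays
below it, so planted cluster totals are exactly recoverable in the noise-
free configuration and with default noise. All randomness in the package
flows through `numpy.random.SeedSequence(seed)`; identical (spec, seed)
pairs are bit-identical.

## Front localization

The front on a measurement line is found from `|frame − reference|` along
the flow axis past the entry line: a centred 5-px moving average (edges
padded with the edge value — a shrinking window would bias the step edge
near the entry line and channel end), then the farthest position whose
smoothed difference exceeds **half the observed contrast**, where contrast
is the raw profile maximum. If the contrast is under 4 intensity units it
cannot be halved meaningfully and an Otsu threshold on the difference
profile is used; if nothing exceeds threshold the distance is 0. The
reported distance is the index of the farthest exceeding pixel plus one
(wetted length), clipped to the channel length. For a clean step this is
pixel-exact; the contract under noise is ±1 px. Measurement lines sit at
20/40/60/80 % of the channel width — equally spaced interior positions that
avoid edge wicking artifacts.

## Profile cleanup and onset detection

A frame is removed on a line when its distance is 0 or ≥ L while at least
one frame within ±2 on *each* side is interior (0 < d < L): mid-flow the
front can neither vanish nor teleport to the channel end. Leading zeros
(pre-flow) and trailing saturation are genuine and kept. Removal beyond
50 % of frames on any line raises a quality failure naming the line. An
optional isotonic pass (off by default) replaces decreases with the running
maximum; it is off because jitter-induced small decreases are information
for the OLS fit, not errors. Cleanup is idempotent and never alters
interior values.

Flow onset f₀: departure is declared at the first frame whose
median-across-lines distance exceeds `baseline_mean + 5·sd` (baseline =
first 5 frames, sd floored at 0.5 px) for 3 consecutive frames; the onset
is then located by backtracking down the monotone rise (steps larger than
the 0.5-px floor) to the frame where the climb began. The backtrack uses
the floor rather than the baseline sd because when flow starts inside the
baseline window the baseline sd is inflated by the rise itself. The
sustained-exceedance requirement rejects single-frame glitches; the
backtrack recovers the exact first-motion frame in noise-free videos
(including flow from frame 0) and is within a frame or two under jitter —
immaterial for a slope estimate. No sustained departure raises a no-flow
error.

## Velocity estimation

Velocity is the OLS slope of distance vs frame index over the half-open
window [0, w) after onset shifting, fitted per line with missing frames
skipped, then averaged over the four lines; the standard error is the sd of
the four slopes over √4. The default w = 35 (35 samples, 1.17 s at 30 fps)
is the empirically optimal analysis window for this assay; fitting a slope
rather than taking an endpoint difference uses every frame and is robust to
removed frames. Fewer than 2 usable frames on any line is a quality
failure. Per-line slopes are averaged (rather than averaging distances
before fitting) so that a missing frame on one line cannot bias the others.

## Calibration and zones

`fit_semilog` regresses response on log₁₀ concentration — base 10 because
curve slopes are quoted per decade — on per-concentration means by default
(replicate-level fitting is available), excluding c = 0 from the log plot.
R² is 1 − SS_res/SS_tot on the fitted points, clipped to [0, 1]. Inverse
prediction divides by a correction factor (default 1.0; 1.5 is the
published constant for the elevated particle-load protocol) and flags
out-of-range predictions with a warning, not an error: extrapolation is
the user's call. The ELISA standard curve is ordinary linear OLS of OD on
concentration; 4PL/5PL dose-response machinery is deliberately out of
scope.

The zone classifier takes sorted concentrations and mean responses, with a
tolerance `eps` defaulting to the pooled (RMS) standard error of the group
means. The equivalence zone is the contiguous run around the maximum mean
within `eps` of it; points before are antibody excess, after are antigen
excess; the equivalence estimate is the argmax concentration (resolution:
one grid point). A strictly monotone series is a boundary case: the formal
rule would label the extreme point "equivalence", but a monotone response
shows no plateau, so when the equivalence run is a single extreme point
reached by a step larger than `eps` the whole series is classified as one
zone and the extreme concentration is reported as a bound on `c_eq`.

## Statistics

One-way ANOVA is the classical fixed-effects decomposition (explicit sums
of squares; p from the central F on (k−1, N−k) df), assuming homoscedastic
normal errors — the spreadsheet-style ANOVA this assay's window screening
uses. Zero within-group variance with separated means gives F = ∞, p = 0;
zero variance everywhere is an undefined-F error. Window optimization runs
the ANOVA per candidate window and picks the minimal p, breaking ties by
the smaller mean per-group SE; no multiple-testing correction is applied
across windows (the screening is descriptive, not confirmatory).

Method comparison regresses flow-derived on reference (ELISA)
concentrations with a free intercept (slope ≈ 1, high R² ⇒ agreement); a
through-origin slope is reported as a secondary summary since published
comparisons sometimes quote one. Outliers are points with externally
studentized residual magnitude > 2 — a conventional screening cut;
flagging is skipped for perfect fits and when leave-one-out residual df
vanish (n ≤ 3). Bland–Altman/Deming alternatives are out of scope.

## Numerical conventions

Pixels and frames are 0-based; distances are measured from the entry line
along the flow axis; windows are half-open. OLS uses the closed-form
centred normal equations throughout (condition is never a concern at these
sizes, and the estimator is then trivially testable against an independent
oracle). Problem sizes in the test bench — 500 calibration tables, 1000
ANOVA null simulations, 100 labeling-oracle masks, videos of 50–80 frames
at 150–200 px channels, 256×256 micrographs — give Monte-Carlo standard
errors a factor ≳ 5 below the tested tolerances while the whole suite runs
in seconds.

## Limitations

- The synthetic flow model is kinematic (constant velocity + jitter); real
  wicking decelerates over minutes, so only the early-window behaviour is
  represented, which is exactly the regime the pipeline analyzes.
- Geometry is user-supplied (fixed-holder assumption); there is no chip
  auto-detection, perspective correction or illumination normalization.
- The particle score is area-based by construction; fluorescence intensity
  quantification on paper is out of scope.
- MP4/AVI decoding needs an imageio ffmpeg plugin; the portable input
  format is a PNG/TIFF frame directory.
- The classifier's equivalence estimate has one-grid-point resolution; it
  does not interpolate the bell peak between tested concentrations.
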