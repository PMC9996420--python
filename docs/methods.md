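# Methods

## The problem

Passive smartphone sensing produces a stream of timestamped interaction
events — screen on/off, foreground-app changes, keystrokes, clicks,
scrolls, view changes — that can be summarized into behavioral measures
plausibly related to depressive symptoms: diversity of app use, sleep-window
phone use, session length, typing speed. Self-reported symptoms arrive as
biweekly two-item questionnaires (loss of interest and depressed mood, each
0–4) that recall the preceding two weeks. `phenosense` implements the full
path from raw events to fitted multilevel models, plus a synthetic-data
generator that stands in for the patient data such studies run on, which
cannot be shared.

## Measures and their conventions

All timestamps are local clock time; the on-disk format stores epoch
milliseconds plus an IANA zone per person, converted at ingest, because
"night" and "hour of day" are local-time concepts.

* **Session**: screen-on to the next screen-off of the same person.
  Defensive rules for malformed streams: a second screen-on while open is
  ignored (original start kept), an orphan screen-off is ignored, a session
  still open at end-of-stream is dropped, and sessions above 24 h are
  dropped as sensor artifacts. Every drop is counted in a QC log. The 24 h
  cap and kept-open policy are our conventions: they are robust to missing
  off-events without inventing sessions.
* **App segments**: inside a session, each `app_foreground` event opens a
  segment ending at the next foreground event or session end. Time before
  the first foreground event is unattributed. How a proprietary collector
  delimits app use across idle gaps is unknowable from outside; this tiling
  rule is our documented convention.
* **App count** (hourly): distinct apps whose segments intersect the
  half-open clock hour `[h:00, h+1:00)`; a segment spanning a boundary
  counts in every hour it touches.
* **Normalized app entropy** (hourly): `-Σ p_i ln p_i / ln N` over the
  within-hour, hour-clipped time shares `p_i` of the `N` distinct apps.
  The ratio is base-invariant. `N = 1` returns 0 by convention (the
  normalizer vanishes; usage is maximally concentrated); an exactly uniform
  allocation returns exactly 1.0 (short-circuited to avoid floating-point
  residue); an hour with no app time has no value.
* **Median session duration** (hourly): median over sessions *starting* in
  the hour. Attribution by start hour is our choice for boundary-spanning
  sessions.
* **Median typing interval** (hourly): for each keystroke, the gap to the
  next event *of any kind* in the same session, clamped to [0, 5] s (values
  above the cap are set to 5 s, not dropped — dropping would bias the
  median down). The hourly summary is a median, chosen by analogy with the
  session-duration rationale for skewed time variables; a mean is the
  plausible alternative and would be a one-line change.
* **Nighttime use** (daily): session time intersected with
  `[00:00, 06:00)`; a session spanning midnight credits its post-midnight
  part to the later date.

Hours without any sensed interaction yield *missing* hourly rows: passive
sensing records nothing when the phone is idle, so absence of events is
non-observation for intensity measures. Nighttime use is the exception — a
silent night is a true zero, because not touching the phone at night is the
measured behavior itself.

## Windows, sufficiency, aggregation

Each survey is paired with the half-open window
`[symptom_date − 14 d, symptom_date)`; the survey day is excluded. A day
qualifies if it shows ≥ 3 unique active hours; a window passes if ≥ 3 days
qualify (both thresholds are flags on the CLI). Failing windows are
reported with reasons and excluded from modeling.

Aggregation: mean over observed (non-missing) hourly values for the four
hourly measures; mean over all 14 daily nighttime values with silent nights
as zeros. The three right-skewed time measures (nighttime, session
duration, typing interval) then get `ln(1 + x)`. Choices made where
multiple readings are defensible, and why:

* transform **after** aggregation — one transform per window value;
* `ln(1 + x)` rather than `ln x` — accommodates the true zeros of
  nighttime use (its transformed minimum is exactly 0);
* note that `ln(1+x)` meaningfully reduces skewness only when the bulk of
  the distribution sits above ~1 unit: it tames minute-scale measures but
  leaves sub-unit second-scale values nearly unchanged (`log1p(x) ≈ x`).
  The skew-reduction property is therefore asserted on minute-scale
  lognormal data only.

Summaries report sample SD (n−1) and the population moment skewness
`g1 = m3 / m2^{3/2}`, undefined for constant input.

## Disaggregation

Each window-level predictor splits exactly as
`X_it = grand_mean + bp_i + wp_it`, with `bp_i` the person mean over that
person's QC-passing windows (grand-mean centered over *persons*, so each
person counts once) and `wp_it` the deviation from the person's own mean.
Centering `bp` is optional (`center_between=False`); it affects only the
intercept, which with centering estimates the prototypical person's
outcome. Missing values propagate to `wp` only; `bp` uses the observed
windows. The three-way correlation table (outcome vs raw / within portion /
between portion) makes the nonergodicity of the process visible: pooled
correlations need not resemble either component.

## The mixed model

For each outcome separately,

    y_it = β0i + Σ_k βki · wp_k,it + e_it
    β0i  = γ00 + Σ_k γ0k · bp_k,i + u0i
    βki  = γk0 + uki                       k = 1..5

with `u ~ N(0, diag(σ²_u0..σ²_u5))` independent across effects (the
"independent"/diagonal structure: random-slope variances are of interest,
their covariances are not estimated) and `e ~ N(0, σ²_e)`. The 0–4 outcome
is treated as continuous. Rows with any missing value are listwise-deleted
(missing-at-random handling).

Estimation is REML (ML available) over log-variances with L-BFGS-B from
method-of-moments starting values at three scales (0.1×, 1×, 10×), best
restricted likelihood wins. Because the random-effect design has at most
six columns, the likelihood is evaluated from per-person sufficient
statistics (`Z'Z`, `Z'X`, `Z'y`, …) with batched 6×6 Cholesky algebra; a
full fit takes well under a second, which is what makes the simulation
studies below routine. Numerical conventions:

* log-variance parameters bounded in [−30, 10]; variances below 1e−6 of
  the residual variance are reported as exactly 0 (boundary solutions);
* rows are internally sorted by (person, covariates, outcome) so fits are
  bit-identical under input row permutations;
* the restricted likelihood includes its full constant, so values are
  directly comparable to dense-matrix implementations;
* non-convergence returns a flagged fit rather than raising; fewer than
  two persons raises (random effects unidentifiable).

Inference: Wald z tests with a standard-normal reference for fixed effects
— a documented approximation (no Satterthwaite/Kenward–Roger degrees of
freedom) that is accurate at this design's person counts; the
parameter-recovery experiment measures its actual coverage. Variance
components get 95% percentile intervals from a seeded parametric bootstrap
(default B = 500; fewer than 50 replicates is refused); refits start from
the base estimates. Estimates at the zero boundary pile up at 0, correctly
giving intervals with lower bound 0.

## Synthetic data

Three generators, all deterministic under a seed:

* **Window level**: draws `bp_i ~ N(0, τ²)` (emitted centered),
  `wp_it ~ N(0, ω²)`, independent random effects, and the outcome from the
  model above. Default truth: γ00 = 2.24, γ (wp app count) = −0.14,
  γ (wp typing) = 0.88, γ (bp session duration) = −0.37, others 0;
  σ²_u0 = 0.86, σ²_u1 = 0.06, other slope variances 0.01, σ²_e = 0.54 —
  magnitudes representative of published biweekly sensing panels. Default
  predictor moments emulate the same scale (app count ≈ 7.5 ± 2 per active
  hour, entropy ≈ 0.48 ± 0.09, log-minutes ≈ 1.7/1.35/0.43), split
  0.8²/0.6² between between- and within-person SD. Optional Likert
  discretization (round + clip to 0–4) attenuates variance-component
  recovery and is off by default.
* **Event level**: per person-day, Poisson daytime sessions plus a separate
  Poisson rate for sessions starting in [00:00, 06:00); lognormal durations
  (minutes); within each session, apps drawn from a personal catalog with
  Dirichlet time shares tiling the session from its first moment;
  keystroke bursts with lognormal inter-key gaps; extra clicks/scrolls.
  Alongside the events it emits the exact hourly/daily feature values,
  accumulated by an independent plain-loop pass over the generated
  primitives — never by calling the pipeline — so round-trip tests compare
  two genuinely separate routes.
* **Linked scenario**: a latent trait per person and a latent state per
  14-day window drive both the survey items and the behavior rates (by
  default: elevated loss-of-interest states reduce apps-per-session by
  `exp(−0.4·state)`; elevated mood states slow typing by +0.25 on the
  log-gap). This exercises the entire pipeline with programmed effect
  signs.

What the generators do **not** emulate: real app taxonomies, circadian
structure beyond the day/night rate split, autocorrelated symptom
trajectories, device artifacts (the streams are well-formed by
construction). Passing tests therefore demonstrate correctness of the
*computational pipeline and estimator* under the model's assumptions — not
that the five measures track depression in any particular real population.

## Simulation-study design

Problem sizes were chosen so each study is statistically decisive yet runs
in minutes on one CPU:

* **Parameter recovery**: 150 persons × 7 windows × 200 replicates at the
  default truth, with *standardized* predictor moments (μ = 0,
  τ = ω = 1). Standardization is deliberate: with realistic Table-scale
  moments the per-fit SEs of the entropy coefficients are ~0.5–1.0, so the
  Monte-Carlo error of a 200-replicate bias estimate would exceed the
  0.03 acceptance band regardless of estimator quality. On standardized
  predictors the Monte-Carlo error is ~0.002–0.006. Checked: max absolute
  bias of the eleven fixed effects < 0.03; per-effect 95% Wald coverage in
  [90%, 98%].
* **Sign recovery end-to-end**: 50 replicates of 25 persons × four 14-day
  windows through the full event pipeline with app-count linkage −0.6;
  the fitted within-person app-count effect must be negative in ≥ 90% of
  replicates.
* **Round trip**: 100 person-days (5 persons × 20 days); counts exact,
  time quantities within 1e−9 minutes.
* The acceptance script's synthetic study uses 142 persons × 7 biweekly
  surveys, matching the scale such a panel actually has.

## Known limitations

* Wald/normal inference is anti-conservative at small person counts; no
  small-sample degrees-of-freedom correction is provided.
* The hourly typing summary uses the median; collectors that report means
  will produce systematically different window values.
* The QC rule counts *any* hourly feature as activity; a stream with only
  screen events (no apps, no typing) still marks hours active.
* Single-person datasets cannot be fit; persons contribute to `bp`
  estimation with as little as one window, which leaves their `wp` at 0.
* DST transitions are resolved by the zone database at ingest; sessions
  spanning a transition use wall-clock arithmetic.
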