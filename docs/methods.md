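# Methods

## Scientific setting

`sjwindow` analyses simultaneity-judgment (SJ) experiments in which an
observer repeatedly judges whether an auditory and a visual stimulus,
separated by a stimulus onset asynchrony (SOA), occurred together. The
proportion of "synchronous" reports as a function of SOA is unimodal:
high near zero asynchrony and falling toward both large auditory leads and
large visual leads. The temporal binding window (TBW) summarizes this
function by the SOA range over which the fitted probability of a
synchronous report exceeds 50 %.

The package's reference design is a two-condition within-subject
experiment: an *active* condition where the audiovisual stimuli are the
observer's own speech (seen and heard with imposed delays) and a *passive*
condition replaying the recorded stimuli. The scientific question it
serves is whether self-generated multisensory input is integrated over a
narrower window than passively received input.

## Sign and delay conventions

* `soa_ms = audio_delay_ms − video_delay_ms`; negative SOAs mean the
  auditory stimulus leads (AV side), positive SOAs the visual stimulus
  leads (VA side). Example: a −200 ms SOA with a 200 ms leading delay
  commands audio at 200 ms and video at 400 ms from the action onset.
* Commanded delays lie in [200, 600] ms; the leading modality's delay is
  drawn uniformly on the feasible integer interval
  `[delay_min, delay_max − |soa|]`. The draw rule is the package's choice —
  any rule covering the stated range is admissible — and is reproducible
  by seed.
* Apparatus calibration (constant reproduction delays, default audio
  170 ± 5 ms jitter and video 150 ± 8 ms) is compensated at design time, so
  analysis uses nominal SOA levels. The simulator can optionally evaluate
  observers at effective onsets (constants + uniform jitter, rounded to
  0.1 ms) to probe robustness; that path is off by default. Delays are
  integer milliseconds — sub-millisecond apparatus granularity is
  irrelevant at these SOAs.
* Trial order is randomized within each block, keeping the designed
  4-trials-per-SOA-per-block balance exact in every block.

## Estimation

Per participant × condition:

1. **Rates.** Per-SOA rates of synchronous reports over non-rejected
   trials; levels with no valid trials are dropped with a warning.
2. **Side fits.** A binomial regression of response on signed SOA with a
   logit link is fitted separately to the AV (SOA < 0) and VA (SOA > 0)
   trials. A zero-SOA level, if a design includes one, joins both sides.
   Fitting uses per-SOA aggregated counts, which is likelihood-identical
   to the trial-level fit. A probit link is available behind an option;
   logit is the default and the tested path.
3. **Crossings.** Each side's 50 % crossing is `|−b0/b1|` — the linear
   predictor's root, where both logit and probit curves pass 0.5. The
   criterion is absolute probability 0.5, not 50 % of the fitted maximum.
4. **Window.** Width = AV + VA crossing (exact sum); asymmetry = AV − VA
   (positive = auditory shift); peak amplitude = the larger of the two
   fitted curves at SOA 0, each side's supremum over its own domain (an
   "observed max rate" definition is available for sensitivity analyses).
5. **Group.** Arithmetic means and n−1 SDs of the per-participant sides,
   widths and peaks per condition.

Numerical safeguards:

* **Separation.** With 16 trials per SOA an all-synchronous side is
  plausible; the ML fit is then unbounded. Sides whose ML fit fails,
  does not converge, or puts |linear predictor| > 15 at any data point are
  refitted with a Jeffreys-prior (Firth) penalty — deterministic, no
  tuning, always finite — and flagged `penalized`.
* **Minimum slope.** Crossings require |b1| ≥ 1e−4 per ms (a 50 ms SOA
  change must move the rate by roughly 0.1 % near midpoint); shallower
  sides are marked unusable and propagate to the group stage as missing
  rather than as a wild extrapolation.
* **Extrapolation.** Crossings outside the measured SOA magnitude range
  (67–400 ms by default) are retained but flagged `extrapolated`.

## Group inference

* **Paired t-tests** (active vs passive on AV, VA, width, peak; AV vs VA
  within condition) report two-tailed p and the paired-design Cohen's
  d_z = mean(diff)/SD(diff), whose standardizer makes d = t/√n an exact
  identity. The average-SD standardizer is deliberately not offered, to
  avoid silently inconsistent effect sizes.
* **2×2 within-subject ANOVA** (condition × stimulus order) uses the
  within-subject sums-of-squares decomposition, testing each effect
  against its own subject × effect interaction; partial
  η² = F·df1/(F·df1 + df2). With two-level factors sphericity holds
  trivially, so no correction machinery is included, and each F equals
  the square of the matching paired contrast t — an identity the tests
  verify against an independent implementation.
* **Power.** Exact noncentral-t power for paired designs (noncentrality
  d·√n, df n−1); `required_n` inverts it by doubling + bisection.
  Tails default to **one-tailed** and are always stated explicitly in
  output: the choice is ambiguous in common practice, and the solver logs
  it (one-tailed yields N = 14 at d = 0.95, α = 0.05, power 0.95;
  two-tailed yields 17).
* No multiple-testing correction by default, matching how families of
  paired contrasts are conventionally reported in this literature; Holm
  adjustment is available by flag.
* Participants with an unusable fit in either condition are dropped
  listwise per analysis, with counts reported.

## The synthetic observer

The generative model is the standard two-sided psychometric form

    p(soa) = guess + (1 − guess − lapse) · core(soa),
    core = logistic(slope_av · (soa + c_av))    for soa < 0,
    core = logistic(−slope_va · (soa − c_va))   for soa ≥ 0,

with no continuity constraint at SOA 0 (no zero-SOA trials exist in the
default design, and the estimator fits sides independently). Defaults set
guess = lapse = 0 so the generative crossings (c_av, c_va) coincide exactly
with the 50 % criterion; nonzero floors are exercised in robustness tests
only.

Population draws:

* Crossings are truncated-at-zero normal per condition. The underlying
  normal's (μ, σ) are **moment-matched** so the truncated distribution has
  exactly the requested population mean and SD — naive truncation would
  inflate the mean by ~15 ms at the default visual-leading values. A
  zero-truncated normal always has SD < mean; infeasible requests error.
* Default condition means/SDs (ms): active AV 240.76/100.71,
  VA 119.53/91.45; passive AV 259.00/79.13, VA 222.41/82.97 — group
  statistics of a 17-participant talk-vs-listen SJ cohort.
* Each crossing is correlated across conditions within participant by a
  Gaussian copula (default ρ = 0.5). The value is a plausibility choice:
  it shapes paired-test power, not marginal means, and is configurable.
* Slopes are lognormal (median 0.02 per ms, log-SD 0.25), drawn per
  participant per side and shared across conditions. No slope information
  is available to match, so these were fixed once at values that produce
  psychometric curves of realistic steepness for speech-like audiovisual
  stimuli (rate moves from ~12 % to ~88 % over ~200 ms around the
  crossing).
* Trial rejection emulates microphone failures: 7 randomly chosen
  participants (of 17) lose a uniform 1–26 trials of the active condition,
  chosen uniformly over trials. The per-participant loss distribution is a
  stand-in — only the participant count and the count range are
  constrained by the reference cohort.

What the simulator does **not** emulate: response times and confidence,
sequential/adaptation effects across trials, condition-order (practice)
effects, SOA-dependent rejection, drift in apparatus delays, and any
lapse/guess asymmetry between conditions. Passing recovery tests therefore
show that the estimator inverts this generative family faithfully at the
study's trial counts — not that real observers follow it.

## Problem sizes in the test suite

Unit and property tests run at the reference session size (14 levels × 16
trials). The deeper stochastic checks use: 500 simulated sessions at 16
trials/SOA and 500 at 1,000 trials/SOA for crossing recovery (median
absolute error reported; < 5 ms required at the asymptotic size); 200 live
fits for the closed-form-vs-root-finder crossing check; and 40 replicated
17-participant cohorts for the directional group-pattern check (group
means within 20 ms of the generative means — about the design's SOA
granularity — a narrower active window in ≥ 70 % of replicates, and far
more frequent VA-side than AV-side rejections). These sizes give stable
Monte-Carlo verdicts at interactive runtimes.

## Known limitations

* The estimator assumes a monotone logistic on each side; bimodal or
  plateaued rate profiles (e.g. strong lapses at mid SOAs) are fitted but
  not modelled, and lapse rates are not estimated from data.
* Crossings are point estimates; no per-participant uncertainty is
  propagated into the group stage (the paired tests absorb it as
  between-subject variance, as is conventional).
* The 2×2 ANOVA and paired tests cover the fully-within two-condition
  design only; mixed or larger factorial designs are out of scope.
* `required_n`'s one-tailed default should be overridden when a two-sided
  alternative is genuinely of interest.
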