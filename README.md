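# sjwindow

Estimation and inference for the **temporal binding window (TBW)** of
audiovisual integration from **simultaneity judgment (SJ)** data.

In an SJ task an observer sees and hears paired stimuli separated by a
stimulus onset asynchrony (SOA; here negative = auditory first) and reports
whether they appeared synchronous. The range of SOAs judged synchronous
above a criterion is the temporal binding window — a standard behavioural
index of how precisely the brain integrates sight and sound. `sjwindow`
provides the full analysis chain for within-subject SJ designs (e.g. an
*active* condition with self-generated speech stimuli versus a *passive*
playback condition):

* **design** — balanced SOA schedules (default: ±67, 100, 167, 200, 267,
  334, 400 ms; 4 blocks × 4 trials per SOA, i.e. 224 trials per condition)
  with audio/video command delays on 200–600 ms and apparatus calibration
  (constant delays + jitter);
* **synthetic observers** — a two-sided psychometric generative model with
  guess/lapse floors, population heterogeneity with matched moments,
  within-subject correlation across conditions, and microphone-failure
  trial rejection, so the pipeline is testable end to end without raw data;
* **window estimation** — per-SOA rates of perceived simultaneity over
  non-rejected trials, separate binomial-GLM (logit) fits to the
  audio-leading and visual-leading sides, 50%-criterion crossings in closed
  form, window width/asymmetry/peak amplitude, with Jeffreys-penalized
  refits under separation;
* **group statistics** — paired t-tests with the paired-design Cohen's
  *d*(= *t*/√n), the 2×2 within-subject ANOVA (condition × stimulus order)
  with partial η², and exact noncentral-*t* power / sample-size analysis.

## The model

For one observer and condition, each side of the window is a binomial
regression on signed SOA with logit link,

    logit P(synchronous | SOA) = b0 + b1·SOA,

fitted separately to SOA < 0 (AV, audio-leading) and SOA > 0 (VA,
visual-leading) trials. The side's crossing is the SOA magnitude where the
fitted curve equals 0.5, `|−b0/b1|`; the window width is the sum of the two
crossings, the asymmetry their difference (positive = auditory shift), and
the peak amplitude the larger fitted probability at SOA 0. Group inference
treats the per-participant crossings as the paired observations.

## Worked example

```python
import sjwindow as sj

# a 17-participant synthetic cohort, two conditions, 224 trials each
trials, truth = sj.simulate_cohort(sj.PopulationSpec(), seed=42)

model = sj.SimultaneityJudgment.from_dataframe(trials, "p01", "active")
print(model.fit().summary())

estimates, failures = sj.fit_cohort(trials)
print(sj.group_tbw(estimates).round(2).to_string(index=False))

wide = estimates.pivot(index="participant", columns="condition", values="va_ms")
print(sj.paired_t(wide["active"], wide["passive"]).summary())
```

prints

```
Temporal binding window [p01 x active]
==============================================
AV side (audio leads)              313.00 ms
VA side (visual leads)             100.87 ms
Total width                        413.87 ms
Asymmetry (AV - VA)                212.13 ms
Peak amplitude                      0.999
----------------------------------------------
AV fit: b0=+6.5119, b1=+0.020805/ms, n=104
VA fit: b0=+1.9359, b1=-0.019191/ms, n=98

condition  n  av_ms_mean  av_ms_sd  va_ms_mean  va_ms_sd  width_ms_mean  width_ms_sd  peak_mean  peak_sd
   active 17      234.27    102.44      146.98     98.40         381.25       125.78       0.97     0.07
  passive 17      261.47     77.82      250.82     68.31         512.30        95.80       1.00     0.01

VA side: t(16) = -4.391, p = 0.000456, Cohen's d = -1.065 (n = 17, mean diff = -103.84, SD diff = 97.52)
```

This participant's window spans 313 ms of auditory lead but only 101 ms of
visual lead (an auditory shift); at the group level the active condition's
visual-leading side is over 100 ms narrower than the passive condition's,
a large paired effect — self-generated stimuli are bound over a tighter
window.

The same pipeline runs from a shell:

```
sjwindow simulate --seed 42 -o trials.csv      # trial log + truth sidecar
sjwindow fit trials.csv -o estimates.tsv       # per-participant windows
sjwindow analyze trials.csv                    # group summary, t-tests, ANOVA
sjwindow power -d 0.95 --alpha 0.05 --power 0.95 --tails one
sjwindow run --seed 42 -o out/                 # everything, with reports
```

The `power` protocol reproduces the classic a-priori computation for a
paired design: detecting d_z = 0.95 with α = 0.05 and 95 % power needs
**N = 14** participants (exact noncentral-*t*, one-tailed).

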