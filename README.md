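# phenosense

Passive smartphone-sensing behavioral measures and within/between-person
multilevel models of depressive symptoms.

Digital-phenotyping studies pair passively sensed human–smartphone
interaction streams (screen on/off, foreground-app changes, keystrokes,
touches) with brief self-report scales, asking whether behavior tracks
symptoms. `phenosense` is a tested, reusable implementation of that whole
analysis for the two-item depression domain (loss of interest and
depressed mood, each 0–4, recalled over two weeks):

1. **Event ingest** — canonical CSV event logs (epoch-ms + IANA zone),
   screen-session reconstruction, per-app usage segments, QC counters for
   malformed streams.
2. **Feature extraction** — five behavioral measures at their native
   timescales: hourly unique **app count**; hourly **normalized app
   entropy** `-Σ pᵢ ln pᵢ / ln N` of within-hour app time shares; hourly
   **median session duration**; hourly **median typing interval** (gap
   from a keystroke to the next event, capped at 5 s); daily **nighttime
   use** (screen minutes in 00:00–06:00).
3. **Window alignment & QC** — each survey gets the preceding 14 days of
   features; windows need ≥ 3 days with ≥ 3 unique active hours; window
   means, `ln(1+x)` transforms for the skewed time measures, and
   Table-style summaries (mean, SD, range, skewness; raw/within/between
   correlations).
4. **Disaggregation** — person-mean centering splits every predictor into
   a between-person portion `bp_i` and within-person deviations `wp_it`
   (`X_it = grand + bp_i + wp_it`, exactly), because within- and
   between-person associations of nonergodic processes differ.
5. **Multilevel models** — for each outcome, a two-level linear mixed
   model with all five `wp` and five `bp` predictors, a random intercept
   and five random `wp` slopes with independent (diagonal) covariance,
   estimated by REML; Wald z inference for fixed effects and seeded
   parametric-bootstrap 95% CIs for variance components.
6. **Synthetic data** — generators for window-level designs drawn from
   the model, raw event streams with exact feature ground truth computed
   by an independent accumulation pass, and a linked scenario where latent
   symptom states drive both surveys and behavior.

It is written for methods researchers and data scientists in behavioral
sensing who need a transparent reference implementation with known-truth
simulation machinery, not a clinical tool.

## Worked example

Generate a linked synthetic study, run the pipeline, fit both models:

```python
import phenosense as ph

cfg = ph.EventSimConfig(n_persons=20, n_days=70, seed=11)
bundle = ph.generate_linked_scenario(cfg)          # events + biweekly surveys
win, design, qc = ph.build_design(bundle["events"], bundle["surveys"])
fit_loss, fit_mood = ph.fit_both_outcomes(design)

print(int(win.qc_pass.sum()), "of", len(win), "windows pass QC")
print(fit_loss.fixed.loc["wp_app_count"].round(3).to_dict())
print(fit_mood.fixed.loc["wp_typing_interval"].round(3).to_dict())
```

prints

```
100 of 100 windows pass QC
{'estimate': -0.225, 'se': 0.134, 'stat': -1.684, 'p': 0.092}
{'estimate': 10.911, 'se': 0.772, 'stat': 14.125, 'p': 0.0}
```

The generator programmed a *negative* link between the latent
loss-of-interest state and app diversity, and a *positive* link between
the mood state and typing slowness; the fitted within-person coefficients
recover both signs (the app-count effect, −0.225 symptom points per extra
within-person app, is modest at 20 persons; the typing effect is strong
because the linkage acts directly on the log inter-key gap). The same
steps are available as a CLI:

```bash
phenosense simulate --scenario linked --seed 11 --out-dir scratch/demo
phenosense windows --events scratch/demo/events.csv \
    --surveys scratch/demo/surveys.csv --out scratch/demo/windows.csv
phenosense disaggregate --windows scratch/demo/windows.csv \
    --out scratch/demo/design.csv
phenosense fit --design scratch/demo/design.csv --outcome both --seed 1
```

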