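# stroopdelta

Distributional (delta-plot) analysis of spatial-Stroop reaction times
for pooled multi-study cohorts, with study-nested linear mixed models.

## What it is for

In the spatial Stroop task a lateralized target — a face, a pair of
eyes, or an arrow — points left or right while its screen position is
task-irrelevant. Arrows produce the standard congruency effect (SCE:
incongruent slower); gaze and face targets can produce a *reversed*
congruency effect (RCE: incongruent faster). Whether and where these
effects emerge across the RT distribution is a distributional question:
the congruency effect at the q-th quantile,

    Δ(q) = Q_incongruent(q) − Q_congruent(q),

plotted against mean RT (the delta plot), separates fast from slow
responses and is the standard tool for testing dual-route accounts of
conflict processing. `stroopdelta` implements the full chain for
researchers pooling several studies:

1. **Preprocessing** — participant exclusion by non-response rate,
   RT trimming to [200, 1300] ms (or a non-trimmed variant), and
   correct-trials-only filtering, with a removal report.
2. **Quantile engine** — per-participant condition quantiles with the
   Hyndman–Fan Type-8 estimator (h = (n + 1/3)p + 1/3) at
   (.1, .3, .5, .7, .9) by default (quartile/decile grids available),
   delta functions, and vincentized (quantile-averaged) group curves.
3. **Mixed models** — RT, delta and polynomial trend models with
   nested random intercepts, e.g.

       delta ~ target * quantile + (1|study:participant)
               + (1|study:target) + (1|study:target:quantile)

   fitted by profiled REML, with Satterthwaite denominator df,
   Type-III-style ANOVA with partial η², backward elimination of
   non-significant fixed terms, estimated marginal means, Tukey HSD and
   Bonferroni contrasts, and Westfall standardized effect sizes
   (estimate / √(sum of all variance components)).
4. **Trend analysis** — orthogonal quadratic polynomials of the
   delta-plot abscissa, back-transformed to raw-scale linear/quadratic
   coefficients per target with pairwise differences.
5. **Synthetic cohorts** — a generator whose incongruent RTs are a
   monotone warp g(X) = X + δ(F(X)) of an ex-Gaussian baseline, so the
   population quantile difference at every q equals the chosen profile
   δ(q) = a + bq + cq² exactly: closed-form ground truth for every
   downstream stage.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import stroopdelta as sd
from stroopdelta.inference import emm

cfg = sd.SimConfig(n_studies=6, participants_per_study=24,
                   trials_per_cell=40, seed=42)
trials = sd.simulate_cohort(cfg)
retained, report, excluded = sd.preprocess(trials)
print(f"retained {len(retained)} of {len(trials)} trials")

cdf = sd.build_cdf_dataset(retained)
delta = sd.build_delta_dataset(cdf)
fit = sd.fit_lmm(delta, sd.delta_model_spec())
print(emm(fit, ("target_type",)).table.round(1).to_string(index=False))

trend = sd.compare_trends(sd.fit_trend_model(delta))
lin = trend.coefficients.query("degree == 'linear'")
print(lin[["target_type", "estimate", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
```

prints

```
retained 31480 of 34560 trials
target_type  estimate  se   df  ci_low  ci_high
       face     -31.9 2.7 17.9   -37.5    -26.4
       eyes     -24.6 2.7 17.9   -30.2    -19.0
     arrows      33.5 2.7 17.9    27.9     39.1
target_type  estimate  ci_low  ci_high
       face    -0.177  -0.213   -0.141
       eyes    -0.103  -0.138   -0.068
     arrows     0.045   0.007    0.083
```

The delta-model EMMs say arrows show a +33 ms congruency effect while
faces and eyes show reversed effects of −32 and −25 ms; the trend
coefficients say the face delta plot falls by ≈ 1.8 ms per 10 ms of
response slowing, steeper than eyes, while arrows stay essentially
flat. The same analysis runs on real trial-level CSVs via
`sd.read_trials(path)` (columns: study_id, participant_id, target_type,
congruency, rt_ms, accuracy, responded).

## Command line

```sh
stroopdelta simulate --out trials.csv --seed 3
stroopdelta preprocess --in trials.csv --out clean.csv --report removals.tsv
stroopdelta quantiles --in clean.csv --out-cdf cdf.tsv --out-delta delta.tsv
stroopdelta fit --cdf cdf.tsv --model rt --out rt_model/
stroopdelta trend --delta delta.tsv --out trend/
stroopdelta run-all --out run/ --seed 3      # everything, plus figures
```

`run-all` writes all tables (TSV), CDF/delta figures, and a
`manifest.json` + `config.yaml` pair that reproduces the run
byte-for-byte under the same library versions.

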