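# frostbloom

Projection of apple (*Malus domestica*) bloom dates and blossom frost risk
from ensembles of regional climate realizations, with full accounting of
climate-model and impact-model uncertainty.

Late frosts during bloom are a major production risk for fruit growers.
Under warming, two shifts race each other: flowering advances (faster
completion of the spring heat requirement, partly offset by delayed
release of winter dormancy), and the last spring freeze advances too.
Whether frost risk rises or falls depends on which moves faster — and any
single climate run driving any single phenological model gives a
deceptively confident answer.  `frostbloom` runs the whole chain across an
ensemble of climate realizations and seven phenological models, and tells
you not only the projected change but *when* that change exceeds the
spread of the projection itself.

## What is inside

* **Seven chilling–forcing phenology models** (integer ids 1–7): thermal
  time, sequential and parallel chilling–forcing, modified Utah, and
  day-length-extended variants.  Chilling accumulates as chill days in the
  0–`Tbc` band (or Utah weights); forcing as `max(T − Tbf, 0)` scaled by
  `(D/12 h)^c`; the forcing requirement follows `F* = a·exp(b·Sc)`.
* **Climate preparation**: cubic-spline daily→hourly interpolation, 3×3
  spatial floating mean, ordinary kriging, and monthly non-parametric
  quantile-mapping bias correction (Gaussian-kernel-smoothed CDFs,
  h = 0.1).
* **Calibration** by bound-constrained simulated annealing (RMSE of bloom
  DOY; base temperatures searched in 0–10 °C), with leave-one-out and
  external PRMSE validation.
* **Blossom frost risk** θ: the fraction of years in a 30-year window with
  daily minimum ≤ β (0 or 2 °C) between bloom and July 31, plus its change
  Δθ and kernel-density summaries; last-spring-freeze extraction;
  unfulfilled-chilling bookkeeping.
* **Uncertainty partitioning**: internal variability V, climate-run
  variance M(t) and error-weighted impact-model variance I(t) from
  10-year-smoothed, polynomial-fitted area means; fractional uncertainty
  F(t) = λ√(V+M+I)/|G| and the time of emergence (first sustained F ≤ 1).
* **Trend tests**: Mann–Kendall (tie-corrected, continuity-corrected) and
  Cox–Lewis for event series.
* **Synthetic data generator** emulating a warming North-German climate
  ensemble (seasonal cycle + AR(1) weather + run bias/trend spread) and
  bloom observations from a known model — so every stage is testable
  without external archives.

## Worked example

```python
from frostbloom import PipelineConfig, ScenarioConfig, run_pipeline, write_report

config = PipelineConfig(
    scenario=ScenarioConfig(n_runs=3, n_grid=2, years=(1951, 2100), seed=42),
    model_ids=(2, 6), truth_model=6, obs_seed=1, bias_correct=False)
result = run_pipeline(config)
for name, table in write_report(result).items():
    print(f"\n== {name} ==")
    print(table.to_string(index=False))
```

prints

```
== model_errors ==
 model  rmse_days   weight
     2   6.183311 0.251139
     6   2.073644 0.748861

== delta_bloom ==
 model  delta_bloom_days
     2        -19.165556
     6        -16.865556

== delta_theta ==
 model  beta  mean_delta_theta
     2   0.0         -0.066667
     2   2.0         -0.100000
     6   0.0         -0.066667
     6   2.0         -0.127778

== emergence ==
   variable  lambda  emergence_year  min_uncertainty_year
temperature   0.674          2000.5                2095.5
temperature   1.000          2000.5                2095.5
temperature   1.645          2009.5                2095.5
      bloom   0.674          2000.5                2081.5
      bloom   1.000          2004.5                2081.5
      bloom   1.645          2021.5                2081.5
```

Reading it: the bloom observations were generated by the day-length
sequential model (6), so model 6 refits them with a ~2 d error and earns
three quarters of the inverse-error weight.  Both models project bloom
17–19 days earlier by 2070–2099 than 1971–2000, and blossom frost risk
falls by 7–13 percentage points depending on the frost threshold β.
Temperature emerges from the projection noise before bloom does, and the
stricter the confidence multiplier λ, the later the emergence — the
joint signal at the 90% level (λ = 1.645) is not distinguishable until the
2020s even though every single run × model series shows a significant
trend much earlier.

A command-line layer mirrors the stages
(`frostbloom run/fit/risk/trend/uncertainty`); see `frostbloom --help`.

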