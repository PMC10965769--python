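# acuitywm

A tested, reusable pipeline for a classic question in visual cognition: **is
visual working-memory capacity functionally independent of numerical
acuity?**  The package implements the full psychophysical analysis chain for
two tasks —

* **whole-display change detection** (memorize 2, 3 or 5 colored squares;
  after a 900 ms blank, judge whether the re-displayed array changed in one
  color), from which per-subject capacity is estimated with **Pashler's
  formula**

  *K* = *N* (ĥ − f̂) / (1 − f̂),

  where *N* is the set-size and ĥ, f̂ the hit and false-alarm proportions,
  alongside signal-detection discriminability *d′* = Z(ĥ) − Z(f̂);

* **dot comparison** (pick the more numerous of two feature-controlled dot
  arrays; references of 16 or 32 dots, eight numerosity ratios), from which
  each subject's **Weber fraction ω** is fitted with the error-function
  psychometric model

  P<sub>larger</sub>(N, N<sub>ref</sub>) = ½ (1 + erf( ln(N/N<sub>ref</sub>) / (√2 ω) )),

  with numerical acuity reported as 1 − ω.

On top of the two estimators the package provides the supporting analyses a
study of this design needs: exclusion rules (accuracy floor, 3-SD outliers),
construct-validity correlations of *K* across set-sizes, split-by-reference
reliability of ω, repeated-measures set-size contrasts with BH-FDR-corrected
pairwise tests, a **Pearson-distribution-system simulation** that
extrapolates the four moments of the *K* distributions to an untested
set-size and samples bounded replicate cohorts there, and a **Bayesian
correlation test** (BF<sub>01</sub> with a stretched beta(1/κ, 1/κ) prior on
the correlation, κ = 1/3 by default) between maximum *K* and acuity.

Because the interesting failure modes of such pipelines are statistical, the
package ships a first-class **synthetic-observer module**: slots-plus-guessing
change-detection observers and Weber-fraction dot-comparison observers with
known ground truth, balanced trial schedules matching the two designs (810
trials in 27 blocks; 192 trials sampled from a 1,280-pair pool), and cohort
generation with a configurable capacity–acuity correlation.  Every estimator
is validated by parameter recovery against these generators.

## Worked example

Simulate a 41-subject null cohort (capacity and acuity independent) and run
the whole analysis:

```python
from acuitywm import RunConfig, run_pipeline

report = run_pipeline(RunConfig(mode="simulate", seed=42,
                                cohort={"n_subjects": 41}))
c = report["correlation"]
print(f"r({c['n']-2}) = {c['r']:.3f}, p = {c['p_two_sided']:.3f}, "
      f"BF01 = {c['bf01']:.2f} ({c['evidence']})")
print("K validity r(3,5) =",
      round(report["validity"]["k_between_set_sizes"]["3v5"], 3))
print("mean omega =", round(report["acuity"]["mean_omega"], 3),
      " mean fit R^2 =", round(report["acuity"]["mean_r_squared"], 2))
```

prints

```
r(39) = -0.007, p = 0.965, BF01 = 2.87 (anecdotal)
K validity r(3,5) = 0.569
mean omega = 0.226  mean fit R^2 = 0.82
```

that is: capacity estimates at the two supra-capacity set-sizes are
internally consistent across subjects, the recovered Weber fractions sit near
the generating mean of 0.20 with psychometric fits explaining ~82% of the
cell-proportion variance, and — as it should under the null — the Bayes
factor leans toward the absence of a capacity–acuity correlation.
Re-running with `cohort={"n_subjects": 41, "k_omega_correlation": 0.6}`
drives BF01 to 0.026 ("very strong (against H0)").

The same run is available from the shell:

```bash
acuitywm simulate --config run.yaml --out results/
acuitywm correlate --k-table k_max.csv --acuity-table acuity.csv --kappa 0.333
```

## Layout

| module | contents |
| --- | --- |
| `acuitywm.observers` | trial schedules, synthetic observers, cohorts, CSV dialects |
| `acuitywm.geometry` | feature-controlled dot-array pairs and decorrelation audits |
| `acuitywm.change_detection` | tallies, Pashler *K*, *d′*, validity, contrasts, exclusions |
| `acuitywm.acuity` | psychometric model, Weber-fraction fits, reliability, outliers |
| `acuitywm.extrapolation` | moment estimation/extrapolation, Pearson-system sampler |
| `acuitywm.inference` | Pearson correlation, BF<sub>01</sub>, power, evidence labels |
| `acuitywm.pipeline` / `acuitywm.cli` | end-to-end orchestration, report schema, CLI |

See `docs/methods.md` for the models, conventions, and numerical choices.
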