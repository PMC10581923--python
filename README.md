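# nutrireq

Analysis toolkit for nutrient dose-response feeding trials: inert-marker
digestibility, growth/feed performance, molecular-weight-aware total
sulfur amino acid (TSAA) dose algebra, and multi-model nonlinear
dose-response fitting with analytic inflection/breakpoint estimation.
A synthetic-trial generator provides complete, reproducible datasets with
the statistical structure the analysis assumes, so the whole pipeline and
its parameter-recovery checks run without any external data.

## Modules

| module            | what it does |
|-------------------|--------------|
| `trial_io`        | Domain types (diets, feces, tanks, fish, ADC tables) and delimited-text readers/writers with full-precision round-trips |
| `performance`     | Weight gain %, specific growth rate (SGR), feed conversion ratio (FCR), hepatosomatic index, per-diet mean ± SEM summaries |
| `digestibility`   | Apparent digestibility coefficients from nutrient:marker ratio shifts, digestible contents, daily digestible intakes per kg geometric body weight |
| `sulfur_amino`    | TSAA as Met + Cys and as Met-equivalents via the molecular-weight ratio (149.21 / 121.16), on dietary / digestible / daily-intake bases |
| `dose_response`   | Power-series, lognormal, cubic and smoothed two-phase ("gentle connection") model fits; closed-form stationary points; AIC/AICc selection; bootstrap CIs; requirement estimates |
| `synthetic_trial` | Seeded trial generator: tank-level Gaussian response noise, feed intake back-solved from a target FCR curve, feces consistent with prescribed ADCs |
| `tissue_metrics`  | sRGB → CIELAB conversion, CIE76 color distances, lamina propria fraction, goblet-mucin densities |
| `datasets`        | Bundled six-diet methionine trial summaries used by the examples and validation suite |

## CLI

```bash
nutrireq simulate --seed 7 --outdir fixtures/          # synthetic trial
nutrireq performance --tanks fixtures/tanks.csv --fish fixtures/fish.csv \
    --diets fixtures/diets.csv --out perf.csv
nutrireq adc --diets fixtures/diets.csv --feces fixtures/feces.csv --out adc.csv
nutrireq digest --diets fixtures/diets.csv --adc adc.csv \
    --tanks fixtures/tanks.csv --out digestible.csv
nutrireq tsaa --diets fixtures/diets.csv --adc adc.csv \
    --tanks fixtures/tanks.csv --basis all --out tsaa.csv
nutrireq fit --doses tsaa.csv --responses perf.csv \
    --families power_series,lognormal,cubic,segmented \
    --basis all --seed 42 --out fits.csv --plot-dir plots/
```

`nutrireq fit` excludes nothing by default; pass `--exclude-diets D6` to
drop a contrast arm from the dose-response fits. A YAML config
(`--config`) can override nutrient-name aliases, molecular weights, the
model list, the hinge blend width, and seeds.

## Reproducibility notes

- All randomness (fitting multi-starts, bootstrap, trial generation)
  derives from explicit integer seeds; the generator spawns independent
  child streams so tank-level noise is invariant to fish-level detail.
- Chained computations carry full precision; rounding to the published
  one-decimal display happens only at report time.
- Out-of-range digestibility coefficients are propagated with a warning,
  never clipped, so downstream fits see the real data.
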