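# sportsel

Copula-based sample-selection modelling of sporting-activity participation
and duration.

The package implements a joint model in which a binary participation
outcome follows a probit margin, the aggregate activity duration over a
28-day recall window follows a Gamma margin whose shape scales with the
number of activity events (`alpha * q`), and the two latent utilities are
coupled by a Frank copula.  Duration is observed only for participants, so
naive separate analyses are biased whenever the dependence parameter is
non-zero; the package provides the full-information likelihood, maximum
likelihood estimation with observed-information standard errors, a
likelihood-ratio test of independence, and conditional-mean duration
predictions by numerical quadrature with a Monte-Carlo cross-check.

## Layout

- `sportsel.data_construction` — per-sport episode records to
  respondent-level summaries: participation, aggregate duration `t`,
  event multiplicity `q` and a three-level vigour class (only sports at
  the respondent's maximal vigour contribute to `t` and `q`).
- `sportsel.copulas` — Frank copula family with the Product-copula limit:
  cdf, Archimedean generator derivative, conditional distribution and its
  inverse, Kendall-tau transform (Debye function by quadrature) and a
  conditional-inversion sampler.
- `sportsel.margins` — probit participation and Gamma duration margins,
  name-resolved design matrices, the default covariate rosters.
- `sportsel.selection_model` — the joint likelihood, quasi-Newton fitting,
  standard errors, LR test.
- `sportsel.prediction` — marginal (`alpha q lambda`) and conditional mean
  durations, Monte-Carlo oracle, and a linear BMI predictor with
  duration-by-vigour interactions.
- `sportsel.synthetic_data` — a seeded generator for datasets with the
  assumed structure, plus checksummed packaged fixtures (published
  coefficient tables, worked covariate profiles, BMI coefficients,
  vigour-by-events counts).

## CLI

```sh
sportsel tau --theta 5.597
sportsel simulate --n 4380 --seed 1 --out-covariates cov.csv --out-episodes epi.csv
sportsel construct --episodes epi.csv --out summaries.csv
sportsel fit --data cov.csv --family frank --out fit.json --coefs-out coefs.csv
sportsel predict --fit fit.json --profile profile.yml --q-per-week 1 --vigour low
sportsel bmi --profile profile.json --duration-hwk 6.7 --vigour high
```

`fit` accepts `--config` (YAML with `participation:` and `duration:`
covariate name lists) to override the default rosters.  Profiles are flat
name/value maps in YAML, JSON or two-column CSV.

## Conventions

- Durations are hours per 28 days internally; hours-per-week figures are
  the 28-day values divided by four, and per-week event counts are
  multiplied by four on input.
- The independence model is the `theta -> 0` limit of the Frank family and
  is selected with `family="independence"`.
- All simulation entry points require an explicit seed; one root seed
  drives independent substreams for covariates, copula pairs and
  multiplicity/vigour draws.
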