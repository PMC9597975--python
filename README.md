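# headmap

Map headache-specific quality-of-life scores to preference-based health
utilities.

The Headache Impact Test (HIT-6, total score 36–78, higher = worse) and the
Chronic Headache Quality of Life Questionnaire (CH-QLQ; Role Restrictive,
Role Preventive and Emotional Function subscales, each 0–100, higher =
better) measure how chronic headache affects daily life — but they are not
preference-based, so they cannot produce the utility values that
quality-adjusted life year (QALY) calculations need. `headmap` closes that
gap for trials and models that collected only the headache instruments: it
converts HIT-6 / CH-QLQ scores into EQ-5D utilities (EQ-5D-5L responses
cross-walked onto the UK EQ-5D-3L time-trade-off tariff, range −0.594 to 1)
and SF-6D utilities (derived from the SF-12, floor 0.345).

It is aimed at health economists and trial statisticians, and provides:

* **Four ready-to-apply published mapping algorithms**, one per
  (instrument, utility) pair. Each is a linear rule
  `u = c + Σ_j β_j x_j` over a published covariate set, e.g. the HIT-6 →
  EQ-5D rule `u = 1.9054 − 0.0198 · HIT6`.
* **The estimation machinery to refit mappings on new data** — OLS,
  censored least absolute deviations (CLAD, median regression made
  consistent under the utility ceiling at 1), fractional logit (binomial
  GLM with logit link on the response affinely rescaled to [0, 1]),
  general GLM families, and response mapping (one multinomial logit per
  SF-6D dimension, converted to an expected utility under the tariff).
  All estimators are scikit-learn-style classes (`fit` / `predict` /
  `get_params`) and compose with sklearn pipelines.
* **The validation toolkit**: MSE, MAE, proportions of predictions within
  0.10 / 0.25 of observed (strict inequality), error breakdown across
  bands of the observed utility range, and a three-step selection
  procedure (AIC within family → MSE within AIC-less families →
  validation-sample MSE across families, with the per-band error table
  attached for judgement).
* **A seeded synthetic-cohort generator** that emulates a chronic-headache
  population: one latent severity factor drives all instruments, EQ-5D
  states come from ordinal thresholds so the characteristic bimodal,
  negatively skewed utility distribution (ceiling mass at 1, long left
  tail) emerges from the tariff itself.

## Worked example

Apply the published HIT-6 → EQ-5D algorithm to a three-person file:

```bash
$ cat demo.csv
id,hit6,age,sex
p01,66,40,F
p02,50,55,male
p03,78,62,f

$ headmap map demo.csv --model hit6_eq5d_clad1 --out pred.csv
$ cat pred.csv
id,predicted_utility,model_name
p01,0.5986,hit6_eq5d_clad1
p02,0.9154,hit6_eq5d_clad1
p03,0.3610,hit6_eq5d_clad1
```

Each value is `1.9054 − 0.0198 × HIT6`: a typical patient (HIT-6 = 66) maps
to utility 0.5986; the worst possible headache impact (78) maps to 0.3610.
Because this CLAD rule is linear and unclipped, very mild scores can map
above 1 — pass `--clip` to truncate to the instrument range.

The same thing in Python:

```python
from headmap import Respondent, load_published_model, predict_utilities

model = load_published_model("hit6_eq5d_clad1")
utilities, kept, dropped = predict_utilities(
    model, [Respondent(id="p01", hit6=66)])
# utilities -> array([0.5986])
```

Simulate a cohort, refit and validate:

```bash
headmap simulate --n 349 --seed 0 --out sim.csv
headmap fit sim.csv --source hit6 --target eq5d --covset 1 \
        --estimator clad --out model.yaml
headmap validate sim.csv --model-file model.yaml --out report.csv
```

The report carries n, the prediction summary, MSE, MAE and the within-0.10
/ within-0.25 percentages; `report.csv.ranges.csv` breaks the errors down
by band of observed utility.

## Data notes

The bundled SF-6D tariff and the 5L→3L crosswalk placeholder are clearly
labelled synthetic stand-ins with the correct structure and published
range anchors; supply the licensed tables via `headmap.tariffs.load_tariff`
/ `load_crosswalk` for applied work. See `docs/methods.md` for the models,
their assumptions, and the generator's calibration.
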