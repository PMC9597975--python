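# Methods

## The mapping problem

Headache-specific instruments (HIT-6; CH-QLQ) quantify impact on daily
life but carry no population preference weights, so their scores cannot
enter a QALY. A *mapping* (crosswalk) algorithm is a regression of a
preference-based utility on the instrument scores, estimated on a sample
that completed both, then applied to samples that completed only the
headache instrument. `headmap` implements both directions of this
machinery: applying the four published algorithms, and re-estimating
mappings with the same estimator families and selection procedure.

Two utility targets are supported. EQ-5D utilities follow the UK policy
position: EQ-5D-5L responses are cross-walked to the EQ-5D-3L descriptive
system and valued with the UK time-trade-off tariff (range −0.594 to 1).
SF-6D utilities come from the SF-12-based six-dimension classification
(floor 0.345). Both value sets are additive: full-health constant minus
per-dimension level decrements minus extra terms ("any dimension beyond
level 1", "any dimension at its worst level" — the latter is what opens
the gap below ~0.2 that makes observed EQ-5D distributions bimodal).

## Estimators

All estimators take a design matrix built from one of three covariate
sets — (1) scores only; (2) scores, age, female indicator; (3) set 2
plus score squares, pairwise score interactions (CH-QLQ), score×age
interactions and age² — with complete-case rows only. Respondents with
unknown sex are dropped whenever the female indicator is in the term
list, since no principled imputation exists for a 0/1 contrast.

* **OLS** — baseline linear fit; AIC under a Gaussian likelihood,
  `AIC = 2k − 2ℓ` with k counting every coefficient including the
  constant.
* **CLAD** — observed utilities are right-censored at 1 (ceiling
  effect), which attenuates least-squares slopes. CLAD is median
  regression made consistent under censoring by iterative trimming: fit
  LAD, drop observations whose *fitted* values reach the censoring
  point, refit on the retained set, repeat until the retained set is
  stable (`max_iter` 100). Convergence is exact set stability; an
  oscillation between two retained sets terminates with
  `converged_ = False` and both set sizes recorded. The inner LAD solve
  is statsmodels' median `QuantReg`. No likelihood, hence no AIC.
  Standard errors, when requested, come from a seeded nonparametric
  bootstrap (default 1000 replicates). Predictions are deliberately not
  clipped at 1 by default: the published EQ-5D CLAD rules do predict
  above 1 at mild severity, and clipping is a reporting choice
  (`clip` option) rather than part of the estimator.
* **Fractional logit** — the response is affinely transformed to [0, 1]
  using the *theoretical* instrument bounds ((−0.594, 1) for EQ-5D,
  (0.345, 1) for SF-6D; configurable, since sample-based bounds are the
  other defensible choice), fitted as a binomial-family logit-link GLM
  (quasi-likelihood; valid for fractional outcomes), and predictions are
  back-transformed — they can therefore never leave the instrument
  range.
* **GLM** — configurable family/link. Gamma fits require positive
  responses, so utilities are affinely shifted (recorded in the fit,
  inverted at prediction; `shift="auto"` puts the minimum at 0.05).
  Gamma-identity on utility data frequently fails to converge; this is
  reported through `converged_ = False` with a note, never an exception,
  because a non-converging candidate is still a datum for model
  selection.
* **Response mapping** — one multinomial logit per SF-6D dimension on
  the covariates. Expected utility uses the additive-tariff
  decomposition `E[u] = c − Σ_d Σ_l P_d(l)·dec(d,l) − extras`, with the
  cross-dimension extra terms evaluated under independence of dimensions
  given covariates: `P(any beyond 1) = 1 − Π_d P_d(1)`, and analogously
  for the worst-level term. Independence is exactly the conditional
  structure the per-dimension logits assume, so the expectation is
  internally consistent (and matches brute-force enumeration on toy
  tariffs). Levels never observed in the fitting sample get probability
  zero. A combined AIC (sum over dimensions) is recorded on the mapper;
  the selection procedure nevertheless treats the family as AIC-less,
  advancing all covariate sets to the MSE step, consistent with how the
  direct and response families are compared in practice.

## Model selection

Step 1 keeps, within each family where AIC is defined, the covariate set
with the lowest AIC; AIC-less families advance all three sets. Step 2
resolves those families by MSE — computed in the **estimation** sample
by default (`step2_sample` switches to the validation sample; the
procedure's description leaves this ambiguous and the estimation sample
is the choice that keeps the validation sample untouched until Step 3).
Step 3 ranks the per-family finalists by validation-sample MSE; the
default rule is lexicographic (lowest MSE wins) with each finalist's
error-by-range table attached, because tail performance is a judgement
call the trace should inform, not hide. The full elimination trace is
returned and is deterministic given fits and samples.

## Metrics

MSE and MAE over predicted minus observed; proportions of |error| < 0.10
and < 0.25 use strict inequality (an |error| within 1e-12 of the
threshold is treated as exactly at it, so it is excluded under the
strict rule and included under the lenient `strict=False` variant).
Error-by-range bands are keyed by the *observed* utility, left-closed /
right-open with the outermost bands absorbing anything beyond their
edge; the first SF-6D band is labelled "0.35 – 0.5" but accepts the
instrument floor 0.345, so the bands always partition the sample.

## Synthetic cohorts

No public dataset carries both headache instruments and both utility
measures, so testing and demonstration run on a seeded generator:

* one standard-normal latent severity `z` per respondent; every
  instrument loads on it with independent noise (higher severity:
  higher HIT-6, lower CH-QLQ, worse health states);
* HIT-6 is integer-rounded and clipped to [36, 78]; CH-QLQ subscales
  clipped to [0, 100];
* EQ-5D-3L and SF-6D states come from per-dimension ordinal thresholds
  on `z_d = λ·z + √(1−λ²)·ε_d` (λ = 0.8 EQ-5D, 0.75 SF-6D), and
  utilities are the tariffs applied to those states — the ceiling mass
  at 1 and the left tail below 0.2 are emergent, not imposed;
* demographics: 82% female; age truncated-normal mean 48, sd 15,
  range 18–88; an optional linear age effect on utilities (default 0)
  exists solely so selection experiments have a ground truth where
  covariate set 2 is genuinely better.

Calibration constants live in `data/cohort_defaults.yaml`, not code.
They were tuned by simulation at n = 20 000 against the published
test-sample summaries (means: HIT-6 65.2, CH-QLQ RR/RP/EF
50.3/63.4/48.8, EQ-5D 0.55, SF-6D 0.57) and then frozen. What the
generator does **not** emulate: item-level responses, between-instrument
correlation structure beyond a single factor, missingness patterns,
medication-overuse or headache-frequency covariates. Tests passing on
synthetic cohorts therefore demonstrate the estimators' and procedures'
correctness under a plausible joint structure, not predictive accuracy
on real patients.

`simulate_true_mapping` overwrites the target utility with
`min(censor_upper, c + Xβ + ε)` (Gaussian or Laplace ε) and keeps the
generating parameters, giving parameter-recovery tests an exact oracle.

## Bundled value sets

* `eq5d3l_uk.tsv` — the standard UK EQ-5D-3L TTO coefficients
  (constant 1; decrements per dimension level; 0.081 any-beyond-full
  term; 0.269 worst-level term). Floor −0.594 over the 243 states.
* `sf6d_sf12_synthetic.tsv` — a clearly-labelled **synthetic** SF-6D
  (SF-12) tariff: published structure (dimensions PF/RL/SF/PAIN/MH/VIT,
  levels 3/4/5/5/5/5, worst-level extra term) and published floor
  (0.345), monotone decrements, but not the licensed coefficient table.
  The upstream scoring-variant is additionally ambiguous in the source
  literature; the fixture records its provenance inline. Swap in the
  licensed table via `load_tariff` for applied work.
* The 5L→3L crosswalk placeholder is constructed programmatically
  (piecewise-linear interpolation of the 3L tariff over fractional
  levels, soft indicator weights for the extra terms); it agrees exactly
  with the 3L tariff on the embedded odd-level states, spans −0.594..1,
  and is monotone. `load_crosswalk` accepts the official 3125-row table.

## Numerical choices and edge cases

* Printed published coefficients are stored to exactly four decimals;
  values printed as ±0.0000 are stored as zero. Reconstructing the
  unrounded coefficients is deliberately not attempted, so summary
  statistics computed from the published rules can differ from the
  originals in the third decimal.
* Rank-deficient designs raise immediately rather than silently pseudo-
  inverting; degenerate CLAD input (every response at the ceiling)
  raises; a response-map dimension with a single observed level raises
  naming the dimension.
* Instrument-range validation tolerates 1e-9 of float error at the
  tariff floors.
* All stochastic routines (generator, bootstrap) take explicit seeds and
  default to fixed constants; identical configuration yields
  byte-identical CLI output.

## Known limitations

* The four published algorithms inherit the double-mapping uncertainty
  of their EQ-5D targets (5L responses → 3L tariff → mapping).
* CLAD standard errors are bootstrap-only; no analytic covariance.
* Ordered-logit response mapping (a natural alternative given ordinal
  SF-6D levels) is not implemented.
* The generator's single-factor structure understates the divergence
  between EQ-5D and SF-6D observed in real cohorts, where the
  instruments weight physical versus social functioning differently.
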