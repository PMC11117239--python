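# Methods

## Cohort model and outcome coding

A case record holds one lizard's harmonized covariates (source, species,
sex, life stage, age, histologic diagnosis, malignancy, metastasis,
tumor location, treatment category), its outcome, and survival time in
months from diagnosis. Categorical fields carry an explicit `unknown`
level; in these pooled case series unknownness is informative (unreported
sex, for example, travels with unreported treatment), so it is modeled,
summarized and tested like any other level rather than imputed or
dropped.

Harmonization rules:

* **Malignancy.** Lymphoma/leukemia-type diagnoses (configurable synonym
  list, case-insensitive substring match) are malignant by definition.
  An unambiguous reported behavior passes through. Ambiguous reports are
  malignant only with observed metastasis or local invasion with tissue
  destruction; otherwise `undetermined`. The function is total and
  deterministic; synonym order is irrelevant.
* **Treatment.** Raw modality tokens map through a synonym table to
  modality classes (surgery — including cryosurgery/cryotherapy;
  chemotherapy — including electrochemotherapy, steroids and NSAIDs in
  registry submissions; radiation — including photoradiation and
  strontium; supportive care; diagnostic sampling). Combinations map to
  combined categories; diagnostic sampling alone is *not* treatment
  (maps to `no_treatment`); supportive care counts only without a
  definitive modality. Unrecognized tokens raise an error naming the
  token, rather than being silently pooled. NSAIDs are classed as
  chemotherapy (their registry submission category) although they also
  appear in supportive-care protocols; a bare "supportive care" token
  stays supportive care.
* **Outcome.** y = 1 = non-neoplastic outcome (alive, death from another
  cause), y = 0 = death/euthanasia due to the neoplasm. This convention
  makes positive modeled effects read as favorable, matching the sign
  convention of the effect tables this package emits;
  `positive_is_non_neoplastic=False` flips it. Deaths of unknown cause
  are grouped with the non-neoplastic class by default — they are not
  deaths attributed to the identified neoplasm — with
  `unknown_death="exclude"` as the alternative; either way the choice is
  surfaced in the validation report. Records with wholly unknown outcome
  are excluded from modeling.

The juvenile life stage denotes animals under 3 months; a juvenile with
a recorded age ≥ 3 months is a validation *warning*, not an error,
because harmonized source data can legitimately violate it.

## Boosting engine

Componentwise L2 boosting on the 0/1 outcome with one base-learner per
categorical predictor. Design block Z_j is the n × L_j one-hot indicator
matrix of variable j (every row sums to 1; unknown is a column). The
base-learner is ridge-penalized least squares,
c_j = (Z_j'Z_j + λ_j I)^{-1} Z_j' r, with λ_j solving
tr[Z_j (Z_j'Z_j + λ_j I)^{-1} Z_j'] = df by bracketed root finding
(tolerance 1e-8). Fixing the hat-matrix trace equalizes the selection
chances of factors with very different level counts — the categorical
"random-effects" base-learner construction. Because indicator columns
are mutually orthogonal, Z'Z is diagonal with level counts, the trace is
Σ_l c_l/(c_l + λ), and the solve reduces to per-level
`group_sum(r)/(count + λ)`; a dense-matrix reference loop in the test
suite confirms the closed form to 1e-10 across random instances.

The loop: offset = mean(y); for m = 1..mstop, fit all blocks to the
current residuals at their λ(df), select the block with minimal fitted
RSS (ties → lowest block index, deterministic), accumulate ν times its
coefficients, update residuals. The residual sum of squares is
non-increasing for any ν ∈ (0, 1] (each update removes
ν(2−ν)·c'Z'r ≥ 0 from the RSS). Reported effects are the accumulated
per-level coefficients; never-selected variables report exact zeros.

Defaults: mstop = 100, ν = 0.1, df = 4, squared-error loss — the
conventional defaults of model-based boosting frameworks; nothing in the
data dictates them and all are exposed in configuration. For blocks with
rank < df (three-level factors like sex), the effective df is
min(df, rank), i.e. λ = 0: such blocks are simply unpenalized, which is
the natural limit of the construction. Indicator columns are *not*
centered; the ridge penalty absorbs the intercept confounding. This is a
known divergence risk against implementations that center base-learners,
and is one reason the package treats effect *values* as
cohort-conditional quantities rather than portable constants.

Age is summarized descriptively but not boosted: the eight modeled
predictors are categorical, and a continuous base-learner family is out
of scope.

## Permutation inference

Null distributions are per level: the full boosting model is refitted on
B uniformly permuted copies of y (design fixed; permutation breaks every
covariate–outcome association while preserving all marginals), and each
level's B refitted effects form its null sample. The default test is the
two-sided absolute-value tail rule with finite-sample correction,
p = (1 + #{|null_b| ≥ |obs|})/(B + 1), exactly valid under
exchangeability at any B. A percentile-interval rule (observed outside
the null's [α/2, 1−α/2] quantiles) is available behind
`tail_rule="percentile"`; the absolute rule is the default for its exact
finite-sample guarantee. Significance requires p < α (default 0.05) and
a level sample size of at least `min_n` (default 2); singleton levels
are reported with significance suppressed. No multiplicity correction is
applied across levels — the procedure screens per level, and readers
should treat the flags accordingly.

B defaults to 2000. The permutation refits are vectorized across
permutations (`fit_boost_multi`), fitted column-for-column identically
to the scalar path (tested to 1e-12), which keeps a B = 500 study on a
274-record cohort under half a second. Permutations are unstratified by
source; stratification would be a one-line extension but is not the
default.

## Survival analysis

Product-limit estimation with right censoring: Ŝ(t) = Π_{t_i ≤ t}
(1 − d_i/n_i), deaths before censorings at tied times, time origin at
diagnosis (time-0 events are legal). Point estimates and risk tables
come from lifelines' `KaplanMeierFitter`; the package adds the
cumulative Greenwood sum V(t) = Σ d_i/(n_i(n_i − d_i)) and the
complementary log-log 95% band
exp(−exp(log(−log Ŝ) ± z·√V/|log Ŝ|)), which stays inside [0, 1] and
degenerates to the point estimate at Ŝ ∈ {0, 1}. Median survival is the
smallest t with Ŝ(t) ≤ 0.5, undefined if never reached.

Group scheme: (malignant | benign) × (neoplasia without treatment |
neoplasia with treatment | died of non-neoplastic cause). Deaths of
unknown cause join the non-neoplastic-death stratum, consistent with the
outcome coding; still-alive animals are censored inside their
treatment-status stratum; records with unknown survival time are
excluded and counted. Log-rank tests and Cox models are deliberately
absent — the analysis contrasts curves descriptively.

One subtlety worth recording: adding a *new* subject censored after all
events does change earlier Ŝ values (it enlarges every earlier risk
set). The invariant that actually holds, and is tested, is that moving
an existing late censoring even later changes nothing.

## Synthetic cohort generator

The generator emulates the study-design features the pipeline depends
on: a 274-record cohort split ~219/55 between a literature source and a
registry source; per-source categorical marginals taken from the
reconstructed printed tables (so unknown sex ≈ 138/219 in the
literature arm, green iguanas 55/219, surgery-only 25/219); a binary
outcome drawn from a logistic (default) or linear-probability link on
baseline + summed per-level true effects; exponential event times with
group means (untreated neoplasia death 2 mo, treated 10 mo,
non-neoplastic death 20 mo, censoring 24 mo — chosen to reproduce the
qualitative ordering "untreated neoplasia dies fastest" at the
magnitudes of the printed medians); and a 25% still-alive censoring
fraction. Default injected effects are ±1 on the log-odds scale for
treatment (surgery/radiation protective, no-treatment harmful) and
benign behavior, mirroring the direction of the reported associations.

What it does *not* emulate: covariates are independent across variables
(no species × diagnosis structure — the printed sources give only
marginals and each variable enters the model through its own
base-learner), ages are not generated, event times are memoryless, and
censoring is independent of covariates. Passing tests on synthetic
cohorts therefore certify the *procedure* (calibration, power,
ordering), not any claim about the restricted real records.

Randomness: one root `SeedSequence`, spawned into named per-stage
substreams (source, covariates, outcome, survival), so cohorts are
bitwise reproducible for a given seed.

`lizonc.datasets` is distinct from the generator: it deterministically
reconstructs 219 + 55 records whose *marginals equal the printed
aggregates exactly* (species union 59 + 20 − 14 = 65, metastasis present
6.6%, lymphoma 18/219, surgery 25 and 17, literature survival mean
20.0/median 0 over 108 known times, registry 10.3/2 over 13). The joint
assignment of values to records is an arbitrary deterministic
convention. Printed numbers that contradict each other are resolved in
favor of the running text and logged machine-readably in
`datasets.DISCREPANCIES`. Age summaries are matched only approximately
(range and rough center), as no analysis consumes them.

## Numerical and design choices

* Ridge λ via `scipy.optimize.brentq` on a monotone trace function;
  upper bracket grown geometrically; df = rank short-circuits to λ = 0.
* RSS computed as ‖r‖² − 2c'Z'r + Σ c_l² n_l (no dense residual
  materialization); ties in block selection are impossible to observe in
  floating point except on degenerate data, and resolve to the lowest
  block index in both the engine and the reference loop.
* Percent cells round half-up (decimal arithmetic, not banker's
  rounding) to one decimal; headline figures to whole percents.
* Unknown CSV tokens: empty cell, `NA`, `N/A`, `nan`, `unk`, `unknown`
  (case-insensitive) normalize to the unknown level; `undetermined` is
  the unknown spelling for malignancy, `unknown_treatment` for
  treatment.
* Degenerate inputs: empty cohorts are errors for fitting and survival
  estimation, identity cases for I/O and summaries; constant outcomes
  yield exact-zero effects; B = 0 yields empty null arrays and refuses
  to produce p-values.

## Study sizes used in the test suite

The statistical guarantees are exercised at sizes chosen to give tight
Monte-Carlo error while keeping the suite quick: type-I-error
calibration uses 100 replicate global-null cohorts of n = 274 with
B = 500 permutations (mean per-level false-positive rate required in
0.05 ± 0.02); power uses 50 replicates of n = 300 with one +0.3
probability-scale effect on a level carried by ≥ 30 animals (≥ 80%
detection, correct direction); engine-vs-reference equivalence uses 25
random instances with n ≤ 50 and up to 4 blocks at 1e-10; the survival
ordering study uses 50 replicate cohorts. The same studies, at the same
sizes, are what `scripts/acceptance.py` reruns and reports.

## Known limitations

* Effects are probability-scale shrunken associations under one
  hyperparameter setting, not causal treatment effects; cross-validated
  mstop selection is out of scope.
* The per-level permutation flags carry no family-wise error control.
* The generator's independence and exponential assumptions above.
* Logistic-loss boosting is not implemented; squared-error on 0/1
  outcomes is the supported family.
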