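# Methods

This note documents the models and procedures implemented in
`cogharmon`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices that
matter for reproducing results.

## Data model

A *visit table* is a long-format frame, one row per participant-visit,
over a *test catalog*. The catalog records, per neuropsychological test:
score range, direction (+1 higher-is-better; −1 for the time-scored
TMT-B), cognitive domain (episodic memory, executive function, language,
or global for the MMSE), whether the raw score is integer-valued, and
the set of cohorts that administer it. The default catalog covers 16
tests over three cohorts (AIBL, ADNI, OASIS naming the study designs
being emulated); several tests are administered by only one or two
cohorts and are therefore structurally missing — 100% absent by design —
elsewhere.

Merging concatenates per-cohort tables, prefixes participant ids with
their cohort, and forces every out-of-panel test to missing. Inclusion
screening drops visits that carry no test scores (demographics/CDR-only
records), participants with a non-AD-spectrum or absent diagnosis flag,
and participants left with fewer than 3 visits (configurable); visit
indices and the per-participant time origin are then recomputed, so
`time_years` is measured from each participant's first retained visit.

Clinical–pathological groups are assigned from the baseline Centiloid
value and CDR global score and held fixed over a participant's visits:
amyloid positivity is Centiloid > 25 (strict; 25 itself is negative),
CDR ≥ 1 is collapsed to one category, amyloid-negative participants with
CDR > 0 and participants without a Centiloid value are excluded from
group analyses.

## Iterative random-forest imputation

Every missing cell — sporadic or structural — is an imputation target.
The algorithm:

1. Seed missing entries with the column mean over observed values
   (median for integer-valued tests, mode for categorical covariates).
2. Visit target columns in ascending order of missingness fraction. For
   each, fit a random forest on the rows where the column was originally
   observed (regression for scores, classification for categorical
   covariates) using the other predictors — age, sex, years of
   education, CDR (categorical), APOE ε4, dataset-of-origin, and all
   other test scores — and overwrite the originally-missing rows with
   predictions.
3. After each full sweep compute the convergence statistic
   Δ = Σ(new−old)²/Σnew² over imputed continuous cells (proportion
   changed for categorical cells). Stop when Δ first increases,
   returning the previous sweep's values (the classic stopping rule), or
   at `max_iterations` (default 10). A relative-change `threshold` rule
   is provided for sensitivity analysis.

Defaults follow the reference implementation of this algorithm: 100
trees, minimum leaf 5, feature subsampling one-third for regression and
√p for classification. Imputed scores are clipped to the catalog range
(`clip_to_range`, on by default); rounding of imputed discrete scores
(`round_discrete`) is off by default so that validation statistics are
computed on unrounded imputations, and exposed for sensitivity analysis.
Rows are treated as independent observations; time between visits is not
modelled — age and CDR at each visit proxy for disease stage.

**Seed policy.** A master seed is combined with the column name (CRC-32)
and sweep number through `numpy.random.SeedSequence` to give each forest
its own substream, so results are bit-reproducible and independent of
the order in which columns happen to be visited. With a single missing
cell and `max_iterations=1` the imputer is exactly one forest fit, which
is what the oracle-equivalence test checks bit-for-bit.

Demographic covariates with missing values (e.g. APOE) can be imputed by
the same loop via classification forests. Fully unobserved columns
(outside the structural design, which always has cross-cohort donors)
raise an error naming the column.

## Hold-out precision protocol

For each test: mask round-half-up(30%) of its observed values uniformly
at random (one test at a time; all other columns untouched), re-run the
*entire* imputation on the masked table, and score the withheld cells:

* **MAE** — mean |imputed − truth|;
* **outlier rate** — % of cells with |imputed − truth| > 2.5 × SD, where
  the SD is that of the test's observed values in the full table.

Repeats (default 50; per-repeat seeds derive from the master seed, the
test index, and the repeat index) give a mean ± SD for both. The
benchmark for "acceptable" MAE is natural test-retest variability: the
**maximum discrepancy score** (max − min observed score per participant,
requiring ≥ 2 observations) summarized over participants who are
amyloid-negative with CDR 0 at every visit. The report mirrors the
standard precision-table layout: range, actual mean ± SD, max-discrepancy
mean ± SD and range, MAE mean ± SD, outlier % mean ± SD, plus verdict
flags. Per-repeat values are retained so aggregates can be recomputed
exactly; failed repeats are recorded and skipped rather than aborting.

## Composite scores

Composites follow the standard four-step recipe: fit per-test norms
(mean, sample SD with n−1) on the *baseline* visits of the cognitively
unimpaired reference group — CDR 0 at baseline, amyloid-agnostic, with
an optional amyloid-negative restriction; z-score every value against
those norms; reverse the sign for time-scored tests so higher z is
always better; average the member z-scores with equal weights. Defaults:
PACC = {MMSE, LMII, CVLT-II delayed recall, digit symbol coding};
episodic memory = {LMII, CVLT-II delayed recall}; executive function =
{TMT-B, digit symbol coding}; language = {BNT no cue, category fluency
animals}. Apart from the PACC, no test belongs to more than one domain
composite. Composites are defined on harmonized (complete) tables only,
so structurally-imputed tests have defined values in every cohort; the
PACC's MMSE enters as a plain z-score (no rescaling).

## Longitudinal mixed-effects validation

Per composite:

    composite ~ time × group + age_c + sex + edu_c + cohort
                + (1 + time | participant)

fitted by REML with a correlated 2×2 random-effects covariance. Age and
education are centered at the sample mean, so the "marginal mean at time
zero" is evaluated at covariate means; cohort and sex are averaged with
equal weights over their levels (a balanced grid). Visits beyond the
follow-up window (default 5 years) are dropped with participants
retained; participants need ≥ 2 remaining visits; the reference group is
Aβ– CDR 0.

Numerical choices: the likelihood is optimized with conjugate gradients
first (it handles the near-boundary random-slope variance well), then
Powell; if neither converges to a positive-definite covariance the model
is refitted with independent intercept and slope and the result flagged
(`re_structure="independent"`). Estimated marginal means/trends and
their delta-method SEs are linear functionals of the fixed effects;
contrasts vs the reference give Wald z and p-values.

**Cohen's d.** No standardization is canonical here, so it is isolated
in one place: intercept contrasts are divided by the subject-level SD
√(random-intercept variance + residual variance); slope contrasts are
multiplied by the follow-up window (the model-implied difference in
change at the horizon) and divided by the same SD. Benjamini–Hochberg
FDR is applied over the full family of intercept and slope contrasts
across all composites fitted in one run.

## Synthetic cohort generator

The generator is the package's stand-in for the access-restricted parent
cohorts; it defines the study conditions every end-to-end test runs
under.

* **Groups.** Each participant draws a clinical–pathological group with
  probabilities 0.380/0.166/0.316/0.137 (proportional to the reference
  cohort composition). The group fixes CDR (0/0/0.5/1), the baseline
  latent deficit (0/−0.2/−1.5/−2.8 reference-SD units) and the latent
  slope (0/−0.05/−0.25/−0.45 per year). Amyloid values are drawn below
  25 CL for the negative group and above 25 otherwise, so labels derived
  from Centiloid agree with the generating group.
* **Latents.** One latent per domain (memory, executive, language);
  participant random intercepts (SD 1) and slopes (SD 0.05/yr) share 60%
  of their variance across domains, which is what makes a structurally
  missing test learnable from same- and other-domain tests. The global
  latent (for the MMSE) is the normalized mean of the three.
* **Scores.** score = mean + direction × scale × latent + N(0, σ),
  clamped to the instrument range and rounded if integer-valued. Per
  test, (mean, whole-sample SD, retest noise σ) mimic the marginal
  distributions and test-retest variability of these instruments in
  elderly research cohorts; σ is set to about half the cognitively
  unimpaired maximum-discrepancy magnitude (the expected range of 3–5
  Gaussian draws is ≈ 2σ), and the affine scale to
  √((SD² − σ²)/2) — the divisor being the total latent variance, unit
  within-group plus ≈ 1.0 between-group mixture variance under the
  default proportions and deficits — so the generated group *mixture*
  reproduces the whole-sample SD. Clamping induces realistic floor and
  ceiling effects (e.g. MMSE at 30, LMII at 0 in the dementia group).
* **Design.** Visit cadence 1.5 / 0.5 / 1.0 years and sporadic
  missing-at-random rates 5% / 19% / 2% for the three cohorts (mildly
  inflated with CDR), 3–5 visits per participant, cohort-specific
  age/education/sex distributions, APOE carriage increasing with group
  severity. Missingness depends only on cohort and CDR — never on the
  unobserved score — matching the imputation model's assumptions.

Ground truth records every pre-masking score, including tests outside a
cohort's panel, plus the latent values, so structural-imputation error —
unobservable on real data — can be scored directly.

**What the generator does not emulate:** practice effects, attrition by
decline (MNAR dropout), site/scanner effects on Centiloid, CDR
progression within participants, domain-specific deficit profiles, or
skewed/heteroscedastic score distributions. Passing tests therefore show
the machinery is correct and well calibrated under a plausible
latent-trajectory model — not that real-data imputation error will match
these numbers.

## Problem sizes and test design

Default generator size is 100 participants per cohort, chosen so the
full pipeline (generate → merge → impute → validate → composites →
mixed models) completes in minutes on one CPU. The end-to-end checks
use: structural-recovery runs at 500 participants/cohort on a reduced
nine-test catalog with exactly one never-administered test per cohort
(CVLT-II delayed / RAVLT delayed / SRT-FREE) and same-domain donors
everywhere; hold-out validation of all 16 tests at 2 repeats with
50-tree forests; mixed-model coverage on 100 replicates simulated
directly from the LME data-generating process (the generator's range
clamping attenuates slopes in the most impaired group, so coverage is
assessed against the model's own truth, while ordering, significance,
and null behaviour are assessed on generator output); and ~20
null-generator replicates for type-I control.

## Known limitations

* A single completed dataset is produced; imputation uncertainty is not
  propagated into downstream models (no multiple imputation).
* Within-participant correlation is ignored during imputation (visits
  are independent rows), as in the underlying method.
* The first-increase stopping rule can run one extra sweep on noisy
  deltas; the iteration cap bounds this.
* Cohen's d for slope contrasts depends on the follow-up-window
  convention documented above; alternative standardizations change its
  magnitude but not the ordering or inference.
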