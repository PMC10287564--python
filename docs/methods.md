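# Methods

This note documents the statistical models implemented by `alcophewas`,
the generative model behind its synthetic cohorts, the numerical choices
made where several were defensible, and what the test suite does and does
not demonstrate.

## Survival model

All hazard-ratio estimation uses Cox proportional-hazards regression with
**age as the underlying time scale** and delayed entry at baseline age
(left truncation). Baseline hazards are stratified by 5-year age-at-risk
band × study area over the 35–84 window; follow-up is first split at band
boundaries (Lexis expansion) so each risk interval lies in a single
stratum. Competing deaths are handled by censoring at death from any cause,
i.e. all estimates are cause-specific hazard ratios. Ties are handled by
the Efron approximation, which is less biased than Breslow for
hospital-registry data where event ages can coincide. The partial
likelihood is maximized by Newton–Raphson with step halving; convergence is
declared when the max-norm of the score falls below `1e-8` per event (the
score and its floating-point noise both scale with the number of events) or
the Newton step becomes negligible, with a maximum of 50 iterations and an
explicit convergence error otherwise. The engine reproduces lifelines'
`CoxPHFitter` to ~1e-9 on coefficients and standard errors (asserted in the
tests, which use lifelines as an independent cross-check) and a brute-force
maximization of the hand-written Efron partial likelihood to 1e-6 on tiny
datasets.

Exact invariance of the estimate under duplicating every record holds for
the Breslow tie rule but only approximately under Efron (duplication
creates ties); the corresponding test asserts agreement to 5e-3.

**Floating absolute risks.** For categorical exposures, floated variances
λ_k give every level (including the reference) its own CI such that
`var(logHR_i − logHR_j) ≈ λ_i + λ_j`. The default is the heterogeneity
(covariance) method: λ_ref is the mean off-diagonal covariance of the
non-reference estimates and λ_i = V_ii − λ_ref; in the zero-covariance
limit this is exact. If any λ is negative the package falls back to an
iterative minimax fit that minimizes the maximum relative error across all
pairwise difference variances. With only two levels the method is
degenerate and the variance is split in inverse proportion to level sizes
(equally when unknown). Reconstruction error is asserted ≤ 10% on simulated
six-level fits.

**Dose–response and regression dilution.** Continuous dose–response among
current drinkers is per 280 g/week (men) or 100 g/week (women). Because a
single baseline measurement understates the association with long-term
(usual) intake, the log HR and its standard error are divided by the
regression-dilution ratio (default 0.53), estimated by the McMahon–Peto
method: quintile groups of baseline intake, group means of baseline and
resurvey intake, least-squares slope of the latter on the former, with a
participant-level bootstrap CI. Quintiles are the method's conventional
grouping; the estimator is scale-invariant.

## Exposure derivation

Weekly grams = frequency (median of the reported interval: 1.5, 4 or 6.5
d/week) × Σ over beverages of typical-day volume (ml) × alcohol content by
volume (beer 4%, grape wine 12%, rice wine 15%, weak spirits 38%, strong
spirits 53%) × ethanol density. The density is not part of the v/v figures
and is set to **ρ = 0.79 g/ml** (the standard 0.789 rounded; configurable).
Reported volumes are interpreted as per typical drinking day. Consumption
categories use left-closed upper intervals (a man at exactly 140 g/week is
"140–279"). "Daily drinking" maps to the 6–7 d/week frequency category;
"spirit drinker" means any positive weak/strong-spirits volume;
heavy-episodic drinking is strictly greater than 60 g (men) / 40 g (women)
per occasion. Drinkers in the "certain seasons" and "monthly but not
weekly" frequency classes count as occasional. When a numeric intake is
needed for non-current drinkers (instrument construction, 2SLS stage 1),
occasional drinkers contribute 5 g/week and non-drinkers 0.

## Endpoint curation

Endpoints are sets of three-character ICD-10 codes with a chapter and a
WHO-alcohol-related flag, shipped as an editable CSV covering the named
endpoints of interest; codes not individually retained pool into a
per-chapter "less-common" endpoint. The ≥ 80-case rule counts distinct
current-drinker participants with a first event (analyses are first-event
Cox), separately by sex. Perinatal (XVI) and congenital (XVII) chapters are
always excluded; pregnancy (XV) is excluded in men. Aggregate endpoints use
each participant's earliest event over the union of member code sets.
Calendar dates are not modelled: follow-up is baseline age + elapsed years.

## Phenome scan

Each endpoint is analyzed twice: ever-regular vs occasional drinkers (with
non-drinkers as their own level, occasional as reference) and continuous
dose–response among current drinkers. Benjamini–Hochberg FDR is applied
within ICD-10 chapter, separately per analysis — the two analyses answer
different questions, so each forms its own family (a pooled family is a
one-line change). WHO-flagged endpoints are tested at nominal p < 0.05
(they are prior hypotheses); all others require FDR-adjusted p < 0.05.
Endpoints whose fits fail are reported as NA, never dropped silently. The
chapter summary counts an endpoint once if significant in either analysis;
endpoints significant in both directions are flagged as conflicts.

The power utility simulates current-drinker cohorts at a given case count,
with the association attenuated by the RDR exactly as in the real analysis
(the hazard ratio argument refers to usual intake, the test is on the
baseline measurement), and reports Monte-Carlo power with a Wilson CI.
Replicate streams are indexed by seed so scenarios at different case counts
share common random numbers.

## Genotype-area Mendelian randomization

Cell means over the 9 genotype combinations × areas are computed from men
only, taking current drinkers at reported g/week, occasional drinkers at
5 g/week, non-drinkers at 0, and excluding ex-drinkers (their baseline
report does not reflect long-term intake). Cells collapse to C1–C6 at
cutoffs 10/25/50/100/150 g/week, left-closed above (a cell mean of exactly
150 is C6). Every genotyped participant — ex-drinkers and women included —
is assigned from genotype and area alone; the assignment never touches
individual drinking reports (asserted as an invariant). Cells with no
eligible men borrow the same genotype combination's mean pooled across
areas and are flagged; this pooling rule is the package's own convention.

The causal slope is estimated within each area: floated category log HRs
(reference = lowest-mean category present, adjusted for genomic PCs,
stratified by age band) are regressed on the area's category mean male
intakes by weighted least squares with a **free intercept** and weights
1/floated-variance; the floating construction is what makes ignoring
the residual correlation between category estimates acceptable. A
`weight="conventional"` switch instead runs a full-covariance GLS on the
non-reference contrasts. Area slopes are combined by fixed-effect
inverse-variance weighting (meta-analytic, scale fixed at 1), reported as
HR per 280 g/week of genotype-predicted mean male intake. Sensitivity
variants: a single pooled fit stratified by age × area ("area-adjusted")
and a deliberately unstratified fit that is exposed to population-structure
confounding. Sex heterogeneity is a 1-df chi-squared on the male-female
slope difference; the female analysis regresses female category log HRs on
the *male* cell means, optionally restricted to female non-drinkers.

Two-stage least squares: stage 1 regresses the numeric baseline intake on
category indicators + area + PCs in men (ex-drinkers excluded), reporting
the categories' joint F (< 10 flags a weak instrument); stage 2 fits the
stratified Cox model on genotype-predicted intake for all participants of
the analyzed sex; standard errors come from a participant-level bootstrap
over both stages.

Note an inherent feature of the category method: because ex-drinkers sit in
the categories with zero current intake while being excluded from the cell
means, the expected category contrast is slightly smaller than the cell-mean
contrast (about 15% under the default generator), so the IVW slope mildly
understates the planted per-gram effect. This mirrors the method itself,
not an implementation artifact; at the event counts used in the tests the
effect stays well inside nominal coverage.

## Burden

The mean cumulative count
`MCC(t) = Σ_{u≤t} Ŝ(u⁻) · d(u)/n(u)` uses the Kaplan–Meier estimator of
death-free survival (lifelines, with delayed entry), episode counts d(u)
and the at-risk count n(u) just before u. Episodes tied with a death at the
same age are counted before the death is processed. Curves are reported on
a 1-year grid over 35–84, unstandardized (a standardization hook would act
on the group definition); no bootstrap CIs.

## Synthetic cohort generator

The generator is first-class, tested code, and defines the study conditions
used throughout:

- **Demographics**: 41% male, ages ~N(52, 10.7²) truncated to 30–79, ten
  areas of equal size.
- **Genotypes**: per-area binomial(2, p) dosages — exactly Hardy–Weinberg
  within area — with linear "north–south" gradients (spread 0.20) around
  overall A-allele frequencies 0.21 (locus 1) and 0.69 (locus 2). Genomic-PC
  surrogates are deterministic cosine area loadings plus unit noise.
- **Drinking**: marginal status fractions (non/ex/occasional/current) of
  20/9/38/33% in men and 64/1/33/2% in women. Genotype multiplies the
  ever-regular probability in men (locus 1: 1/0.35/0.03 by A dosage,
  locus 2: 1/0.85/0.65); a base probability computed analytically from the
  genotype distribution keeps the marginals exact in expectation. Mean
  intake among male current drinkers is 286 g/week (women 116), scaled by
  genotype (locus 1: 1/0.70/0.35; locus 2: 1/0.90/0.80) and renormalized so
  the marginal mean is preserved. By default genotype has **no** effect on
  female drinking — the pleiotropy-null configuration; both female factor
  sets are configurable. 62% of drinkers report 6–7 d/week. Questionnaire
  volumes are constructed to reproduce the baseline intake exactly under
  the grams formula; beverage mix is spirits-dominant.
- **Measurement model**: the *reported* baseline intake B is log-normal
  within genotype (log-s.d. 0.8, capped at 1500 g/week — questionnaire
  fields are bounded, and an uncapped log-normal tail combined with an
  exponential hazard occasionally produces absurd event counts). Usual
  intake regresses toward the genotype mean m:
  `U = m + r·(B − m) + δ`, `δ ~ N(0, (0.5(1−r)m)²)`, with resurvey
  measurements `R = U + ε` of the same noise scale. This construction makes
  `E[U | B]` exactly linear with slope r, so the grouped McMahon–Peto
  estimator, the attenuation of the linear Cox term in B, and the
  configured target r = 0.53 all coincide (empirically: MP ≈ 0.54, Cox
  attenuation ≈ 0.54). Simpler multiplicative or additive noise models do
  *not* have this property — their MP slope, covariance ratio and Cox
  attenuation diverge from each other — which is why the linear
  conditional-mean construction was chosen. A target of r = 1 reproduces
  zero within-person variation exactly. 5% of participants attend
  resurveys.
- **Outcomes**: each configured endpoint is a Poisson episode process with
  rate `baseline_rate × area multiplier × exp(β·U/280)`; competing
  mortality is an independent exponential (default 0.008/year) and censors
  everything at death or at 12 years of follow-up. Area baseline-hazard
  multipliers follow an exp-linear gradient (log-spread 0.5) oriented so
  heavier-drinking areas also have higher disease rates — deliberate
  area-level confounding of the genetic instrument, which the
  area-stratified MR must remove and the unstratified variant must absorb.
  The sick-quitter hazard multiplier for ex-drinkers defaults to 1 (off) so
  the null generator is exactly null; it is configurable for robustness
  studies. Default endpoint effects span several chapters with hazard
  ratios from 0.85 to 2.30 per 280 g/week, including exact nulls.

**What the generator does not emulate**: calendar time and secular trends,
correlated measurement error, genotype–environment interaction,
dependence between mortality and endpoint processes (independent by
default), within-chapter correlation of endpoint processes, and
confounding through the behavioural covariates (education, smoking, income
etc. are correlated with drinking but carry no hazard effect, so adjusting
for them is exercised but not stress-tested). Passing tests therefore
demonstrate internal statistical correctness of the estimators under the
stated generative assumptions, not robustness to every failure mode of
real registry data.

## Problem sizes in the test suite and acceptance script

Replicate counts and cohort sizes were chosen to make Monte-Carlo noise
small relative to the asserted margins while keeping the default `pytest`
run comfortably under half an hour on one CPU: dose–response coverage uses
100 replicates of n = 50,000 (planted HR 1.5, ~1,700 events each); MR
recovery uses 60 replicates (planted HR 1.4, ~700 male events each, 30 of
them also fitted unstratified); pleiotropy calibration uses 50 replicates
of a common outcome (~4,700 male events); null-scan calibration uses 5
replicates of an all-null 13-endpoint catalog at n = 20,000; the RDR check
uses 5,000 resurveyed drinkers. Coverage assertions allow for binomial
noise at these replicate counts (e.g. ≥ 51/60 where the nominal rate is
95%). `scripts/acceptance.py` runs one default cohort of n = 50,000 and
finishes in about a minute.

## Known limitations

- Floated variances are attributed per level; rank-deficient or heavily
  unbalanced designs may trigger the minimax fallback, which is slower and
  approximate by construction.
- The MR meta-regression treats category means as fixed; sampling noise in
  small genotype-area cells adds a small attenuation on top of the
  ex-drinker effect discussed above.
- 2SLS standard errors require enough bootstrap replicates (default 100) to
  stabilize; the point estimate does not depend on them.
- The MCC implementation reports no confidence bands.
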