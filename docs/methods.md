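# Methods

## The clock

PhysiAge is an ordinary least-squares prediction of phenotypic age from
sex, fasting glucose (mmol/L), average daily steps and systolic blood
pressure (mmHg), re-anchored to the age axis by the per-age normalization
factor NF(a) = median raw prediction among training participants of
integer age a. The re-anchoring makes the median deltaAge identically zero
at every populated training age — an algebraic identity the test suite
checks exactly. NF is the raw per-age median with no smoothing; ages with
no training participants are filled by linear interpolation between the
nearest populated ages (endpoints take the nearest value) and flagged.
Ages above the tabulated maximum are served the maximum age's factor
(clamping, logged); participants recorded as 85+ are scored at a default
age of 85 this way, since their exact age is unknown and they are excluded
from fitting.

Preparation mirrors the intended use on survey data: rows with a zero or
missing entry in any required column are excluded (sex = 0 is a valid
code, not a zero entry), ages restricted to 20–84 with 85+ rows held
separately, and step counts outside the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles over the whole population,
linear-interpolation quantiles) removed. The 80/20 train/test split is
stratified by sex with per-stratum training counts rounded half-up, driven
by a named integer seed of numpy's PCG64 generator.

## Phenotypic age

The training target maps nine blood biomarkers plus calendar age through a
linear predictor xb, a Gompertz ten-year mortality risk
M = 1 − exp(−exp(xb)·(exp(120γ)−1)/γ), and an outer log transform back to
years. The default coefficients are transcribed reference values
(`src/physiage/data/phenoage_levine.yaml`, externally sourced and labeled
as such); every self-contained test uses synthetic configs or round-trips
rather than those constants. CRP enters on the natural-log scale as an
explicit `crp_ln` field so no hidden transform sits inside the operation.
All units are declared in the config and checked at compute time; an
out-of-domain mortality score raises rather than returning NaN.

Because the mapping is strictly increasing in xb, it inverts in closed
form: given a target phenotypic age, the two outer transforms are
inverted analytically and one free biomarker (default: red-cell
distribution width, whose weight is comfortably large) absorbs the
residual linearly. Round-trip error is at floating-point level, far below
the 1e-6-year contract.

## Synthetic cohorts

The generator exists to make every downstream stage testable with known
ground truth; it emulates the *calibration targets* of the source survey
population, not its full joint distribution.

* **Ages** are uniform over the integers 20–84. The real survey's age
  pyramid is not copied: the rank-correlation targets, not marginal
  realism, drive downstream behaviour.
* **Physiology** is Gaussian around a linear-in-age mean. For each
  variable the slope is solved from
  corr = slope·σ_age / sqrt(slope²·σ_age² + σ²) so the realized rank
  correlation with age hits its target (glucose 0.400, systolic BP 0.474,
  resting heart rate −0.224, diastolic BP −0.151, BMI 0.075, steps
  0.029). A numerical check at n = 2×10⁶ shows that with the uniform age
  marginal this Pearson identity lands the *Spearman* correlation on
  target to within ~0.003, so no copula correction is applied. Age-20
  intercepts and residual SDs sit at clinically typical values (e.g.
  glucose 4.6 ± 1.1 mmol/L, systolic 112 ± 12 mmHg, steps 9000 ± 4800).
  Plateaus at older ages are deliberately not modeled.
* **Latent phenotypic age** has two modes. `age_anchored` (default) draws
  phenoage_true = age + N(0, 7.4): with the uniform-age SD of ≈18.8 years
  this yields corr(phenoage_true, age) ≈ 0.93, matching the observed
  phenotypic-age/age relation. `planted_linear` draws it from the
  published-coefficient linear predictor plus N(0, 12), so a refit
  recovers known coefficients. In both modes the participant's biomarker
  panel is built by exact inversion, so recomputing phenotypic age from
  the panel reproduces the latent value. Note the age-anchored mode's
  deviation from age is independent of physiology by construction, so
  deltaAge carries no mortality signal there; demonstrations of
  deltaAge–mortality separation use the planted-linear mode.
* **Mortality** is a Gompertz-type hazard constant over the 10-year
  follow-up: h = h0·exp(b·(phenoage_true − 50)), defaults h0 = 0.004/yr
  and b = 0.08/yr chosen to give roughly 10% ten-year mortality over the
  cohort, comparable to the survey's follow-up. h0 = 0 is allowed and
  means nobody dies. An optional glucose term in the log-hazard creates
  cohorts where glucose carries mortality information beyond phenotypic
  age — the construction behind the ablation tradeoff demonstration, in
  which omitting glucose improves test RMSE yet weakens the
  alive/deceased separation.
* **The 4-group cohort** defaults to sizes 17/19/17/6 (young 20–30;
  trained, normal, impaired older adults 65–80). Group means are ordered
  trained > normal > impaired for steps and impaired > normal > trained
  for glucose and systolic BP, so the deltaAge ordering
  trained < normal < impaired emerges when scored; magnitudes are not
  tuned to any reported medians.
* **The metabolome** draws 113 log-normal metabolites over a metabolomics
  subset of 48 samples (12 young, 17 trained, 16 normal, 3 impaired; the
  36 older adults form the deltaAge screen). Planted deltaAge
  correlations use a Gaussian copula on the older adults' deltaAge ranks
  with latent correlation 2·sin(πρ/6); defaults plant citrate −0.61,
  isocitrate −0.47, malate −0.35, glucose +0.36 and ribose 5-phosphate
  −0.45. A log-scale shift per ordinal health-group step gives the
  intersection metabolites (malate, ribose 5-phosphate, glucose) a group
  signal as well, and nicotinamide carries a female-only association.
  Unplanted metabolites are independent noise, which keeps the screens'
  type-I error at the nominal 5%.

What the generator does **not** emulate: survey sampling weights,
accelerometer epoch processing, non-Gaussian biomarker tails, age
plateaus, correlated biomarker panels beyond the planted structure, or
informative censoring. Passing tests therefore demonstrate that the
pipeline recovers what it is supposed to recover under its stated model,
not that the published point estimates would reproduce on restricted
survey data.

## Statistical conventions

* Alive/deceased contrasts: two-tailed two-sample t test, Welch
  (unequal-variance) by default — the original analysis environment's
  default — with a pooled-variance option. Zero variance in both groups
  degenerates to t = 0, p = 1.
* Screens: Spearman (mid-ranks, two-sided t approximation) by default;
  the sex-stratified deltaAge screen defaults to Pearson, matching how
  that analysis is conventionally displayed, and is configurable.
* Group contrasts: tie-corrected Kruskal–Wallis with asymptotic
  chi-square p; optional unadjusted pairwise two-sided rank-sum p values
  as the documented stand-in for pairwise annotations.
* Signature selection: raw-p cutoffs (deltaAge screen p < 0.05, group
  screen p < 0.01), strict inequalities, no multiple-testing correction
  in the selection; a Benjamini–Hochberg FDR column is emitted for
  reference only. Health groups are coded young = 0, trained = 1,
  normal = 2, impaired = 3 along the health-decline ordering.
* Cross-correlations of the clock inputs: Pearson with significance
  stars at 0.05 / 0.01 / 0.001.
* Glucose supplied in mg/dL is converted by ÷18.016 at load time and
  logged; the model consumes mmol/L throughout.

## Problem sizes and determinism

Default analyses use the full-scale cohort (n = 3342, matching the
retained survey population, split 80/20 by sex), 50 seeds for
coefficient-coverage checks, 200 seeds for screen type-I calibration, and
10 split-robustness seeds — all complete in seconds. All randomness flows
from a single top-level seed expanded into named per-stage streams
(cohort, mortality, split, mitohealth, metabolome), so a rerun of any
stage with its stream reproduces the full run.

## Known limitations

* Linear influence of glucose and blood pressure means pathologically low
  values (hypoglycemia, hypotension) score deceptively young.
* The published normalization table is not redistributed; scoring with
  the published constants outside a fitted pipeline uses a synthetic
  reference NF built from the default generator, which differs from the
  original table wherever the generator's median physiology differs from
  the survey's.
* The age-anchored generator cannot exhibit deltaAge–mortality
  separation (see above); that is a property of its independence
  structure, not a bug in the clock.
* Only the binary ten-year vital status is modeled; no survival analysis
  (Cox, Kaplan–Meier) or calendar-time censoring.
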