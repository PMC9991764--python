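# Methods

## Scope and design

`dietna` is an analysis package: a synthetic-cohort generator with a known
measurement-error structure, twelve sodium-estimation methods (one
reference, six spot-urine conversions, five dietary scorers), and the
agreement battery that compares each method with the reference. Every
statistic the analysis scripts print is computed by library code that the
tests exercise against independently coded oracles.

## The generative model

Each participant *i* has a true usual intake
*T*ᵢ ~ LogNormal(mean μ = 3120 mg/d, CV 0.39), split into a food component
(1 − *s*) *T*ᵢ and a discretionary component *s* *T*ᵢ with *s* = 0.15
(salt added in cooking — 75 % of the discretionary part — and at the
table). The instruments observe:

* **24-h urine**: Na content *e* · *T*ᵢ · δᵢ with excretion fraction
  *e* = 0.90 and day factor δᵢ ~ LogNormal(mean 1, CV 0.25), decomposed
  into a volume (log-normal around 1.6 L) and Na/K/creatinine
  concentrations; creatinine excretion per kg is drawn inside the
  sex-specific physiological bounds so that completeness screening flags
  exactly the injected incompletes. A fraction 0.074 of collections is
  made incomplete by truncating the collected volume below the 0.5 L
  screening threshold (concentrations stay physiological — part of the
  day's urine is simply missing). The defaults give a mean measured 24-h
  Na of ≈ 0.90 × 3120 ≈ 2810 mg/d with SD ≈ 1300 (total CV
  √(ln-sum of 0.39² and 0.25²) ≈ 0.46).
* **Spot urine**: concentrations drawn from log-normals whose log-scale
  deviate correlates (default ρ = 0.6, configurable; no published
  generative model exists) with the day's 24-h excretion. `spot_scale`
  multiplies the spot Na concentration; values above 1 push all six
  conversion equations toward overestimation.
* **24-h recalls** (3 per participant, occasionally 1–2): the food
  component times a participant-level underreporting factor
  *u*ᵢ ~ TruncNormal(0.70, 0.10) on (0, 1.2] — dietary self-report is
  reported 15–40 % low in validation work, and 0.70 with a 15 % food
  share puts the expected recall bias (e − u(1 − s)) μ ≈ 950 mg/d in the
  middle of that literature — times a day factor (CV 0.15), itemised into
  four meals. The salt-question answers are the *quantised inverse* of the
  participant's true discretionary rate: Q1 picks the answer whose
  mg/100 g rate is nearest to the true cooking-salt rate over the meal's
  grams, Q2 answers "yes" when the per-meal table salt exceeds half the
  two-dash quantum. This makes the scoring approximately invertible and
  exactly invertible in the zero-discretionary limit.
* **FFQ / NaFFQ**: the food component times *u*ᵢ times an instrument
  noise factor (CV 0.35), allocated over the bundled composition table.
  A share (default 0.10) of food Na sits in the Na-rich items that only
  the extended NaFFQ asks about, so the standard FFQ structurally misses
  it; question b is quantised from the discretionary rate over the cooked
  meals and salads. Instrument availability defaults mirror a 122-person
  study layout (spot 71/122, recalls 119/122, FFQ 87/122, NaFFQ 60/122
  as fractions), with NaFFQ respondents nested in FFQ respondents.

Randomness uses one root seed with named, CRC-keyed substreams per data
type, so adding or reconfiguring one stream never perturbs another, and a
fixed seed reproduces every table bit-identically.

### What the generator does not emulate

Food-level dietary patterns (each meal is a single composite item),
seasonality, nutrients other than Na, correlated spot K/creatinine
dynamics, and intake-dependent underreporting. Passing tests therefore
demonstrate that the estimators and statistics behave correctly under the
*assumed* error structure, not that any instrument is accurate in real
cohorts.

## Estimation methods

* `u24`: concentration (mmol/L) × volume (L) × 23.0 mg/mmol (molar mass
  configurable to 22.9898).
* Spot conversions: coefficients live in `src/dietna/data/equations.csv`
  (equation_id, sex, term, coefficient, unit, provenance), never inline.
  Kawasaki, Tanaka and both INTERSALT forms carry their original published
  coefficients; the evaluator supports the two structural families (scaled
  power of the Na/creatinine ratio times predicted 24-h creatinine, and
  the INTERSALT linear form in concentrations, BMI and age). The Mage and
  Toft entries are **reconstructed**: their primary coefficient tables
  were not recoverable, so they are implemented in their documented
  creatinine-ratio form with body-size creatinine models calibrated to
  normal adult excretion (~1600 mg/d for a 70 kg/170 cm man) and flagged
  as reconstructed in the registry provenance column. Negative linear
  outputs are floored at 0 with a warning, since excretion cannot be
  negative. Creatinine concentrations are mg/dL throughout; the INTERSALT
  adapter converts to mmol/L via the 113.12 g/mol molar mass.
* Completeness screening: volume ≥ 0.5 L and creatinine excretion within
  14.4–33.6 (men) / 10.8–25.2 (women) mg/kg/d; each rule individually
  switchable. These defaults follow the criteria customary in the
  urinary-sodium literature.
* Dietary scorers: see README for the constants. Q1 is applied to the
  meal's total item grams (the generator produces food items only;
  beverages are out of scope of the itemisation). Q2 is quantified per
  meal answered "yes"; a one-dash variant (387.5 mg) is available via
  `dashes_per_yes`. The +15 % correction defaults to division by 0.85
  (the 15 % is a share of *total* intake); the multiplicative ×1.15
  reading is available as `dr15_mode="markup"`. Missing salt-question
  answers score 0 with a warning rather than invalidating the recall,
  matching the "average of the available recalls" tolerance.

## Agreement battery

Bias is reference − estimate, so a method that overestimates intake has
negative bias. The paired test is Student's t when the differences pass a
Lilliefors-corrected KS normality check at α = 0.05 (the plain KS with
estimated parameters is anticonservative), Wilcoxon signed-rank otherwise
(exact p for n ≤ 25 without ties, continuity-corrected normal
approximation above). The ICC is the two-way single-measure coefficient;
the form is not standardised across software, so both are implemented —
ICC(A,1) absolute agreement (default, the form that penalises systematic
offsets) and ICC(C,1) consistency — with McGraw–Wong F-based 95 % CIs.
Note that ICC(A,1) ≤ ICC(C,1) is only guaranteed when the between-method
mean square is at least the residual mean square; on samples without a
systematic difference the inequality can reverse slightly. The limits of
agreement use the literal 1.96 multiplier. Reports round to one decimal;
all stored values are full precision. No multiple-testing correction is
applied (stated in every report).

Degenerate inputs: identical paired series give bias 0 with p = 1 and
ICC 1 with flagged (NaN) confidence limits; zero-variance series give NaN
correlations with a warning rather than a silent 0; n < 3 pairs are
rejected.

## Problem sizes and tolerances

The oracle-equivalence tests compare ICC, Bland–Altman slope/p, paired-t
and correlation values to brute-force reimplementations at 1e-10 on 20+
seeded fixtures. Calibration checks run at n = 10 000 (3 Monte-Carlo
standard errors); parameter recovery pools 50 replicates of n = 2000 and
restricts to complete collections, since truncated collections measure
only part of a day. Unit-bridge inverses hold to 1e-12; file round-trips
to 1e-9 on floats. The zero-noise configuration (all CVs 0, excretion 1,
underreporting 1, no discretionary salt, no structurally missed items)
reproduces true intake exactly through the 24-h collection and all five
dietary scorers; the spot conversion equations are population-calibrated
formulas with no such identity, which is itself the scientific point of
carrying a reference method.

## Known limitations

* Mage/Toft coefficients are reconstructions (see above); all six spot
  equations still satisfy the tested structural properties (positivity,
  monotonicity in spot Na, frozen double-transcription vectors).
* The discretionary-salt quantisation floor means the salt-questions
  method recovers discretionary intake only up to the Q1 rate grid.
* Printed ICCs from other software may differ when a different ICC
  model/type/unit is chosen; both single-measure forms are reported to
  make that ambiguity explicit.
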