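# Methods

## Decision process

The model is a finite-horizon, discrete-time MDP over a woman's annual
mammography visits. States: 101 integer risk-score states (0–100, the percent
probability of breast cancer from an upstream risk model, mapped to the grid
by half-up rounding), a benign-biopsy state, and two absorbing states
(malignant biopsy, death) — 104 in all. Decisions (biopsy BX vs annual
mammography AM) are made at every age from `start_age` (default 40) through
`last_decision_age` (default 99); at `terminal_age` (100) every alive state
receives a terminal reward equal to the all-cause expected remaining life,
irrespective of the last action. Rewards are undiscounted QALYs; a
configurable per-year discount factor (default 1.0) exists for exploration
only.

Biopsy is assumed perfectly sensitive and specific, and the risk score is
taken to fully describe current risk: electing biopsy at score s leads to the
malignant state with probability s/100 and the benign state otherwise. The
benign branch leaves the patient cancer-free for that year (she faces only
other-cause mortality) and her next-year score is drawn from the same kernel
row as under AM — no biopsy memory is kept. Patients are risk-neutral and
fully adherent; costs, short-interval follow-up, ultrasound and MRI are out of
scope.

## Rewards

- **Intermediate reward**: 1 QALY for a survived year, 1/2 for a year of
  death (half-cycle correction).
- **Death probability under AM**: other-cause mortality q_o(a) compounded, as
  independent competing risks, with the risk-weighted untreated breast-cancer
  mortality f · (s/100) · min(1, τ·q_t(a)), where q_t is annual treated
  breast-cancer mortality, τ (base 1.6, range 1.2–2) the treatment
  effectiveness factor relating untreated to treated mortality, and f the
  invasive fraction (see below). The "with treatment versus without" reading
  of τ is taken in the only direction consistent with τ > 1: treatment
  reduces mortality.
- **Biopsy disutility**: d40 weeks at age 40 (base 2, range 0–3) rising
  linearly to `factor`·d40 weeks at age 100 (factor base 2, range 0.5–4);
  52 weeks/year. It is charged on both biopsy branches: the procedure's
  burden is incurred regardless of pathology. (Charging it only on the
  benign branch is switchable via `RewardSpec.disutility_on_malignant`.)
- **Lump sum** on malignant biopsy at age a:
  `pct_invasive · E[life | invasive, a] + (1 − pct_invasive) · E[life | DCIS, a]`
  (pct_invasive base 0.75, range 0.65–0.85). Nothing accrues after the lump
  sum; death pays 0.

**Invasive fraction in the surveillance hazard.** The invasive share of a
prospective cancer is the lethal-while-undetected share: in-situ disease does
not threaten life within the year it goes undiagnosed. The solver therefore
weights the AM-year breast-cancer hazard by `pct_invasive` (the
`lethal_fraction` argument of `annual_death_prob`, default 1 when the
function is used standalone). This is what produces the observed sensitivity
direction — raising the invasive fraction lowers the biopsy threshold,
because waiting becomes more dangerous faster than the lump sum shrinks. With
the hazard unweighted, the invasive fraction would act only through the lump
sum and the response would reverse sign.

## Transition-kernel estimation

Trajectories (one finding's time-ordered (age, score) observations) are
annualized assuming risk changes linearly with time: gaps wider than a year
are filled at integer-year offsets from the first observation by linear
interpolation of the score, rounded half-up to the grid (interpolation is on
the integer score scale, not the probability scale). Trajectories with a
single observation are excluded. Every consecutive annual pair contributes
one count — interpolated pairs count exactly like observed ones — and each
row is normalized to the empirical next-score distribution. Rows never
observed are imputed as self-transitions and flagged (`support_counts == 0`);
no further smoothing is applied. A `mean-drift` mode (all row mass on the
rounded mean next score) is available for comparison; the default empirical
mode retains the stochastic structure the expectation in the Bellman equation
needs. Observations at non-integer offsets from a trajectory's first exam are
interpolated onto the anchored grid; anything beyond the last whole-year
offset is dropped.

## Solver

Plain backward induction, vectorized over the score grid; ties between the
two actions (within 1e-12) resolve to AM, so the reported threshold is the
smallest risk at which biopsy is strictly better. Death preempts the
risk-score transition (continuation weighted by survival), keeping the
per-row transition mass normalized. Threshold extraction checks, per age,
whether the policy is of control-limit form (BX for every score above the
cut-off); violations are reported in a diagnostics list, never repaired. The
generic array-level core (`solve_decision_problem`) also evaluates fixed
policies, which is how `evaluate_policy` and the exhaustive-enumeration test
oracle are built.

## Synthetic cohort

The generator emulates the statistical shape of a large screening/diagnostic
practice: entry ages Normal(56.5, 12.7) clipped to the horizon (clipping, not
truncation, so mass below 40 piles at 40 — the cohort it mimics includes
younger women the model horizon excludes); exams per patient with mean ≈ 2.7
including a 25% mass at a single exam (exercising the exclusion rule); exam
intervals of 2–3 years with probability 0.25 (exercising interpolation);
baseline scores geometrically concentrated below 5; annual score evolution by
a known ground-truth kernel with mild upward drift and a score-dependent
upward jump tail; per-exam cancer outcomes with probability proportional to
the current score, scaled (by bisection) so the marginal rate matches the
target 9.7/1000 exams. Outcomes are used only for calibration and reporting —
the MDP consumes risk scores. Everything derives from one seed;
identical configs reproduce byte-identical cohorts.

What the generator does **not** emulate: reader variability and systematic
drift in risk scoring, informative exam timing (sicker women returning
sooner), death and loss to follow-up within trajectories, breast/quadrant
matching noise, and any real lesion biology. Passing tests therefore show
the pipeline is correct and well-calibrated under its own assumptions, not
that the shipped thresholds are clinically transportable.

## Fixture tables

Synthetic stand-ins, shipped as CSVs and regenerable with
`scripts/make_fixtures.py`:

- other-cause mortality: Gompertz hazard 6.366e-5 · exp(0.0861·age)
  (≈0.002 at 40, ≈0.35 at 100), US-life-table shaped;
- treated breast-cancer mortality: 0.12 + 0.001·(age−40) per year — the
  hazard scale of leaving a (mostly invasive) cancer unaddressed, chosen so
  delay carries a material survival penalty;
- lump-sum expected life: computed from the Gompertz table plus a constant
  post-treatment excess hazard of 0.01/yr (invasive) or 0.001/yr (DCIS),
  hazards extended to age 120, with a half-year timing credit; DCIS
  dominates invasive at every age and both decline with age;
- terminal reward: all-cause expected remaining life at 100 (≈2.0 years).

These levels were chosen once for clinical plausibility and to make the
base-case solve non-trivial (a low single-digit threshold at 40 rising with
age, control-limit at every age). On them, the base case yields a threshold
of 2% through the 40s–50s rising to 23% at 99.

## Numerical choices and problem sizes

Kernel rows must sum to 1 within 1e-9; instance validation rejects, never
repairs. Serialization round-trips integers exactly and probabilities to
1e-12 (`%.12g`). The default pipeline uses 10,000 patients and the 60-age
horizon; solver cost is negligible (60×101×101 products per solve). Test
oracles use exhaustive policy enumeration on ≤4 states × ≤3 epochs and
10,000 transitions per row for kernel recovery (total-variation < 0.05) —
sizes at which enumeration and sampling error are decisive yet the suite
runs in about a minute.

## Known limitations

- The risk score is assumed to summarize all prognosis-relevant information
  (Markov property on a scalar score); no partially-observable extension.
- A single kernel serves all ages; real risk dynamics are age-dependent.
- The untreated-mortality scale and the lump-sum tables are synthetic:
  absolute threshold values should not be read clinically, only their
  structure (monotone in age; directions under the four sensitivity
  parameters).
- Sparse kernel rows are imputed as self-transitions, which slightly
  overstates persistence at rarely-visited scores.
- One-way sensitivity only; no probabilistic sensitivity analysis (a two-way
  grid can be composed from `one_way_sweep` but is not part of the shipped
  analysis).
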