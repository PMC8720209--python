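# Methods

## Scope and model

`prostate-da` is a decision-analysis engine for shared decision making in
newly diagnosed, radiation-eligible prostate cancer. It combines four
pieces:

1. **Risk stratification.** The NCCN six-group rule set (very low .. very
   high) over clinical T stage, Grade Group, PSA, and biopsy-core
   features, collapsed onto three broad categories (LOW / INTERMEDIATE /
   HIGH) because treatment eligibility and outcome data are usually
   reported at that granularity.
2. **Toxicity transition matrices.** For each treatment and each of four
   side effects — erectile function, urinary incontinence, nocturia,
   bowel incontinence — a row-stochastic matrix
   `P(post-state | pre-state)` estimated by a frequentist count over
   paired pre/post questionnaire records. The pre-treatment state is the
   single best predictor of the post-treatment state, which is why the
   model conditions on it and on nothing else.
3. **Preference elicitation.** Per side effect, a *preference threshold*
   τ_s (the worst level the patient tolerates) and a *willingness to
   accept* (WTA) dollar value w_s for living strictly worse than τ_s;
   a per-alternative burden value b_a for the alternative's non-medical
   attributes; and a failure value w_F for biochemical recurrence.
   Dollars are elicited as willingness to *get paid* so that a patient's
   bank balance never caps the answer; the engine uses them only as
   burden magnitudes on a common scale.
4. **Linear additive valuation.** For an alternative *a* with matrices
   `M_{a,s}`, pre-state x, and broad risk r:

       cost(a) = Σ_s Pr(post worse than τ_s | x_s; M_{a,s}) · w_s
               + b_a
               + (1 − FFBF(a, r)) · w_F

   where FFBF is the 5-year freedom-from-biochemical-failure probability.
   Eligible alternatives are ranked by ascending cost; lower expected
   burden is better. A display layer may negate the sign to show "value";
   the ranking is unaffected.

## Assumptions

* **Ordinal scales are totally ordered**, best level first; "worse than
  threshold" is strict, so the threshold level itself is tolerated
  (tolerating waking twice a night means paying applies to *more than*
  two wakings).
* **Linearity and additivity**: attribute values combine additively with
  no interactions and no risk attitude (utility curvature). Extreme
  dollar values are legal and simply dominate.
* **One-step transition model**: toxicity is pooled at a stabilized
  endpoint (a year or more after treatment); there is no time-resolved or
  covariate-adjusted component.
* **Active surveillance carries no attributed side effects**: its
  matrices are identity matrices. This is a modeling convention, not a
  clinical claim — men on surveillance do decline with age.
* **No discounting** is applied to the lifetime-horizon dollar amounts.

## Estimation details

`tally_transitions` counts records per (pre, post) cell;
`estimate_matrix` divides by row totals. Numerical choices:

* **Empty rows** (pre-states never observed) default to the identity row
  — state persists — and are flagged in `ToxicityMatrix.empty_rows`;
  a strict `empty_row_policy="error"` and add-α (Laplace) smoothing
  (default α = 0) are available. The identity default is conservative and
  mirrors the surveillance convention.
* Raw counts and row totals are stored alongside probabilities so
  bootstrap-style uncertainty work remains possible.
* Display rounding is two decimals on percentages (e.g. `17.39%`); all
  internal arithmetic is unrounded. Row-stochasticity is enforced to
  1e-9 on construction.
* EBRT standard and hypofractionated fractionation derive from the same
  trial population; by default one shared matrix may serve both arms, and
  per-arm matrices are accepted whenever supplied.

Pre/post association (`assess_pretreatment_predictiveness`) is the
Spearman rank correlation of scale ranks per (treatment, side effect);
degenerate (constant) inputs yield NaN, never a fabricated zero.

## Risk classifier

Rules are evaluated from most to least severe — very high → high →
unfavorable intermediate → favorable intermediate → very low → low — so
exclusions like "no very high risk features" hold by construction.
Intermediate risk factors are cT2b–cT2c, Grade Group 2–3, PSA 10–20;
high-risk features are cT3a, Grade Group 4–5, PSA > 20; very-high
features are cT3b–cT4, primary Gleason pattern 5, ≥ 2 high-risk
features, or > 4 cores with Grade Group 4/5. Favorable intermediate
follows the printed rule text (Grade Group "1 or 2" with exactly one
intermediate risk factor and < 50% positive cores). The classifier is
total over valid inputs with one documented exception: when very-low
versus low hinges on per-core involvement and
`max_single_core_involvement` is absent, it raises a
`ClassificationGapError` naming the rule rather than assuming a value.
T stages below cT1c and N/M staging are outside the rule set and outside
the input enum.

## Synthetic cohorts

The institutional questionnaire datasets behind a deployed aid are not
redistributable, so estimators and the pipeline are exercised on
synthetic cohorts with known ground truth:

* **Truth matrices** keep probability `diagonal` (default 0.5) on the
  pre-state and spread the rest geometrically (`decay` 0.5) with 75% of
  the off-diagonal mass on worse states — states tend to persist or
  decline, rarely improve. `diagonal=1` gives identity;
  active surveillance always gets identity. The base construction is
  deterministic; optional Dirichlet `jitter` is seeded.
* **Cohorts** draw pre-states i.i.d. from a marginal (uniform by
  default) and post-states from the truth row, 150 patients per
  treatment arm by default — the approximate per-arm size of the pooled
  source datasets — with one record per patient per side effect.
* **The worked-example fixture** is a deterministic erectile-function
  cohort: 46 patients entering at 100% potency, 8 retaining it
  (8/46 = 17.39%), the other 38 spread 12/10/8/8 over 75/50/25/0%. Only
  the retained-potency cell is anchored by published data; the split of
  the decliners is fixture convention.

What the synthetic generator does **not** emulate: inter-institutional
heterogeneity, dropout, within-patient correlation across side effects
(records are sampled independently per side effect), and any real
post-treatment distribution beyond the single anchored cell. Passing
tests therefore demonstrate correctness of the estimators and engine, not
fidelity of any particular probability to clinical reality.

## Catalog defaults

Eligibility (LOW: surveillance, SBRT, EBRT±hypofractionation;
INTERMEDIATE: SBRT, EBRT±hypo, EBRT+HDR, EBRT+ADT; HIGH: EBRT+ADT,
EBRT+HDR+ADT) is configuration, not code, and follows common
NCCN-style radiation-oncology practice. The 5-year FFBF success
probabilities shipped in `data/default_catalog.yaml` are **placeholders**
in a clinically plausible range; they are not published estimates, and
every shipped test either fixes them explicitly or is invariant to them.
Surgery and brachytherapy monotherapy are out of scope for lack of
paired toxicity data.

## Ranking and search

Ties in total cost break by the catalog's documented treatment order
(least intensive first), making results deterministic. Ranking is a pure
function of its inputs, which is what gives the interactive
"recompute-on-every-toggle" behavior.

`find_supporting_preferences` searches a documented grid for a profile
making a chosen alternative the *unique* minimizer: one threshold
position applied across all scales (clamped per scale), side-effect
dollar patterns that are uniform or concentrated on one side effect with
values in {0, 100, 1,000, 10,000}, failure dollars over the same set,
and — when the burden lever is on (default) — the option of charging all
competitors 10,000 while the target costs nothing. The grid is
overridable via `SearchConfig`. Exhausting the grid without a winner is
reported honestly as `None`; with the lever off, a strictly dominated
alternative provably has no supporting profile under the additive form.
On the default synthetic matrices and catalog, every one of the seven
alternatives has a supporting profile — no alternative is
deterministically dominant, so the preference elicitation genuinely
matters.

## Problem sizes used in the shipped checks

Counting equivalence runs 1,000 random cohorts of up to 40 records;
parameter recovery uses 5,000 observations per pre-level row over 20
seeded replicates, plus per-arm sizes 150 / 1,000 / 5,000 for the
monotone-convergence check; the end-to-end synthetic pipeline check uses
2,000 patients per arm with a five-standard-error binomial bound per
cell. These sizes were chosen so every check is decisively powered while
the whole suite runs in seconds.

## Known limitations

* The exact value-function normalization used by the original interactive
  application was not published; the additive monetized form above is
  this package's documented interpretation, and success enters as an
  expected failure cost rather than a separately displayed probability.
* No uncertainty is propagated to the ranking (point probabilities only).
* The four modeled side effects exclude ADT-specific effects (e.g. hot
  flashes) and the instrument items are used singly, not as EPIC/IPSS
  domain summary scores.
* Dollar inputs are unconstrained (no caps or increments).
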