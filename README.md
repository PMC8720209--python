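# prostate-da

A decision-analysis engine for shared decision making in newly diagnosed,
radiation-eligible prostate cancer. It is written for clinical
decision-support developers and methods researchers who need the
quantitative core of a personalized decision aid as a tested,
scriptable library rather than a web form.

Men with localized prostate cancer typically face several options of
similar oncologic efficacy — active surveillance, SBRT, standard or
hypofractionated EBRT, EBRT with HDR brachytherapy and/or androgen
deprivation — that differ mainly in side-effect risk and day-to-day
burden. The package makes that trade-off explicit and personal:

1. **Risk**: classify the patient's NCCN risk group (very low .. very
   high) from T stage, Grade Group, PSA, and biopsy cores, simplified to
   LOW / INTERMEDIATE / HIGH for eligibility and outcome tables.
2. **Toxicity**: from paired pre/post patient-reported outcomes (EPIC and
   IPSS items for erectile function, urinary incontinence, nocturia, and
   bowel incontinence), estimate row-stochastic transition matrices
   `P(post-state | pre-state)` by frequentist counting — the
   pre-treatment state is the best available predictor of the
   post-treatment state.
3. **Preferences**: elicit, per side effect, the worst tolerated level
   (preference threshold τ_s) and a willingness-to-accept dollar value
   w_s for living worse than it, plus per-alternative burden dollars b_a
   and a failure value w_F.
4. **Ranking**: score each eligible alternative *a* with a linear
   additive value function on the common dollar scale,

       cost(a) = Σ_s Pr(post worse than τ_s | pre; M_{a,s}) · w_s
               + b_a + (1 − FFBF_{a,r}) · w_F

   where FFBF is 5-year freedom from biochemical failure, and rank by
   ascending expected burden.

Because the institutional datasets behind deployed aids are not
redistributable, the package includes a first-class synthetic-cohort
generator with known ground-truth matrices (default 150 patients per
treatment arm), used by the test suite for parameter-recovery and
dominance properties. See `docs/methods.md` for the model, assumptions,
and numerical choices.

## Worked example

`prostate-da demo` writes an example patient bundle (very-low-risk
disease, mild pre-treatment symptoms, side-effect valuations of
$1,000–8,000, $20,000 on cure), simulates a synthetic cohort, estimates
matrices, and evaluates:

```text
$ prostate-da demo --out-dir demo_out
risk: very_low (LOW)
 1. active_surveillance    $2,000  *best*
 2. EBRT_hypofractionated  $6,856
 3. SBRT                   $7,517
 4. EBRT_standard          $8,444
```

Each number is the expected dollar burden the patient attached to that
alternative. Surveillance costs this patient only its failure term
(10% failure risk × $20,000 = $2,000) because, with no attributed side
effects, a state within all thresholds stays there; the radiation arms
add expected side-effect costs (e.g. $4,656 for hypofractionated EBRT)
and any stated travel/visit burden. Lower is better; with these
preferences surveillance wins, but raising the failure value or
tolerating fewer clinic visits reorders the list — the ranking is a pure
function of the inputs, so every preference toggle is just a re-run.

The same pipeline is available as subcommands (`classify`,
`build-matrices`, `evaluate`, `search-dominance`, `simulate`) and as
plain library calls (`classify_nccn`, `estimate_matrices`,
`rank_alternatives`, `find_supporting_preferences`).

A reference worked example ships as a deterministic fixture: in a cohort
of 46 patients entering treatment with 100% potency, 8 retain it, so the
estimated erectile-function matrix shows

```text
P(post = 100% | pre = 100%) = 8/46 = 17.39%   (row total 46)
```

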