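# Methods

## The measurement problem

The package treats a black-box responder as a measurement subject. A panel
of items — ten material anchors spanning an intuitive hardness continuum
(Marshmallow … Steel) plus five abstract concept targets (Life, Kindness,
Silence, Justice, Death) — is presented in two-alternative forced-choice
trials: two labeled items, one forced choice of the "harder" item, and an
integer confidence in [0, 100], returned as exactly one line of JSON. The
prompt template, item labels, trial order, and A/B positions are all part
of the instrument: two runs are comparable only if those bytes match,
which is why run files are archivable CSVs and signatures store a digest
of (template bytes + run file bytes).

## Trial plans

A `PanelSpec` fixes the instrument: items with roles and canonical anchor
ranks, the axis definition, block counts, a repeat plan, and a seed.
`build_trial_plan` is a pure function of the spec; the same spec always
yields a byte-identical plan. Blocks sample distinct unordered pairs
(concept-anchor, concept-concept, anchor-anchor); catch trials re-present
the pinned anchor pair, whose expected winner is known from the canonical
ranks; the repeat plan adds a second presentation of a seeded subset of
non-catch pairs with independently randomized A/B order. The planned
total is

    total = sum(block_counts) + n_repeated_pairs * (reps_per_pair - 1).

The stock panel uses blocks {concept_anchor: 50, concept_concept: 10,
anchor_anchor: 44, catch: 23} and a (63, 2) repeat plan: 190 trials with
exactly 64 unordered pairs presented more than once (the 63 repeat-plan
pairs plus the catch pair). This composition is a *reconstruction*: a
190-trial run over 64 repeated pairs is consistent with several block
splits, and with 15 items (105 unordered pairs) any duplicate-free plan
plus 64 disjoint twice-presented pairs could total at most 169 trials —
so the catch pair must itself be one of the repeated pairs. Users auditing
a different instrument should set their own counts; everything downstream
is composition-agnostic.

Trial ids are prefixed with a hash fragment of the panel version so trials
from different panel versions can never collide.

## Response parsing

Strict parsing accepts exactly the schema language — one JSON object on
one line, exactly the keys trial_id / choice / confidence, choice in
{A, B}, confidence an integer in [0, 100] — and classifies every rejection
with a distinct error code, because parse-failure modes are themselves
part of the behavioral signature. Lenient parsing (opt-in) strips code
fences and surrounding prose and marks the record repaired; repairs are
counted in the ingestion report, never silent. Joining resolves each
winner from the chosen *position* on that specific trial, so the analysis
is invariant to A/B counterbalancing. Duplicate responses keep the first
occurrence; orphans, missing trials, duplicates and parse failures are
reported, not raised — a partially failed run still yields QC output.

## Scaling

Bradley-Terry with an L2 penalty: maximize
Σ log σ(β_w − β_l) − λ Σ βᵢ², no intercept. λ defaults to 0.1 and is
recorded in every signature; it is part of the instrument, since a
near-deterministic responder produces separated data for which the
unpenalized MLE diverges. The objective is smooth and strictly convex for
λ > 0, so a damped Newton iteration (step-halving line search, full
Hessian solve — the item count is small) converges in a few steps;
convergence is declared at a penalized-gradient max-norm of 1e-8, and the
solver is vectorized over bootstrap replicates. Strengths are
mean-centered for reporting (the anchoring step removes the arbitrary
origin anyway).

Anchoring maps scores linearly: score = 100 · (β − β_low) / (β_high −
β_low). Items ranked beyond the anchors legitimately land outside
[0, 100], and CIs are not clipped. Equal anchor strengths make the scale
undefined and raise an `AnchoringError` — deliberately a loud failure,
because a run that cannot separate its own endpoints is a QC event.

Fit is summarized as classification accuracy (observation counted correct
when the winner's β is strictly higher; exact ties contribute 0.5) and
log loss (negative mean log fitted probability of the observed winner).

The parametric bootstrap (default 1,000 replicates, percentile method,
one seeded generator) redraws each observation's winner Bernoulli from
the fitted probability, refits with the same λ, and rescales per
replicate; pinned anchors are exactly 0 and 100 in every replicate, so
their intervals are degenerate by construction. Replicates that fail to
refit are dropped and counted; more than 10% drops aborts with an error.

## QC metrics and flags

- **Repeated-pair agreement**: a pair presented ≥2 times agrees when all
  its observations name the same winner (unanimity — the strictest
  reading; a majority variant is available). Reported as agreeing pairs /
  repeated pairs, rendered to one decimal.
- **Confidence-distance correlation**: Pearson r between per-trial
  confidence and |Δ anchored score|, catch trials excluded by default
  (they probe attention, not graded distance; a switch includes them).
  95% CI by Fisher z transform; a bootstrap CI is available. Zero
  variance in either variable is reported as degenerate, not as r = 0.
- **Catch pass rate**: fraction of catch trials won by the expected
  (higher-canonical-rank) anchor; absent catch trials yield an explicit
  not-computed status.
- **Anchor order**: anchors sorted by canonical rank; every adjacent pair
  whose fitted scores invert (or tie) is a violation. The denominator is
  the number of adjacent pairs — 9 for a 10-anchor panel. Other
  conventions exist (e.g., counting only non-pinned anchors gives an
  8-pair denominator); this package fixes and documents the adjacent-pairs
  convention.

Default flag thresholds: repeat agreement < 0.95 → `LOW_REPEAT`; any
anchor inversion → `ANCHOR_ORDER`; r < 0.6 →
`WEAK_CONFIDENCE_CALIBRATION`; catch pass rate < 1.0 → `CATCH_FAIL`. The
thresholds sit between the behavior of a well-calibrated responder
(agreement ≈ 1, r ≈ 0.8–0.95) and a visibly degraded one (agreement
≈ 0.9, r ≈ 0.2–0.4) and are review triggers, not safety claims; all are
configurable.

## Invariance comparisons

Per condition, each unordered pair gets its majority winner (exact ties →
indeterminate, excluded from the denominator and listed). Two conditions
are compared on the pairs both determined: reversals are differing
winners, agreement = 100 · (n − reversals) / n, reported to one decimal.
Wrapper vs prompt-family is metadata only; the arithmetic is identical.

## Drift monitoring

A `RunSignature` stores the fitted scale (scores + CIs), the QC summary,
the analysis configuration (λ, bootstrap reps and seed), and the
instrument digest; the file carries its own content hash, and loading
re-verifies both the content hash and — when the referenced template/run
artifacts are readable — the instrument digest. Signatures are comparable
only when panel version, axis, and item set match; mismatches raise a
named error rather than producing a silently wrong delta.

`compare_to_baseline` reports per-item score deltas, CI-overlap
indicators, ordering reversals implied by the scores, and QC deltas. The
default action rule triggers `review` when any item moves beyond the
half-width of its baseline CI, any new anchor-order violation appears, or
repeat agreement drops by more than 0.05 — CI-scaled thresholds adapt to
each item's own uncertainty. `mitigation` and `rebaseline` are manual
escalations recorded in the report, not auto-triggered.

## The simulated responder

`simulate_responses` draws choices from P(choose A) = σ((s_A − s_B)/τ)
over latent item scores s, and confidence from
round(clip(gain·|s_A − s_B| + offset + N(0, noise_sd), 0, 100)). The
choice rule is deliberately the Bradley-Terry generative family, so
pipeline runs on simulated data are clean self-consistency tests, and
confidence is linked to *latent* (not fitted) distance so the correlation
metric tests recovery of a known monotone link. All outputs are
bit-reproducible given (plan, profile, seed).

Default latent scores place the ten anchors in canonical order across a
0–100 latent axis (endpoints at the pinned anchors, adjacent gaps ≈ 5–13
units) and interleave the five concepts at plausible positions (soft
concepts low, hard concepts high). Because the latent endpoints coincide
with the anchoring convention, the latent scores double as true anchored
scores for recovery and coverage studies.

Two stock profiles:

- **clean** — τ = 0.5 latent units, confidence (gain 0.7, offset 12,
  noise sd 5). With the smallest latent gap ≈ 5 units, the flip
  probability per trial is < 1e-4: over a 190-trial run the responder is
  effectively deterministic, which is how a well-behaved production
  responder presents (perfect repeat agreement, accuracy ≈ 1.0, strong
  confidence-distance correlation).
- **degraded** — the clean profile plus three failure modes: the
  Polycarbonate-sheet/Steel latent scores swapped (guaranteeing
  anchor-order violations downstream), τ boosted ×16 (effective τ = 8,
  typical repeat agreement ≈ 0.90, below the flag threshold), and
  confidence decalibrated (gain ×0.2, noise sd ≥ 25, collapsing r to
  ≈ 0.2). This is the profile of an on-premise or updated responder that
  warrants review.

What the simulator does *not* emulate: linguistic behavior, systematic
position or label biases, drift within a session, non-stationary
confidence policies, or refusal/malformed-output modes beyond what the
parser's error codes represent. Passing tests therefore demonstrate that
the pipeline measures what it claims under its own statistical
assumptions — not that any real model is safe or stable.

## Verification choices and problem sizes

- The solver is checked against an independent dense-grid + simplex
  maximizer of the identical penalized objective on ≤4-item instances
  (agreement ≤ 1e-3).
- Parameter recovery: 20 independent 190-trial clean-profile runs must
  recover the exact latent ordering, with Spearman ρ ≥ 0.95 against
  truth.
- Bootstrap coverage: 200 simulated 190-trial runs of a moderate-noise
  responder (τ = 15, so the likelihood is informative rather than
  separated), 500 replicates each; pooled coverage of true anchored
  scores by the nominal-95% intervals is required to lie in [0.90, 0.99].
  Measured: ≈ 0.96. The anchored scale helps here: the L2 shrinkage on β
  is largely proportional and cancels in the anchored ratio.
- Schema strictness is fuzzed with property-based tests: every generated
  schema instance must parse, and decorated/perturbed variants must
  raise.

## Known limitations

- The hardness axis is a metaphor instrument, not a validated clinical
  construct; flags are review triggers only.
- The default 190-trial composition is one plausible reconstruction of a
  panel of this size (see above), not a canonical plan.
- Agreement under unanimity becomes harsh as reps-per-pair grows; use the
  majority option for high-rep designs.
- The drift monitor compares two signatures; it implements no longitudinal
  statistical test across many runs.
- No live model adapter is included: the package renders prompts and
  ingests responses, and deliberately never talks to a model.
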