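# anchorpanel

Anchored forced-choice quality-assurance panels for black-box language
models.

Health systems increasingly expose patients and clinicians to vendor-hosted
language models whose behavior can change silently after an update. This
package implements a compact behavioral QC assay for that governance
problem: a versioned two-alternative forced-choice (2AFC) panel. The model
repeatedly compares pairs of items ("which is harder, A or B?") against a
fixed set of reference anchors with a known canonical order, returns one
line of JSON per trial, and the resulting win/loss data is scaled, checked
for internal consistency, and compared against a stored baseline — the same
logic a clinical laboratory applies to control materials.

It is intended for quality/safety engineers and applied statisticians who
need a repeatable, auditable *behavioral signature* of a black-box
responder, not a clinical validity measure.

## The model

Pairwise choices are modeled with the Bradley-Terry framework: each item
*i* carries a latent strength βᵢ and

P(i beats j) = exp(βᵢ) / (exp(βᵢ) + exp(βⱼ)) = σ(βᵢ − βⱼ).

Strengths are estimated by maximizing the L2-penalized log-likelihood

Σ log σ(β_w − β_l) − λ Σ βᵢ²  (λ = 0.1 by default)

with a damped Newton iteration (the penalty makes the objective strictly
convex and keeps estimates finite under perfectly separated data). Fitted
strengths are linearly rescaled so the pinned low anchor (Marshmallow)
sits at 0 and the pinned high anchor (Steel) at 100; other items may fall
outside [0, 100]. 95% confidence intervals come from a parametric
bootstrap: redraw every trial's winner from the fitted probabilities,
refit, rescale, take percentile bounds — so the pinned anchors have
degenerate intervals by construction.

On top of the scale, the QC layer computes repeated-pair agreement
(identical winners across re-presented unordered pairs), the Pearson
correlation between reported confidence and the absolute anchored-score
difference, catch-trial pass rate, and anchor-order violations; a
condition-comparison layer counts pairwise-winner reversals between
wrapper or prompt-family variants; and a drift monitor stores baseline
run signatures (scores + CIs + QC + instrument digest) and flags reruns
that shift beyond their baseline uncertainty.

A built-in simulated responder generates responses with exactly the
structure the analysis assumes (logistic choice noise over latent scores,
distance-linked confidence), with switchable degradation modes, so the
whole pipeline is testable without querying any model.

## Worked example

```python
import anchorpanel as ap

spec = ap.default_panel_spec(seed=7)          # 190-trial hardness panel
plan = ap.build_trial_plan(spec)              # seeded, archivable trial plan
clean, _ = ap.make_default_profiles()         # simulated well-behaved responder
responses = ap.simulate_responses(plan, clean, seed=42)
dataset, report = ap.join_responses(plan, responses)
scale = ap.fit_scale(dataset, spec.axis, l2_lambda=0.1, n_reps=1000, seed=9)
qc = ap.compile_qc_report(dataset, scale, spec)

roles = {it.item_id: it.role for it in spec.items}
print(scale.to_frame(roles).to_string(index=False))
print(ap.render_qc_table(qc, scale))
```

which prints (abridged):

```
               item    role  score ci_low ci_high
        marshmallow  anchor   0.00   0.00    0.00
               life concept  11.77 -11.35   29.13
           kindness concept  22.81   4.26   41.92
            ...
            justice concept  83.19  65.87  104.26
              death concept  90.91  73.78  115.15
              steel  anchor 100.00 100.00  100.00

Bradley-Terry classification accuracy    1.000
Bradley-Terry log loss                   0.0970
Repeated-pair agreement (n=64 pairs)     100.0% (64/64)
Confidence vs absolute score difference  r = 0.943 (95% CI 0.923-0.957)
Catch-trial pass rate                    1.000 (23/23)
Anchor-order violations (0/9)            none
Flags                                    none
```

The two pinned anchors sit exactly at 0 and 100 with degenerate CIs; the
concepts and remaining anchors are placed between (or beyond) them with
bootstrap uncertainty. A clean responder reproduces the canonical anchor
order, agrees with itself on all 64 repeated pairs, and shows confidence
rising with pair distance — so no QC flag is raised. Running the same
pipeline with the `degraded` profile (a swapped anchor pair, noisier
choices, decalibrated confidence) raises `ANCHOR_ORDER` and `LOW_REPEAT`,
and `compare_to_baseline` on the two runs' signatures triggers a `review`
action.

The same workflow is available from the shell:

```
anchorpanel init-spec --out panel.json
anchorpanel design --spec panel.json --seed 7 --out run.csv
anchorpanel simulate --run run.csv --profile clean --seed 42 --out resp.jsonl
anchorpanel ingest --run run.csv --responses resp.jsonl --out dataset.csv
anchorpanel fit --dataset dataset.csv --spec panel.json --out scale.json
anchorpanel qc --dataset dataset.csv --scale scale.json --spec panel.json --out qc.json
```

To audit a real responder, render the prompts (`anchorpanel render`),
collect its one-line JSON answers by whatever access mode you govern, and
feed them to `ingest` unchanged.

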