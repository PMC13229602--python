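"""Repeatability, confidence calibration, anchor order, and QC flags."""

import numpy as np
import pytest

import anchorpanel as ap
from anchorpanel.response_io import ComparisonDataset, Observation

# Frozen direct-formula oracle: Pearson r of distances (10,20,30,40,50)
# against confidences (20,35,30,60,80), computed independently.
TOY_R = 0.9359710


def _pair_obs(pair_winners):
    """pair_winners: dict pair_key -> list of winners; builds observations."""
    obs = []
    k = 0
    items = set()
    for pk, winners in pair_winners.items():
        a, b = pk.split("|")
        items |= {a, b}
        for w in winners:
            obs.append(Observation(w, b if w == a else a, 50, f"t{k:04d}",
                                   "anchor_anchor", pk, "pf", "wr"))
            k += 1
    return ComparisonDataset(tuple(sorted(items)), obs)


class TestRepeatedPairAgreement:
    def test_all_identical_winners_is_100_percent(self):
        ds = _pair_obs({f"a{i:02d}|b{i:02d}": [f"a{i:02d}"] * 2 for i in range(64)})
        res = ap.repeated_pair_agreement(ds)
        assert (res.n_agree, res.n_pairs) == (64, 64)
        assert res.percent == "100.0%"

    def test_58_of_64_concordant_renders_90_6(self):
        pairs = {f"a{i:02d}|b{i:02d}": [f"a{i:02d}"] * 2 for i in range(58)}
        pairs.update({f"x{i:02d}|y{i:02d}": [f"x{i:02d}", f"y{i:02d}"] for i in range(6)})
        res = ap.repeated_pair_agreement(_pair_obs(pairs))
        assert (res.n_agree, res.n_pairs) == (58, 64)
        assert res.percent == "90.6%"

    def test_single_discordant_pair_is_zero(self):
        res = ap.repeated_pair_agreement(_pair_obs({"a|b": ["a", "b"]}))
        assert res.fraction == 0.0

    def test_no_repeats_is_not_computed(self):
        res = ap.repeated_pair_agreement(_pair_obs({"a|b": ["a"], "c|d": ["c"]}))
        assert res.status == "not_computed"

    def test_majority_mode_differs_from_unanimity_on_2_of_3(self):
        ds = _pair_obs({"a|b": ["a", "a", "b"]})
        assert ap.repeated_pair_agreement(ds).fraction == 0.0
        assert ap.repeated_pair_agreement(ds, require_unanimity=False).fraction == 1.0

    def test_invariant_to_trial_order(self, clean_dataset):
        rng = np.random.default_rng(1)
        obs = [clean_dataset.observations[i] for i in rng.permutation(len(clean_dataset))]
        shuffled = ComparisonDataset(clean_dataset.items, obs)
        assert (
            ap.repeated_pair_agreement(shuffled).fraction
            == ap.repeated_pair_agreement(clean_dataset).fraction
        )


def _scale(scores, accuracy=1.0, log_loss=0.01):
    items = tuple(scores)
    return ap.FittedScale(
        items=items,
        scores=dict(scores),
        ci_low={k: v - 1 for k, v in scores.items()},
        ci_high={k: v + 1 for k, v in scores.items()},
        accuracy=accuracy,
        log_loss=log_loss,
        l2_lambda=0.1,
        bootstrap_reps=100,
        bootstrap_seed=0,
        axis_id="hardness",
        low_anchor=items[0],
        high_anchor=items[-1],
    )


class TestConfidenceDistanceCorrelation:
    def _toy_dataset(self, distances, confidences):
        scores = {"base": 0.0}
        obs = []
        for k, (d, c) in enumerate(zip(distances, confidences)):
            item = f"i{k}"
            scores[item] = float(d)
            obs.append(Observation(item, "base", int(c), f"t{k:04d}",
                                   "concept_anchor", ap.pair_key(item, "base"), "pf", "wr"))
        return ComparisonDataset(tuple(scores), obs), _scale(scores)

    def test_affine_confidence_gives_r_one(self):
        ds, scale = self._toy_dataset([10, 20, 30, 40], [15, 25, 35, 45])
        res = ap.confidence_distance_correlation(ds, scale)
        assert res.r == pytest.approx(1.0)

    def test_five_point_toy_matches_formula_oracle(self):
        ds, scale = self._toy_dataset([10, 20, 30, 40, 50], [20, 35, 30, 60, 80])
        res = ap.confidence_distance_correlation(ds, scale)
        assert res.r == pytest.approx(TOY_R, abs=1e-6)
        assert res.ci_low <= res.r <= res.ci_high

    def test_affine_rescale_of_scores_leaves_r_unchanged(self):
        ds, scale = self._toy_dataset([10, 20, 30, 40, 50], [20, 35, 30, 60, 80])
        stretched = _scale({k: 3.0 * v + 11.0 for k, v in scale.scores.items()})
        r1 = ap.confidence_distance_correlation(ds, scale).r
        r2 = ap.confidence_distance_correlation(ds, stretched).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_confidence_is_degenerate(self):
        ds, scale = self._toy_dataset([10, 20, 30], [50, 50, 50])
        assert ap.confidence_distance_correlation(ds, scale).status == "degenerate"

    def test_too_few_observations_not_computed(self):
        ds, scale = self._toy_dataset([10, 20], [10, 20])
        assert ap.confidence_distance_correlation(ds, scale).status == "not_computed"

    def test_bootstrap_ci_contains_point_estimate(self):
        ds, scale = self._toy_dataset(range(10, 110, 10), [18, 30, 28, 55, 75, 60, 80, 82, 95, 90])
        res = ap.confidence_distance_correlation(ds, scale, ci_method="bootstrap", seed=4)
        assert res.ci_low <= res.r <= res.ci_high


class TestAnchorOrder:
    def _items(self, n=10):
        return tuple(ap.Item(f"a{i}", f"A{i}", "anchor", i) for i in range(1, n + 1))

    def test_monotone_scores_have_zero_violations(self):
        items = self._items()
        scale = _scale({f"a{i}": 10.0 * i for i in range(1, 11)})
        res = ap.anchor_order_check(scale, items)
        assert (res.n_violations, res.n_pairs) == (0, 9)

    def test_single_adjacent_swap_flags_that_chain(self):
        scores = {f"a{i}": 10.0 * i for i in range(1, 11)}
        scores["a4"], scores["a5"] = scores["a5"], scores["a4"]
        res = ap.anchor_order_check(_scale(scores), self._items())
        assert ("a4", "a5") in res.violations

    def test_fully_reversed_order_has_9_of_9(self):
        scale = _scale({f"a{i}": -10.0 * i for i in range(1, 11)})
        res = ap.anchor_order_check(scale, self._items())
        assert (res.n_violations, res.n_pairs) == (9, 9)

    def test_concepts_are_ignored(self):
        items = self._items(3) + (ap.Item("c", "C", "concept"),)
        scale = _scale({"a1": 0.0, "a2": 5.0, "a3": 10.0, "c": -99.0})
        assert ap.anchor_order_check(scale, items).n_violations == 0

    def test_clean_pipeline_scale_preserves_canonical_order(self, clean_scale, default_spec):
        res = ap.anchor_order_check(clean_scale, default_spec.items)
        assert res.n_violations == 0


class TestCompileReport:
    def test_clean_run_raises_no_flags(self, clean_dataset, clean_scale, default_spec):
        report = ap.compile_qc_report(clean_dataset, clean_scale, default_spec)
        assert report.flags == []
        assert report.repeat_agreement.fraction == 1.0

    def test_degraded_run_raises_anchor_and_repeat_flags(
        self, degraded_dataset, default_spec
    ):
        scale = ap.fit_scale(degraded_dataset, default_spec.axis, n_reps=60, seed=2)
        report = ap.compile_qc_report(degraded_dataset, scale, default_spec)
        assert "ANCHOR_ORDER" in report.flags
        assert "LOW_REPEAT" in report.flags

    def test_missing_catch_block_reported_without_flag(
        self, clean_dataset, clean_scale, default_spec
    ):
        report = ap.compile_qc_report(
            clean_dataset.exclude_block("catch"), clean_scale, default_spec
        )
        assert report.catch.status == "not_computed"
        assert "CATCH_FAIL" not in report.flags

    def test_report_serializes_to_json(self, clean_dataset, clean_scale, default_spec, tmp_path):
        import json

        report = ap.compile_qc_report(clean_dataset, clean_scale, default_spec)
        path = tmp_path / "qc.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["flags"] == []
        assert loaded["repeat_agreement"]["n_pairs"] == 64

    def test_rendered_table_mentions_key_metrics(self, clean_dataset, clean_scale, default_spec):
        report = ap.compile_qc_report(clean_dataset, clean_scale, default_spec)
        text = ap.render_qc_table(report, clean_scale)
        assert "Repeated-pair agreement" in text and "log loss" in text
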