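"""Response parsing (strict schema), joining, and catch-trial scoring."""

import json

import pytest
from hypothesis import given, settings, strategies as st

import anchorpanel as ap
from anchorpanel.response_io import ResponseParseError


def _line(trial_id="t007", choice="B", confidence=90):
    return json.dumps(
        {"trial_id": trial_id, "choice": choice, "confidence": confidence},
        separators=(",", ":"),
    )


class TestParseStrict:
    def test_schema_instance_parses(self):
        rec = ap.parse_response_line('{"trial_id":"t007","choice":"B","confidence":90}')
        assert (rec.trial_id, rec.choice, rec.confidence) == ("t007", "B", 90)
        assert not rec.repaired

    @pytest.mark.parametrize(
        "text,code",
        [
            ('{"trial_id":"t007","choice":"B","confidence":101}', "CONF_RANGE"),
            ('{"trial_id":"t007","choice":"B","confidence":-1}', "CONF_RANGE"),
            ('{"trial_id":"t007","choice":"B","confidence":90.5}', "CONF_NOT_INT"),
            ('{"trial_id":"t007","choice":"B","confidence":true}', "CONF_NOT_INT"),
            ('{"trial_id":"t007","choice":"C","confidence":90}', "BAD_CHOICE"),
            ('{"trial_id":"t007","choice":"B"}', "WRONG_KEYS"),
            ('{"trial_id":"t007","choice":"B","confidence":90,"note":"x"}', "WRONG_KEYS"),
            ('Sure! {"trial_id":"t007","choice":"B","confidence":90}', "EXTRA_TEXT"),
            ("not json at all", "NOT_JSON"),
            ('["trial_id","choice","confidence"]', "NOT_OBJECT"),
            ('{"trial_id":"","choice":"B","confidence":90}', "BAD_TRIAL_ID"),
        ],
    )
    def test_violations_get_distinct_codes(self, text, code):
        with pytest.raises(ResponseParseError) as err:
            ap.parse_response_line(text)
        assert err.value.code == code

    def test_multiline_rejected(self):
        with pytest.raises(ResponseParseError) as err:
            ap.parse_response_line('{"trial_id":"t1",\n"choice":"A","confidence":5}')
        assert err.value.code == "NOT_ONE_LINE"

    def test_trailing_newline_is_tolerated(self):
        assert ap.parse_response_line(_line() + "\n").confidence == 90

    def test_confidence_zero_is_valid(self):
        assert ap.parse_response_line(_line(confidence=0)).confidence == 0


class TestParseLenient:
    def test_prose_wrapped_object_repaired(self):
        rec = ap.parse_response_line(
            'Sure! {"trial_id":"t007","choice":"B","confidence":90}', strict=False
        )
        assert rec.choice == "B" and rec.repaired

    def test_code_fence_repaired(self):
        rec = ap.parse_response_line("```json\n" + _line() + "\n```", strict=False)
        assert rec.confidence == 90 and rec.repaired

    def test_clean_line_not_marked_repaired(self):
        assert not ap.parse_response_line(_line(), strict=False).repaired

    def test_schema_violations_still_rejected(self):
        with pytest.raises(ResponseParseError):
            ap.parse_response_line(_line(confidence=101), strict=False)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    trial_id=st.text(
        st.characters(min_codepoint=33, max_codepoint=126, exclude_characters='"\\'),
        min_size=1,
        max_size=12,
    ),
    choice=st.sampled_from(["A", "B"]),
    confidence=st.integers(min_value=0, max_value=100),
)
def test_parser_accepts_exactly_the_schema_language(trial_id, choice, confidence):
    """Any instance of the schema parses; perturbed variants are rejected."""
    line = json.dumps(
        {"trial_id": trial_id, "choice": choice, "confidence": confidence},
        separators=(",", ":"),
    )
    rec = ap.parse_response_line(line)
    assert (rec.trial_id, rec.choice, rec.confidence) == (trial_id, choice, confidence)
    for bad in (
        "ok " + line,
        line + " done",
        line.replace('"choice"', '"pick"', 1),
        line[:-1],
    ):
        with pytest.raises(ResponseParseError):
            ap.parse_response_line(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(confidence=st.one_of(st.integers(min_value=101), st.integers(max_value=-1)))
def test_out_of_range_confidence_always_rejected(confidence):
    with pytest.raises(ResponseParseError) as err:
        ap.parse_response_line(_line(confidence=confidence))
    assert err.value.code == "CONF_RANGE"


class TestJoin:
    def test_complete_join_has_empty_anomaly_report(self, default_plan, clean_dataset):
        assert len(clean_dataset) == len(default_plan) == 190

    def test_orphan_response_counted_and_excluded(self, default_plan, profiles):
        clean, _ = profiles
        responses = ap.simulate_responses(default_plan, clean, seed=3)
        responses.append(ap.ResponseRecord("ghost-t0001", "A", 50))
        dataset, report = ap.join_responses(default_plan, responses)
        assert report.orphan_responses == ["ghost-t0001"]
        assert len(dataset) == 190

    def test_duplicate_keeps_first(self, default_plan, profiles):
        clean, _ = profiles
        responses = ap.simulate_responses(default_plan, clean, seed=3)
        first = responses[0]
        flipped = ap.ResponseRecord(first.trial_id, "B" if first.choice == "A" else "A", 1)
        dataset, report = ap.join_responses(default_plan, responses + [flipped])
        assert report.duplicate_responses == [first.trial_id]
        obs = next(o for o in dataset.observations if o.trial_id == first.trial_id)
        # the retained winner matches the FIRST response's choice
        trial = next(t for t in default_plan if t.trial_id == first.trial_id)
        want = trial.item_a if first.choice == "A" else trial.item_b
        assert obs.winner == want

    def test_missing_trial_counted(self, default_plan, profiles):
        clean, _ = profiles
        responses = ap.simulate_responses(default_plan, clean, seed=3)[:-1]
        dataset, report = ap.join_responses(default_plan, responses)
        assert report.missing_trials == [default_plan[-1].trial_id]
        assert len(dataset) == 189

    def test_winner_is_item_at_chosen_position(self):
        trial = ap.TrialRecord("x-t0001", "steel", "oak_hardwood", "anchor_anchor",
                               ap.pair_key("steel", "oak_hardwood"), 0, "pf", "w")
        ds, _ = ap.join_responses([trial], [ap.ResponseRecord("x-t0001", "A", 80)])
        assert ds.observations[0].winner == "steel"

    def test_position_flip_invariance(self, default_plan, profiles):
        """Swapping A/B and the recorded choice leaves observations unchanged."""
        clean, _ = profiles
        responses = ap.simulate_responses(default_plan, clean, seed=5)
        flipped_plan = [
            ap.TrialRecord(t.trial_id, t.item_b, t.item_a, t.block, t.pair_key,
                           t.repeat_index, t.prompt_family_id, t.wrapper_id)
            for t in default_plan
        ]
        flipped_responses = [
            ap.ResponseRecord(r.trial_id, "B" if r.choice == "A" else "A", r.confidence)
            for r in responses
        ]
        ds1, _ = ap.join_responses(default_plan, responses)
        ds2, _ = ap.join_responses(flipped_plan, flipped_responses)
        assert [(o.winner, o.loser) for o in ds1.observations] == [
            (o.winner, o.loser) for o in ds2.observations
        ]


class TestResponsesFileIO:
    def test_jsonl_round_trip(self, default_plan, profiles, tmp_path):
        clean, _ = profiles
        responses = ap.simulate_responses(default_plan, clean, seed=8)
        path = tmp_path / "resp.jsonl"
        ap.write_responses(responses, path)
        back, failures = ap.read_responses(path)
        assert failures == [] and back == responses

    def test_parse_failures_reported_per_line(self, tmp_path):
        path = tmp_path / "resp.jsonl"
        path.write_text(_line() + "\nnot json\n" + _line(confidence=200) + "\n")
        records, failures = ap.read_responses(path)
        assert len(records) == 1
        assert [f["code"] for f in failures] == ["NOT_JSON", "CONF_RANGE"]


class TestCatchTrials:
    def test_all_correct_is_one(self, default_spec, clean_dataset):
        res = ap.catch_trial_pass_rate(clean_dataset, default_spec)
        assert res.status == "computed" and res.pass_rate == 1.0

    def test_three_of_four_is_three_quarters(self, default_spec):
        trials = [
            ap.TrialRecord(f"c-t{i:04d}", "marshmallow", "steel", "catch",
                           "marshmallow|steel", i, "pf", "w")
            for i in range(4)
        ]
        choices = ["B", "B", "B", "A"]  # B = steel three times, A = marshmallow once
        ds, _ = ap.join_responses(
            trials, [ap.ResponseRecord(t.trial_id, c, 50) for t, c in zip(trials, choices)]
        )
        res = ap.catch_trial_pass_rate(ds, ap.default_panel_spec())
        assert res.pass_rate == 0.75 and res.n_catch == 4

    def test_no_catch_block_is_not_computed(self, default_spec, clean_dataset):
        no_catch = clean_dataset.exclude_block("catch")
        res = ap.catch_trial_pass_rate(no_catch, default_spec)
        assert res.status == "not_computed" and res.pass_rate is None
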