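import pytest

import anchorpanel as ap


@pytest.fixture(scope="session")
def default_spec():
    return ap.default_panel_spec(seed=7)


@pytest.fixture(scope="session")
def default_plan(default_spec):
    return ap.build_trial_plan(default_spec)


@pytest.fixture(scope="session")
def profiles():
    return ap.make_default_profiles()


@pytest.fixture(scope="session")
def clean_dataset(default_plan, profiles):
    clean, _ = profiles
    responses = ap.simulate_responses(default_plan, clean, seed=42)
    dataset, report = ap.join_responses(default_plan, responses)
    assert report.clean
    return dataset


@pytest.fixture(scope="session")
def clean_scale(clean_dataset, default_spec):
    return ap.fit_scale(clean_dataset, default_spec.axis, n_reps=300, seed=9)


@pytest.fixture(scope="session")
def degraded_dataset(default_plan, profiles):
    _, degraded = profiles
    responses = ap.simulate_responses(default_plan, degraded, seed=42)
    dataset, _ = ap.join_responses(default_plan, responses)
    return dataset


@pytest.fixture()
def tiny_spec():
    """Three-item panel, all pairs once, no repeats, no catch."""
    items = (
        ap.Item("lo", "Low", "anchor", 1),
        ap.Item("mid", "Mid", "anchor", 2),
        ap.Item("hi", "High", "anchor", 3),
    )
    return ap.PanelSpec(
        panel_version="tiny-v1",
        axis=ap.AxisSpec("hardness", "resistance to indentation", "lo", "hi"),
        items=items,
        block_counts={"anchor_anchor": 3},
        repeat_plan=ap.RepeatPlan(0, 2),
        seed=1,
    )
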