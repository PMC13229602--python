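"""Versioned panel instruments and deterministic trial-plan generation.

An anchored 2AFC panel is a fixed measurement instrument: a set of items
(reference anchors with a canonical hardness-like ordering, plus abstract
concept targets), an axis definition, a block composition, and a repeat
plan.  Given a seed, :func:`build_trial_plan` expands the instrument into a
concrete, archivable run file — every trial with its A/B positions already
assigned — because trial order and position are part of what makes two runs
of the same panel comparable.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Item",
    "AxisSpec",
    "RepeatPlan",
    "PanelSpec",
    "TrialRecord",
    "PanelConfigError",
    "TemplateError",
    "RunFileError",
    "pair_key",
    "build_trial_plan",
    "render_prompt",
    "write_run_file",
    "read_run_file",
    "default_panel_spec",
    "DEFAULT_PROMPT_TEMPLATE",
]

BLOCKS = ("concept_anchor", "concept_concept", "anchor_anchor", "catch")

#: The default hardness prompt.  The template is the instrument: rendering
#: substitutes only the three bracketed placeholders and must leave every
#: other byte untouched.
DEFAULT_PROMPT_TEMPLATE = (
    "Quality-assurance forced-choice trial. Compare A and B as same-sized "
    "solid materials. Hardness means resistance to indentation and "
    "scratching. Exclude brittleness, fragility, size, weight, emotional "
    "valence, moral desirability, and clinical importance. "
    "Trial_id: [TRIAL_ID]. A: [ITEM_A]. B: [ITEM_B]. "
    "Choose the harder item. Return exactly one line of JSON and no other "
    'text: {"trial_id":"[TRIAL_ID]","choice":"A" or "B",'
    '"confidence":[integer 0-100]}.'
)

PLACEHOLDERS = ("[TRIAL_ID]", "[ITEM_A]", "[ITEM_B]")


class PanelConfigError(ValueError):
    """The panel specification is internally inconsistent or infeasible."""


class TemplateError(ValueError):
    """A prompt template is missing a required placeholder."""


class RunFileError(ValueError):
    """A run file failed validation on read."""


def pair_key(item_a: str, item_b: str) -> str:
    """Canonical unordered-pair key: ids sorted lexicographically, joined by '|'."""
    return "|".join(sorted((item_a, item_b)))


@dataclass(frozen=True)
class Item:
    """One panel item: a material anchor or an abstract concept target."""

    item_id: str
    label: str
    role: str  # "anchor" | "concept"
    canonical_rank: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("anchor", "concept"):
            raise PanelConfigError(
                f"item {self.item_id!r}: role must be 'anchor' or 'concept', got {self.role!r}"
            )
        if self.role == "anchor" and self.canonical_rank is None:
            raise PanelConfigError(f"anchor {self.item_id!r} needs a canonical_rank")
        if self.role == "concept" and self.canonical_rank is not None:
            raise PanelConfigError(f"concept {self.item_id!r} must not carry a canonical_rank")


@dataclass(frozen=True)
class AxisSpec:
    """The measured axis and the two anchors pinned to its endpoints."""

    axis_id: str
    definition_text: str
    low_anchor: str
    high_anchor: str

    def __post_init__(self) -> None:
        if self.low_anchor == self.high_anchor:
            raise PanelConfigError("low_anchor and high_anchor must differ")


@dataclass(frozen=True)
class RepeatPlan:
    """How many unordered pairs are re-presented, and how many times each."""

    n_repeated_pairs: int
    reps_per_pair: int = 2

    def __post_init__(self) -> None:
        if self.n_repeated_pairs < 0:
            raise PanelConfigError("n_repeated_pairs must be >= 0")
        if self.reps_per_pair < 2:
            raise PanelConfigError("reps_per_pair must be >= 2")


@dataclass(frozen=True)
class TrialRecord:
    """One presented comparison: two items at randomized A/B positions."""

    trial_id: str
    item_a: str
    item_b: str
    block: str
    pair_key: str
    repeat_index: int
    prompt_family_id: str
    wrapper_id: str

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise PanelConfigError(f"trial {self.trial_id!r}: item_a == item_b")


@dataclass(frozen=True)
class PanelSpec:
    """The versioned instrument.

    ``block_counts`` maps block name -> number of distinct unordered pairs
    presented once in that block (catch trials instead re-present the pinned
    anchor pair ``block_counts['catch']`` times).  The repeat plan then adds
    ``n_repeated_pairs * (reps_per_pair - 1)`` extra presentations of pairs
    drawn from the non-catch blocks, so

        total trials = sum(block_counts.values())
                       + n_repeated_pairs * (reps_per_pair - 1)
    """

    panel_version: str
    axis: AxisSpec
    items: tuple[Item, ...]
    block_counts: Mapping[str, int]
    repeat_plan: RepeatPlan
    prompt_family_id: str = "baseline"
    wrapper_id: str = "plain"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "block_counts", dict(self.block_counts))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelConfigError(f"duplicate item_id(s): {dup}")
        ranks = [it.canonical_rank for it in self.items if it.role == "anchor"]
        if len(set(ranks)) != len(ranks):
            raise PanelConfigError("anchor canonical_ranks must be distinct")
        by_id = {it.item_id: it for it in self.items}
        for end in (self.axis.low_anchor, self.axis.high_anchor):
            if end not in by_id:
                raise PanelConfigError(f"axis anchor {end!r} not in panel items")
            if by_id[end].role != "anchor":
                raise PanelConfigError(f"axis anchor {end!r} does not have role 'anchor'")
        for block in self.block_counts:
            if block not in BLOCKS:
                raise PanelConfigError(f"unknown block {block!r}; expected one of {BLOCKS}")
        if any(v < 0 for v in self.block_counts.values()):
            raise PanelConfigError("block counts must be >= 0")

    # -- convenience views ------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def anchors(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.role == "anchor")

    @property
    def concepts(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.role == "concept")

    def total_trials(self) -> int:
        """Planned trial count (documented formula; verified by tests)."""
        reps_extra = self.repeat_plan.n_repeated_pairs * (self.repeat_plan.reps_per_pair - 1)
        return sum(self.block_counts.values()) + reps_extra

    def labels(self) -> dict[str, str]:
        return {it.item_id: it.label for it in self.items}

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "panel_version": self.panel_version,
            "axis": {
                "axis_id": self.axis.axis_id,
                "definition_text": self.axis.definition_text,
                "low_anchor": self.axis.low_anchor,
                "high_anchor": self.axis.high_anchor,
            },
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "role": it.role,
                    **({"canonical_rank": it.canonical_rank} if it.canonical_rank is not None else {}),
                }
                for it in self.items
            ],
            "block_counts": dict(self.block_counts),
            "repeat_plan": {
                "n_repeated_pairs": self.repeat_plan.n_repeated_pairs,
                "reps_per_pair": self.repeat_plan.reps_per_pair,
            },
            "prompt_family_id": self.prompt_family_id,
            "wrapper_id": self.wrapper_id,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelSpec":
        return cls(
            panel_version=d["panel_version"],
            axis=AxisSpec(**d["axis"]),
            items=tuple(Item(**it) for it in d["items"]),
            block_counts=dict(d["block_counts"]),
            repeat_plan=RepeatPlan(**d["repeat_plan"]),
            prompt_family_id=d.get("prompt_family_id", "baseline"),
            wrapper_id=d.get("wrapper_id", "plain"),
            seed=int(d.get("seed", 0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PanelSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Trial-plan generation
# ---------------------------------------------------------------------------


def _block_pools(spec: PanelSpec) -> dict[str, list[tuple[str, str]]]:
    """Eligible unordered pairs per block, in deterministic lexicographic order."""
    anchors = sorted(it.item_id for it in spec.anchors)
    concepts = sorted(it.item_id for it in spec.concepts)
    pinned = tuple(sorted((spec.axis.low_anchor, spec.axis.high_anchor)))
    aa = [tuple(sorted(p)) for p in itertools.combinations(anchors, 2)]
    # The pinned endpoint pair is reserved for the catch block when catch
    # trials are requested, so it cannot leak into anchor_anchor as a
    # duplicate presentation.
    if spec.block_counts.get("catch", 0) > 0:
        aa = [p for p in aa if p != pinned]
    return {
        "concept_anchor": [tuple(sorted((c, a))) for c, a in itertools.product(concepts, anchors)],
        "concept_concept": [tuple(sorted(p)) for p in itertools.combinations(concepts, 2)],
        "anchor_anchor": aa,
        "catch": [pinned],
    }


def build_trial_plan(spec: PanelSpec) -> list[TrialRecord]:
    """Expand a panel spec into a seeded, shuffled list of trials.

    Deterministic in ``spec`` (including its seed): the same spec always
    yields a byte-identical plan.  Catch trials re-present the pinned anchor
    pair (known expected winner); every other block samples distinct
    unordered pairs; the repeat plan then adds extra presentations of a
    seeded selection of non-catch pairs, each with independently randomized
    A/B order.
    """
    rng = np.random.default_rng(spec.seed)
    pools = _block_pools(spec)

    chosen: list[tuple[tuple[str, str], str, int]] = []  # (pair, block, repeat_index)
    non_catch_pairs: list[tuple[str, str]] = []
    for block in ("concept_anchor", "concept_concept", "anchor_anchor"):
        want = spec.block_counts.get(block, 0)
        pool = pools[block]
        if want > len(pool):
            raise PanelConfigError(
                f"block {block!r} requests {want} pairs but only {len(pool)} distinct "
                f"pairs exist"
            )
        idx = rng.choice(len(pool), size=want, replace=False) if want else []
        picked = [pool[i] for i in sorted(idx)]
        chosen.extend((p, block, 0) for p in picked)
        non_catch_pairs.extend(picked)

    n_catch = spec.block_counts.get("catch", 0)
    catch_pair = pools["catch"][0]
    chosen.extend((catch_pair, "catch", r) for r in range(n_catch))

    rp = spec.repeat_plan
    if rp.n_repeated_pairs > len(non_catch_pairs):
        raise PanelConfigError(
            f"repeat plan requests {rp.n_repeated_pairs} pairs but only "
            f"{len(non_catch_pairs)} non-catch pairs are in the plan"
        )
    if rp.n_repeated_pairs:
        ridx = rng.choice(len(non_catch_pairs), size=rp.n_repeated_pairs, replace=False)
        block_of = {p: b for p, b, _ in chosen if b != "catch"}
        for i in sorted(ridx):
            p = non_catch_pairs[i]
            for r in range(1, rp.reps_per_pair):
                chosen.append((p, block_of[p], r))

    # Presentation order, then per-trial A/B randomization, then ids.
    order = rng.permutation(len(chosen))
    prefix = hashlib.sha256(spec.panel_version.encode("utf-8")).hexdigest()[:6]
    plan: list[TrialRecord] = []
    for seq, j in enumerate(order):
        (x, y), block, rep = chosen[j]
        a, b = (x, y) if rng.random() < 0.5 else (y, x)
        plan.append(
            TrialRecord(
                trial_id=f"{prefix}-t{seq + 1:04d}",
                item_a=a,
                item_b=b,
                block=block,
                pair_key=pair_key(a, b),
                repeat_index=rep,
                prompt_family_id=spec.prompt_family_id,
                wrapper_id=spec.wrapper_id,
            )
        )
    return plan


def expected_catch_winner(spec: PanelSpec) -> str:
    """The item a competent responder must pick on a catch trial (higher rank)."""
    lo = spec.item(spec.axis.low_anchor)
    hi = spec.item(spec.axis.high_anchor)
    return hi.item_id if hi.canonical_rank > lo.canonical_rank else lo.item_id


# ---------------------------------------------------------------------------
# Prompt rendering
# ---------------------------------------------------------------------------


def render_prompt(
    trial: TrialRecord,
    template: str,
    labels: Mapping[str, str] | None = None,
) -> str:
    """Substitute the three placeholders; preserve every other byte.

    ``labels`` maps item_id -> display label (``PanelSpec.labels()``);
    without it, raw item ids are inserted.
    """
    for ph in PLACEHOLDERS:
        if ph not in template:
            raise TemplateError(f"template is missing required placeholder {ph}")
    labels = labels or {}
    out = template.replace("[TRIAL_ID]", trial.trial_id)
    out = out.replace("[ITEM_A]", labels.get(trial.item_a, trial.item_a))
    out = out.replace("[ITEM_B]", labels.get(trial.item_b, trial.item_b))
    return out


# ---------------------------------------------------------------------------
# Run-file I/O
# ---------------------------------------------------------------------------

RUN_FILE_COLUMNS = (
    "trial_id",
    "block",
    "item_a",
    "item_b",
    "pair_key",
    "repeat_index",
    "prompt_family_id",
    "wrapper_id",
)


def write_run_file(plan: Sequence[TrialRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RUN_FILE_COLUMNS)
        for t in plan:
            w.writerow(
                [t.trial_id, t.block, t.item_a, t.item_b, t.pair_key,
                 t.repeat_index, t.prompt_family_id, t.wrapper_id]
            )


def read_run_file(path, spec: PanelSpec | None = None) -> list[TrialRecord]:
    """Read a run file back; validation errors carry the offending row number.

    With ``spec`` given, every item id is checked against the panel.
    """
    plan: list[TrialRecord] = []
    seen: set[str] = set()
    known = set(spec.item_ids) if spec is not None else None
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(RUN_FILE_COLUMNS) - set(reader.fieldnames):
            missing = sorted(set(RUN_FILE_COLUMNS) - set(reader.fieldnames or []))
            raise RunFileError(f"run file missing column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            tid = row["trial_id"]
            if tid in seen:
                raise RunFileError(f"row {rownum}: duplicate trial_id {tid!r}")
            seen.add(tid)
            if known is not None:
                for col in ("item_a", "item_b"):
                    if row[col] not in known:
                        raise RunFileError(
                            f"row {rownum}: unknown item_id {row[col]!r} in column {col}"
                        )
            if row["pair_key"] != pair_key(row["item_a"], row["item_b"]):
                raise RunFileError(f"row {rownum}: pair_key does not match items")
            try:
                rep = int(row["repeat_index"])
            except ValueError as exc:
                raise RunFileError(f"row {rownum}: bad repeat_index") from exc
            try:
                plan.append(
                    TrialRecord(
                        trial_id=tid,
                        item_a=row["item_a"],
                        item_b=row["item_b"],
                        block=row["block"],
                        pair_key=row["pair_key"],
                        repeat_index=rep,
                        prompt_family_id=row["prompt_family_id"],
                        wrapper_id=row["wrapper_id"],
                    )
                )
            except PanelConfigError as exc:
                raise RunFileError(f"row {rownum}: {exc}") from exc
    return plan


# ---------------------------------------------------------------------------
# Default instrument
# ---------------------------------------------------------------------------

_DEFAULT_ANCHORS = [
    ("marshmallow", "Marshmallow", 1),
    ("oak_hardwood", "Oak hardwood", 2),
    ("abs_plastic_block", "ABS plastic block", 3),
    ("polycarbonate_sheet", "Polycarbonate sheet", 4),
    ("acrylic_sheet", "Acrylic sheet", 5),
    ("aluminum_plate", "Aluminum plate", 6),
    ("dry_bone", "Dry bone", 7),
    ("window_glass", "Window glass", 8),
    ("porcelain", "Porcelain", 9),
    ("steel", "Steel", 10),
]

_DEFAULT_CONCEPTS = [
    ("life", "Life"),
    ("kindness", "Kindness"),
    ("silence", "Silence"),
    ("justice", "Justice"),
    ("death", "Death"),
]


def default_panel_spec(seed: int = 0, panel_version: str = "hardness-v1") -> PanelSpec:
    """The stock 190-trial hardness panel: 10 anchors, 5 concepts.

    Composition is a reconstruction, not a uniquely determined plan: all 50
    concept-anchor and 10 concept-concept pairs once, all 44 non-pinned
    anchor-anchor pairs once, 23 catch presentations of the pinned
    Marshmallow/Steel pair, and a second presentation of 63 seeded non-catch
    pairs — 190 trials, 64 unordered pairs seen more than once (the 63
    repeat-plan pairs plus the catch pair).
    """
    items = [Item(i, lbl, "anchor", rk) for i, lbl, rk in _DEFAULT_ANCHORS]
    items += [Item(i, lbl, "concept") for i, lbl in _DEFAULT_CONCEPTS]
    return PanelSpec(
        panel_version=panel_version,
        axis=AxisSpec(
            axis_id="hardness",
            definition_text=(
                "Hardness means resistance to indentation and scratching. "
                "Exclude brittleness, fragility, size, weight, emotional "
                "valence, moral desirability, and clinical importance."
            ),
            low_anchor="marshmallow",
            high_anchor="steel",
        ),
        items=tuple(items),
        block_counts={
            "concept_anchor": 50,
            "concept_concept": 10,
            "anchor_anchor": 44,
            "catch": 23,
        },
        repeat_plan=RepeatPlan(n_repeated_pairs=63, reps_per_pair=2),
        seed=seed,
    )
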