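"""Parsing and joining of forced-choice JSON responses.

The response contract is one line of JSON per trial with exactly three
keys — trial_id, choice ("A"|"B"), confidence (integer 0-100) — and no
other text.  Strict parsing enforces that contract literally; anything the
responder wraps around the object (prose, code fences) is itself a QC
signal, so lenient parsing repairs it but always reports that it did.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel_design import PanelSpec, TrialRecord, expected_catch_winner

__all__ = [
    "ResponseRecord",
    "Observation",
    "ComparisonDataset",
    "IngestionReport",
    "ResponseParseError",
    "CatchResult",
    "parse_response_line",
    "read_responses",
    "write_responses",
    "join_responses",
    "catch_trial_pass_rate",
]


class ResponseParseError(ValueError):
    """A raw response line violating the schema; ``code`` identifies how.

    Codes: NOT_ONE_LINE, NOT_JSON, EXTRA_TEXT, NOT_OBJECT, WRONG_KEYS,
    BAD_TRIAL_ID, BAD_CHOICE, CONF_NOT_INT, CONF_RANGE.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class ResponseRecord:
    """One parsed forced-choice answer."""

    trial_id: str
    choice: str  # "A" | "B"
    confidence: int
    repaired: bool = False  # True when lenient parsing had to strip wrapping

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B"):
            raise ResponseParseError("BAD_CHOICE", f"choice must be 'A' or 'B', got {self.choice!r}")
        if not isinstance(self.confidence, int) or isinstance(self.confidence, bool):
            raise ResponseParseError("CONF_NOT_INT", "confidence must be an integer")
        if not 0 <= self.confidence <= 100:
            raise ResponseParseError("CONF_RANGE", f"confidence {self.confidence} outside [0, 100]")


_FENCE_RE = re.compile(r"^```(?:json)?\s*|\s*```$")


def _validate_object(obj) -> ResponseRecord:
    if not isinstance(obj, dict):
        raise ResponseParseError("NOT_OBJECT", "response is not a JSON object")
    if set(obj) != {"trial_id", "choice", "confidence"}:
        raise ResponseParseError(
            "WRONG_KEYS",
            f"expected exactly keys trial_id/choice/confidence, got {sorted(obj)}",
        )
    if not isinstance(obj["trial_id"], str) or not obj["trial_id"]:
        raise ResponseParseError("BAD_TRIAL_ID", "trial_id must be a non-empty string")
    choice = obj["choice"]
    if choice not in ("A", "B"):
        raise ResponseParseError("BAD_CHOICE", f"choice must be 'A' or 'B', got {choice!r}")
    conf = obj["confidence"]
    if isinstance(conf, bool) or not isinstance(conf, int):
        raise ResponseParseError("CONF_NOT_INT", f"confidence must be a JSON integer, got {conf!r}")
    if not 0 <= conf <= 100:
        raise ResponseParseError("CONF_RANGE", f"confidence {conf} outside [0, 100]")
    return ResponseRecord(obj["trial_id"], choice, conf)


def parse_response_line(text: str, strict: bool = True) -> ResponseRecord:
    """Parse one raw response line.

    Strict mode accepts exactly one JSON object on one line with exactly the
    three schema keys and nothing else — the language the instrument's
    "no other text" instruction defines.  Lenient mode strips surrounding
    whitespace/code fences, extracts the first top-level ``{...}`` object,
    and marks the record ``repaired`` if it had to change anything.
    """
    line = text[:-1] if text.endswith("\n") else text
    if "\n" in line:
        if strict:
            raise ResponseParseError("NOT_ONE_LINE", "response spans multiple lines")
        line = " ".join(line.splitlines())
    if strict:
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            # Distinguish prose around a valid object from plain bad JSON.
            if _extract_object(line) is not None:
                raise ResponseParseError("EXTRA_TEXT", "text surrounds the JSON object") from exc
            raise ResponseParseError("NOT_JSON", f"not valid JSON: {exc}") from exc
        return _validate_object(obj)
    # lenient
    cleaned = _FENCE_RE.sub("", line.strip()).strip()
    try:
        obj = json.loads(cleaned)
        repaired = cleaned != line
    except json.JSONDecodeError:
        fragment = _extract_object(cleaned)
        if fragment is None:
            raise ResponseParseError("NOT_JSON", "no JSON object found in line")
        obj = json.loads(fragment)
        repaired = True
    rec = _validate_object(obj)
    return ResponseRecord(rec.trial_id, rec.choice, rec.confidence, repaired=repaired)


def _extract_object(line: str) -> str | None:
    """First balanced top-level {...} substring that parses as JSON, else None."""
    start = line.find("{")
    while start != -1:
        depth = 0
        in_str = False
        esc = False
        for i in range(start, len(line)):
            ch = line[i]
            if in_str:
                if esc:
                    esc = False
                elif ch == "\\":
                    esc = True
                elif ch == '"':
                    in_str = False
            elif ch == '"':
                in_str = True
            elif ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    frag = line[start : i + 1]
                    try:
                        json.loads(frag)
                        return frag
                    except json.JSONDecodeError:
                        break
        start = line.find("{", start + 1)
    return None


# ---------------------------------------------------------------------------
# Response files
# ---------------------------------------------------------------------------


def write_responses(records: Sequence[ResponseRecord], path) -> None:
    """JSON-Lines, one schema-conformant object per record."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {"trial_id": r.trial_id, "choice": r.choice, "confidence": r.confidence},
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_responses(path, strict: bool = True) -> tuple[list[ResponseRecord], list[dict]]:
    """Read a responses file; returns (records, parse_failures).

    Accepts JSON-Lines, or a CSV with a ``raw_response`` column.  Parse
    failures are collected per line with their error code — they are QC
    signals, not fatal errors.
    """
    path = str(path)
    records: list[ResponseRecord] = []
    failures: list[dict] = []

    def _try(lineno: int, raw: str) -> None:
        if not raw.strip():
            return
        try:
            records.append(parse_response_line(raw, strict=strict))
        except ResponseParseError as exc:
            failures.append({"line": lineno, "code": exc.code, "message": str(exc)})

    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        fh.seek(0)
        if "raw_response" in first.split(","):
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                _try(lineno, row["raw_response"])
        else:
            for lineno, raw in enumerate(fh, start=1):
                _try(lineno, raw)
    return records, failures


# ---------------------------------------------------------------------------
# Joining responses to the plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Observation:
    """A paired-comparison outcome: who beat whom, with metadata."""

    winner: str
    loser: str
    confidence: int
    trial_id: str
    block: str
    pair_key: str
    prompt_family_id: str
    wrapper_id: str


@dataclass
class ComparisonDataset:
    """Winner/loser encoding of all matched trials — the scaling input."""

    items: tuple[str, ...]
    observations: list[Observation]

    def __post_init__(self) -> None:
        idx = set(self.items)
        for o in self.observations:
            if o.winner not in idx or o.loser not in idx:
                raise ValueError(f"observation {o.trial_id}: item not in index")

    def __len__(self) -> int:
        return len(self.observations)

    def filter(self, **conditions: str) -> "ComparisonDataset":
        """Subset by metadata equality, e.g. ``filter(block='catch')``."""
        obs = [
            o
            for o in self.observations
            if all(getattr(o, k) == v for k, v in conditions.items())
        ]
        return ComparisonDataset(self.items, obs)

    def exclude_block(self, block: str) -> "ComparisonDataset":
        return ComparisonDataset(
            self.items, [o for o in self.observations if o.block != block]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": o.trial_id,
                    "winner": o.winner,
                    "loser": o.loser,
                    "confidence": o.confidence,
                    "block": o.block,
                    "pair_key": o.pair_key,
                    "prompt_family_id": o.prompt_family_id,
                    "wrapper_id": o.wrapper_id,
                }
                for o in self.observations
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, items: Iterable[str] | None = None) -> "ComparisonDataset":
        df = pd.read_csv(path)
        obs = [
            Observation(
                winner=r.winner,
                loser=r.loser,
                confidence=int(r.confidence),
                trial_id=r.trial_id,
                block=r.block,
                pair_key=r.pair_key,
                prompt_family_id=str(r.prompt_family_id),
                wrapper_id=str(r.wrapper_id),
            )
            for r in df.itertuples()
        ]
        if items is None:
            items = sorted(set(df.winner) | set(df.loser))
        return cls(tuple(items), obs)


@dataclass
class IngestionReport:
    """Anomaly accounting for one run's join; nothing here is fatal."""

    n_trials: int = 0
    n_responses: int = 0
    n_matched: int = 0
    missing_trials: list[str] = field(default_factory=list)
    orphan_responses: list[str] = field(default_factory=list)
    duplicate_responses: list[str] = field(default_factory=list)
    parse_failures: list[dict] = field(default_factory=list)
    n_repaired: int = 0

    @property
    def clean(self) -> bool:
        return not (
            self.missing_trials
            or self.orphan_responses
            or self.duplicate_responses
            or self.parse_failures
        )

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_responses": self.n_responses,
            "n_matched": self.n_matched,
            "missing_trials": self.missing_trials,
            "orphan_responses": self.orphan_responses,
            "duplicate_responses": self.duplicate_responses,
            "parse_failures": self.parse_failures,
            "n_repaired": self.n_repaired,
        }


def join_responses(
    plan: Sequence[TrialRecord],
    responses: Sequence[ResponseRecord],
    items: Iterable[str] | None = None,
    parse_failures: Sequence[dict] = (),
) -> tuple[ComparisonDataset, IngestionReport]:
    """Match responses to trials by trial_id and resolve winners.

    The winner is the item occupying the chosen position on that specific
    trial, so A/B counterbalancing is undone here.  Duplicates keep the
    first response; orphans, missing trials, duplicates and parse failures
    are counted, never raised.
    """
    by_trial = {t.trial_id: t for t in plan}
    report = IngestionReport(
        n_trials=len(plan),
        n_responses=len(responses),
        parse_failures=list(parse_failures),
    )
    first_seen: dict[str, ResponseRecord] = {}
    for r in responses:
        if r.trial_id not in by_trial:
            report.orphan_responses.append(r.trial_id)
            continue
        if r.trial_id in first_seen:
            report.duplicate_responses.append(r.trial_id)
            continue
        first_seen[r.trial_id] = r
        if r.repaired:
            report.n_repaired += 1

    obs: list[Observation] = []
    for t in plan:
        r = first_seen.get(t.trial_id)
        if r is None:
            report.missing_trials.append(t.trial_id)
            continue
        winner, loser = (t.item_a, t.item_b) if r.choice == "A" else (t.item_b, t.item_a)
        obs.append(
            Observation(
                winner=winner,
                loser=loser,
                confidence=r.confidence,
                trial_id=t.trial_id,
                block=t.block,
                pair_key=t.pair_key,
                prompt_family_id=t.prompt_family_id,
                wrapper_id=t.wrapper_id,
            )
        )
    report.n_matched = len(obs)

    if items is None:
        ids = sorted({x for t in plan for x in (t.item_a, t.item_b)})
    else:
        ids = list(items)
    return ComparisonDataset(tuple(ids), obs), report


# ---------------------------------------------------------------------------
# Catch trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatchResult:
    status: str  # "computed" | "not_computed"
    pass_rate: float | None
    n_pass: int
    n_catch: int
    outcomes: tuple[tuple[str, bool], ...]  # (trial_id, passed)


def catch_trial_pass_rate(dataset: ComparisonDataset, spec: PanelSpec) -> CatchResult:
    """Fraction of catch trials where the observed winner is the expected one.

    The expected winner is the catch pair's higher-canonical-rank anchor.
    No catch observations → explicit "not_computed", never 0.
    """
    catch = [o for o in dataset.observations if o.block == "catch"]
    if not catch:
        return CatchResult("not_computed", None, 0, 0, ())
    expected = expected_catch_winner(spec)
    outcomes = tuple((o.trial_id, o.winner == expected) for o in catch)
    n_pass = sum(ok for _, ok in outcomes)
    return CatchResult("computed", n_pass / len(catch), n_pass, len(catch), outcomes)
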