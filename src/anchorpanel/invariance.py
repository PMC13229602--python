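"""Pairwise-winner invariance across wrapper or prompt-family conditions.

Superficial wrapper changes (style, language) should preserve every
unordered pair's winner; a substantive prompt-family change may not.  The
comparison is deliberately descriptive: winners per pair under each
condition, the pairs on which they differ (reversals), and the resulting
agreement percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from collections import Counter, defaultdict

from .response_io import ComparisonDataset

__all__ = [
    "WinnerMap",
    "InvarianceReport",
    "InvarianceError",
    "derive_winner_map",
    "compare_conditions",
    "render_invariance_table",
]

INDETERMINATE = "indeterminate"


class InvarianceError(ValueError):
    pass


@dataclass(frozen=True)
class WinnerMap:
    """Majority winner per unordered pair under one condition."""

    condition_id: str
    winners: dict[str, str]  # pair_key -> item_id or "indeterminate"

    def determinate(self) -> dict[str, str]:
        return {k: w for k, w in self.winners.items() if w != INDETERMINATE}


def derive_winner_map(dataset: ComparisonDataset, condition_id: str) -> WinnerMap:
    """Winner per pair_key by majority across that pair's observations.

    The dataset should already be filtered to a single condition (the
    label is carried through for reporting).  Exact ties are recorded as
    indeterminate rather than broken arbitrarily.
    """
    if not dataset.observations:
        raise InvarianceError("empty dataset: no observations to derive winners from")
    counts: dict[str, Counter] = defaultdict(Counter)
    for o in dataset.observations:
        counts[o.pair_key][o.winner] += 1
    winners: dict[str, str] = {}
    for pk, c in counts.items():
        ranked = c.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            winners[pk] = INDETERMINATE
        else:
            winners[pk] = ranked[0][0]
    return WinnerMap(condition_id, winners)


@dataclass(frozen=True)
class InvarianceReport:
    condition_a: str
    condition_b: str
    n_pairs: int  # pairs determinate in both conditions
    reversals: int
    agreement_pct: float  # one decimal
    reversal_list: tuple[str, ...]
    indeterminate_pairs: tuple[str, ...]  # shared pairs dropped for ties

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n_pairs": self.n_pairs,
            "reversals": self.reversals,
            "agreement_pct": self.agreement_pct,
            "reversal_list": list(self.reversal_list),
            "indeterminate_pairs": list(self.indeterminate_pairs),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def compare_conditions(map_a: WinnerMap, map_b: WinnerMap) -> InvarianceReport:
    """Count winner reversals over the pairs both conditions determined.

    Pairs indeterminate in either condition are excluded from the
    denominator and listed separately.  Agreement is reported to one
    decimal: 100 * (n_pairs - reversals) / n_pairs.
    """
    det_a, det_b = map_a.determinate(), map_b.determinate()
    shared_all = set(map_a.winners) & set(map_b.winners)
    shared = sorted(set(det_a) & set(det_b))
    if not shared:
        raise InvarianceError(
            f"conditions {map_a.condition_id!r} and {map_b.condition_id!r} share no "
            f"determinate pairs"
        )
    reversals = [pk for pk in shared if det_a[pk] != det_b[pk]]
    n = len(shared)
    return InvarianceReport(
        condition_a=map_a.condition_id,
        condition_b=map_b.condition_id,
        n_pairs=n,
        reversals=len(reversals),
        agreement_pct=round(100.0 * (n - len(reversals)) / n, 1),
        reversal_list=tuple(sorted(reversals)),
        indeterminate_pairs=tuple(sorted(shared_all - set(shared))),
    )


def render_invariance_table(reports: list[InvarianceReport], axis_id: str = "") -> str:
    """Text table: Axis / Comparison / n / Reversals / Agreement (%)."""
    header = f"{'Axis':<10}{'Comparison':<45}{'Pairs':>6}{'Reversals':>11}{'Agreement (%)':>15}"
    lines = [header]
    for r in reports:
        comp = f"{r.condition_a} vs {r.condition_b}"
        lines.append(
            f"{axis_id:<10}{comp:<45}{r.n_pairs:>6}{r.reversals:>11}{r.agreement_pct:>15.1f}"
        )
    return "\n".join(lines)
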