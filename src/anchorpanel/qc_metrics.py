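"""Quality-control metrics: repeatability, confidence calibration, anchor order.

Three behavioral checks summarize whether a run behaved like a usable
measurement instrument: repeated unordered pairs should yield the same
winner (repeatability), reported confidence should track the fitted
distance between the compared items (a margin-like signal), and the
reference anchors should come out in their canonical order.  Each metric
degrades to an explicit "not_computed" status rather than a misleading
zero when its inputs are absent.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel_design import Item, PanelSpec
from .response_io import CatchResult, ComparisonDataset, catch_trial_pass_rate
from .bt_scaling import FittedScale

__all__ = [
    "AgreementResult",
    "CorrelationResult",
    "AnchorOrderResult",
    "QCThresholds",
    "QCReport",
    "repeated_pair_agreement",
    "confidence_distance_correlation",
    "anchor_order_check",
    "compile_qc_report",
    "render_qc_table",
]


@dataclass(frozen=True)
class AgreementResult:
    status: str  # "computed" | "not_computed"
    fraction: float | None
    n_agree: int
    n_pairs: int

    @property
    def percent(self) -> str:
        """Rendered to one decimal, e.g. '90.6%'."""
        if self.status != "computed":
            return "not computed"
        return f"{100.0 * self.fraction:.1f}%"


def repeated_pair_agreement(
    dataset: ComparisonDataset, require_unanimity: bool = True
) -> AgreementResult:
    """Agreement of inferred winners across repeated unordered pairs.

    A pair presented n>=2 times agrees when all its observations name the
    same winner (default, the strict reading) or, with
    ``require_unanimity=False``, when a strict majority winner exists.
    """
    winners: dict[str, list[str]] = defaultdict(list)
    for o in dataset.observations:
        winners[o.pair_key].append(o.winner)
    repeated = {k: v for k, v in winners.items() if len(v) >= 2}
    if not repeated:
        return AgreementResult("not_computed", None, 0, 0)
    n_agree = 0
    for ws in repeated.values():
        if require_unanimity:
            n_agree += len(set(ws)) == 1
        else:
            top = max(set(ws), key=ws.count)
            n_agree += ws.count(top) * 2 > len(ws)
    return AgreementResult("computed", n_agree / len(repeated), n_agree, len(repeated))


@dataclass(frozen=True)
class CorrelationResult:
    status: str  # "computed" | "not_computed" | "degenerate"
    r: float | None
    ci_low: float | None
    ci_high: float | None
    n: int


def confidence_distance_correlation(
    dataset: ComparisonDataset,
    scale: FittedScale,
    exclude_catch: bool = True,
    ci_method: str = "fisher",
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson r between reported confidence and |anchored score difference|.

    Catch trials are excluded by default (they probe attention, not
    graded distance).  The 95% CI uses the Fisher z transform; a
    nonparametric bootstrap CI is available with ``ci_method='bootstrap'``.
    Zero variance in either variable yields a "degenerate" status.
    """
    obs = dataset.observations
    if exclude_catch:
        obs = [o for o in obs if o.block != "catch"]
    conf = np.array([o.confidence for o in obs], dtype=float)
    dist = np.array(
        [abs(scale.scores[o.winner] - scale.scores[o.loser]) for o in obs], dtype=float
    )
    n = conf.size
    if n < 3:
        return CorrelationResult("not_computed", None, None, None, n)
    if conf.std() == 0.0 or dist.std() == 0.0:
        return CorrelationResult("degenerate", None, None, None, n)
    r = float(stats.pearsonr(conf, dist).statistic)
    if ci_method == "fisher":
        if n <= 3 or abs(r) == 1.0:
            lo = hi = r
        else:
            z = math.atanh(r)
            se = 1.0 / math.sqrt(n - 3)
            zc = stats.norm.ppf(0.975)
            lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        rs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            c, d = conf[idx], dist[idx]
            if c.std() == 0.0 or d.std() == 0.0:
                continue
            rs.append(stats.pearsonr(c, d).statistic)
        lo, hi = (float(x) for x in np.percentile(rs, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # the CI must contain the point estimate
    lo, hi = min(lo, r), max(hi, r)
    return CorrelationResult("computed", r, float(lo), float(hi), n)


@dataclass(frozen=True)
class AnchorOrderResult:
    status: str
    violations: tuple[tuple[str, str], ...]  # (lower-ranked, higher-ranked) inverted pairs
    n_violations: int
    n_pairs: int  # adjacent anchor pairs checked


def anchor_order_check(scale: FittedScale, items: list[Item] | tuple[Item, ...]) -> AnchorOrderResult:
    """Check fitted scores against the canonical anchor ordering.

    Anchors are sorted by canonical_rank; each adjacent pair whose fitted
    scores invert the canonical order is a violation.  The denominator is
    the number of adjacent pairs (9 for a 10-anchor panel).
    """
    anchors = sorted(
        (it for it in items if it.role == "anchor"), key=lambda it: it.canonical_rank
    )
    if len(anchors) < 2:
        return AnchorOrderResult("not_computed", (), 0, 0)
    violations = []
    for lo, hi in zip(anchors, anchors[1:]):
        if scale.scores[lo.item_id] >= scale.scores[hi.item_id]:
            violations.append((lo.item_id, hi.item_id))
    return AnchorOrderResult(
        "computed", tuple(violations), len(violations), len(anchors) - 1
    )


@dataclass(frozen=True)
class QCThresholds:
    """Flag triggers; all configurable, defaults chosen as review triggers
    separating a clean high-agreement run from a visibly degraded one."""

    min_repeat_agreement: float = 0.95  # below -> LOW_REPEAT
    min_confidence_r: float = 0.6  # below -> WEAK_CONFIDENCE_CALIBRATION
    min_catch_pass_rate: float = 1.0  # below -> CATCH_FAIL
    # any anchor-order inversion always raises ANCHOR_ORDER


@dataclass
class QCReport:
    repeat_agreement: AgreementResult
    confidence_distance_r: CorrelationResult
    catch: CatchResult
    anchor_order: AnchorOrderResult
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "repeat_agreement": {
                "status": self.repeat_agreement.status,
                "fraction": self.repeat_agreement.fraction,
                "n_agree": self.repeat_agreement.n_agree,
                "n_pairs": self.repeat_agreement.n_pairs,
            },
            "confidence_distance_r": {
                "status": self.confidence_distance_r.status,
                "r": self.confidence_distance_r.r,
                "ci_low": self.confidence_distance_r.ci_low,
                "ci_high": self.confidence_distance_r.ci_high,
                "n": self.confidence_distance_r.n,
            },
            "catch": {
                "status": self.catch.status,
                "pass_rate": self.catch.pass_rate,
                "n_pass": self.catch.n_pass,
                "n_catch": self.catch.n_catch,
            },
            "anchor_order": {
                "status": self.anchor_order.status,
                "violations": [list(v) for v in self.anchor_order.violations],
                "n_violations": self.anchor_order.n_violations,
                "n_pairs": self.anchor_order.n_pairs,
            },
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def compile_qc_report(
    dataset: ComparisonDataset,
    scale: FittedScale,
    spec: PanelSpec,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Aggregate the QC metrics and raise flags from the thresholds.

    Metrics whose inputs are absent carry their not-computed status and
    never trigger a flag.
    """
    agree = repeated_pair_agreement(dataset)
    corr = confidence_distance_correlation(dataset, scale)
    catch = catch_trial_pass_rate(dataset, spec)
    order = anchor_order_check(scale, spec.items)

    flags: list[str] = []
    if agree.status == "computed" and agree.fraction < thresholds.min_repeat_agreement:
        flags.append("LOW_REPEAT")
    if order.status == "computed" and order.n_violations > 0:
        flags.append("ANCHOR_ORDER")
    if corr.status == "computed" and corr.r < thresholds.min_confidence_r:
        flags.append("WEAK_CONFIDENCE_CALIBRATION")
    if catch.status == "computed" and catch.pass_rate < thresholds.min_catch_pass_rate:
        flags.append("CATCH_FAIL")
    return QCReport(agree, corr, catch, order, flags)


def render_qc_table(report: QCReport, scale: FittedScale) -> str:
    """Human-readable summary table (metric / value layout)."""
    rows = [
        ("Bradley-Terry classification accuracy", f"{scale.accuracy:.3f}"),
        ("Bradley-Terry log loss", f"{scale.log_loss:.4f}"),
        (
            f"Repeated-pair agreement (n={report.repeat_agreement.n_pairs} pairs)",
            report.repeat_agreement.percent
            + (
                f" ({report.repeat_agreement.n_agree}/{report.repeat_agreement.n_pairs})"
                if report.repeat_agreement.status == "computed"
                else ""
            ),
        ),
    ]
    c = report.confidence_distance_r
    if c.status == "computed":
        rows.append(
            (
                "Confidence vs absolute score difference",
                f"r = {c.r:.3f} (95% CI {c.ci_low:.3f}-{c.ci_high:.3f})",
            )
        )
    else:
        rows.append(("Confidence vs absolute score difference", c.status))
    if report.catch.status == "computed":
        rows.append(
            ("Catch-trial pass rate", f"{report.catch.pass_rate:.3f} "
             f"({report.catch.n_pass}/{report.catch.n_catch})")
        )
    else:
        rows.append(("Catch-trial pass rate", "not computed"))
    o = report.anchor_order
    if o.status == "computed":
        detail = "none" if not o.violations else "; ".join(f"{a} >= {b}" for a, b in o.violations)
        rows.append((f"Anchor-order violations ({o.n_violations}/{o.n_pairs})", detail))
    rows.append(("Flags", ", ".join(report.flags) if report.flags else "none"))
    width = max(len(k) for k, _ in rows)
    return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)
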