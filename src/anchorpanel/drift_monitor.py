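"""Baseline behavioral signatures and rerun comparison.

The governance loop this module supports: run the panel once under a
version-controlled instrument, store the fitted scale + QC summary as a
baseline signature, and compare every later rerun against it.  Signatures
store summaries, not raw trials; the raw artifacts (prompt template, run
file) are referenced by digest so a later comparison can prove it used the
same instrument.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .bt_scaling import FittedScale
from .qc_metrics import QCReport

__all__ = [
    "RunSignature",
    "DriftThresholds",
    "DriftReport",
    "SignatureIntegrityError",
    "NonComparableError",
    "instrument_hash",
    "build_signature",
    "save_signature",
    "load_signature",
    "compare_to_baseline",
    "render_drift_report",
]


class SignatureIntegrityError(RuntimeError):
    """Stored signature or referenced instrument artifacts were altered."""


class NonComparableError(ValueError):
    """Two signatures do not describe the same instrument/item set."""


def instrument_hash(template_bytes: bytes, run_file_bytes: bytes) -> str:
    """Digest of (prompt template bytes + run file bytes): the instrument id."""
    h = hashlib.sha256()
    h.update(template_bytes)
    h.update(run_file_bytes)
    return h.hexdigest()


@dataclass(frozen=True)
class RunSignature:
    signature_id: str
    panel_version: str
    axis_id: str
    prompt_family_id: str
    wrapper_id: str
    timestamp: str
    scale: FittedScale
    qc: dict  # QCReport.to_dict() summary
    analysis_config: dict  # l2_lambda, bootstrap reps/seed, ...
    instrument_hash: str
    artifacts: dict = field(default_factory=dict)  # name -> {"path":..., "sha256":...}

    def to_dict(self) -> dict:
        return {
            "signature_id": self.signature_id,
            "panel_version": self.panel_version,
            "axis_id": self.axis_id,
            "prompt_family_id": self.prompt_family_id,
            "wrapper_id": self.wrapper_id,
            "timestamp": self.timestamp,
            "scale": self.scale.to_dict(),
            "qc": self.qc,
            "analysis_config": self.analysis_config,
            "instrument_hash": self.instrument_hash,
            "artifacts": self.artifacts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunSignature":
        return cls(
            signature_id=d["signature_id"],
            panel_version=d["panel_version"],
            axis_id=d["axis_id"],
            prompt_family_id=d["prompt_family_id"],
            wrapper_id=d["wrapper_id"],
            timestamp=d["timestamp"],
            scale=FittedScale.from_dict(d["scale"]),
            qc=d["qc"],
            analysis_config=d["analysis_config"],
            instrument_hash=d["instrument_hash"],
            artifacts=d.get("artifacts", {}),
        )


def build_signature(
    signature_id: str,
    panel_version: str,
    prompt_family_id: str,
    wrapper_id: str,
    scale: FittedScale,
    qc: QCReport,
    template_bytes: bytes,
    run_file_bytes: bytes,
    analysis_config: dict | None = None,
    artifacts: dict | None = None,
    timestamp: str | None = None,
) -> RunSignature:
    """Assemble a signature from a completed fit + QC run."""
    cfg = {
        "l2_lambda": scale.l2_lambda,
        "bootstrap_reps": scale.bootstrap_reps,
        "bootstrap_seed": scale.bootstrap_seed,
    }
    cfg.update(analysis_config or {})
    return RunSignature(
        signature_id=signature_id,
        panel_version=panel_version,
        axis_id=scale.axis_id,
        prompt_family_id=prompt_family_id,
        wrapper_id=wrapper_id,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds"),
        scale=scale,
        qc=qc.to_dict(),
        analysis_config=cfg,
        instrument_hash=instrument_hash(template_bytes, run_file_bytes),
        artifacts=artifacts or {},
    )


def save_signature(sig: RunSignature, path) -> None:
    """Write the signature with a content digest for tamper detection."""
    payload = sig.to_dict()
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    doc = {"payload": payload, "payload_sha256": hashlib.sha256(body.encode()).hexdigest()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_signature(path, verify_artifacts: bool = True) -> RunSignature:
    """Load a signature; verify its content digest and, where the referenced
    artifact files are readable, re-derive the instrument hash from them."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    payload = doc["payload"]
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    if hashlib.sha256(body.encode()).hexdigest() != doc.get("payload_sha256"):
        raise SignatureIntegrityError(f"{path}: stored signature content was modified")
    sig = RunSignature.from_dict(payload)
    if verify_artifacts and {"template", "run_file"} <= set(sig.artifacts):
        try:
            with open(sig.artifacts["template"]["path"], "rb") as fh:
                tb = fh.read()
            with open(sig.artifacts["run_file"]["path"], "rb") as fh:
                rb = fh.read()
        except OSError:
            return sig  # artifacts not present here; digest check not possible
        if instrument_hash(tb, rb) != sig.instrument_hash:
            raise SignatureIntegrityError(
                f"{path}: instrument artifacts no longer match the stored hash "
                f"(template or run file changed)"
            )
    return sig


# ---------------------------------------------------------------------------
# Baseline comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftThresholds:
    """When a rerun warrants action.  Review triggers when any item moves
    beyond the half-width of its baseline CI, a new anchor-order violation
    appears, or repeat agreement drops by more than ``max_agreement_drop``.
    Mitigation and rebaselining are manual escalations recorded, not
    auto-triggered."""

    ci_halfwidth_multiple: float = 1.0
    max_agreement_drop: float = 0.05


@dataclass
class DriftReport:
    baseline_id: str
    candidate_id: str
    deltas: dict[str, float]  # item -> candidate - baseline score
    ci_overlap: dict[str, bool]  # item -> do the two CIs overlap
    reversed_pairs: tuple[tuple[str, str], ...]  # ordering flips between runs
    qc_deltas: dict
    triggered_actions: tuple[str, ...]  # subset of none/review/mitigation/rebaseline
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "baseline_id": self.baseline_id,
            "candidate_id": self.candidate_id,
            "deltas": self.deltas,
            "ci_overlap": self.ci_overlap,
            "reversed_pairs": [list(p) for p in self.reversed_pairs],
            "qc_deltas": self.qc_deltas,
            "triggered_actions": list(self.triggered_actions),
            "reasons": list(self.reasons),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _check_comparable(baseline: RunSignature, candidate: RunSignature) -> None:
    if baseline.panel_version != candidate.panel_version:
        raise NonComparableError(
            f"panel_version mismatch: {baseline.panel_version!r} vs "
            f"{candidate.panel_version!r}"
        )
    if baseline.axis_id != candidate.axis_id:
        raise NonComparableError(
            f"axis mismatch: {baseline.axis_id!r} vs {candidate.axis_id!r}"
        )
    b_items, c_items = set(baseline.scale.items), set(candidate.scale.items)
    if b_items != c_items:
        only_b = sorted(b_items - c_items)
        only_c = sorted(c_items - b_items)
        raise NonComparableError(
            f"item sets differ (baseline-only: {only_b}, candidate-only: {only_c})"
        )


def compare_to_baseline(
    baseline: RunSignature,
    candidate: RunSignature,
    thresholds: DriftThresholds = DriftThresholds(),
) -> DriftReport:
    """Score deltas, CI overlap, ordering reversals, QC shifts, and actions."""
    _check_comparable(baseline, candidate)
    bs, cs = baseline.scale, candidate.scale
    items = sorted(bs.items)
    deltas = {it: cs.scores[it] - bs.scores[it] for it in items}
    ci_overlap = {
        it: not (cs.ci_low[it] > bs.ci_high[it] or cs.ci_high[it] < bs.ci_low[it])
        for it in items
    }
    reversed_pairs = []
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            d_base = bs.scores[a] - bs.scores[b]
            d_cand = cs.scores[a] - cs.scores[b]
            if d_base * d_cand < 0:
                reversed_pairs.append(tuple(sorted((a, b))))

    def _metric(qc: dict, *keys):
        d = qc
        for k in keys:
            d = d.get(k) if isinstance(d, dict) else None
            if d is None:
                return None
        return d

    qc_deltas = {}
    b_agree = _metric(baseline.qc, "repeat_agreement", "fraction")
    c_agree = _metric(candidate.qc, "repeat_agreement", "fraction")
    if b_agree is not None and c_agree is not None:
        qc_deltas["repeat_agreement"] = c_agree - b_agree
    b_r = _metric(baseline.qc, "confidence_distance_r", "r")
    c_r = _metric(candidate.qc, "confidence_distance_r", "r")
    if b_r is not None and c_r is not None:
        qc_deltas["confidence_distance_r"] = c_r - b_r
    b_viol = _metric(baseline.qc, "anchor_order", "n_violations") or 0
    c_viol = _metric(candidate.qc, "anchor_order", "n_violations") or 0
    qc_deltas["anchor_order_violations"] = c_viol - b_viol

    reasons = []
    for it in items:
        half = thresholds.ci_halfwidth_multiple * (bs.ci_high[it] - bs.ci_low[it]) / 2.0
        if abs(deltas[it]) > half:
            reasons.append(f"score shift on {it}: {deltas[it]:+.2f} exceeds baseline CI half-width {half:.2f}")
    if c_viol > b_viol:
        reasons.append(f"new anchor-order violations: {b_viol} -> {c_viol}")
    if (
        b_agree is not None
        and c_agree is not None
        and b_agree - c_agree > thresholds.max_agreement_drop
    ):
        reasons.append(f"repeat agreement dropped {b_agree:.3f} -> {c_agree:.3f}")

    actions = ("review",) if reasons else ("none",)
    return DriftReport(
        baseline_id=baseline.signature_id,
        candidate_id=candidate.signature_id,
        deltas=deltas,
        ci_overlap=ci_overlap,
        reversed_pairs=tuple(reversed_pairs),
        qc_deltas=qc_deltas,
        triggered_actions=actions,
        reasons=tuple(reasons),
    )


def render_drift_report(report: DriftReport) -> str:
    lines = [
        f"Baseline {report.baseline_id} vs candidate {report.candidate_id}",
        "",
        f"{'item':<24}{'delta':>10}{'CI overlap':>12}",
    ]
    for it in sorted(report.deltas, key=lambda k: -abs(report.deltas[k])):
        lines.append(
            f"{it:<24}{report.deltas[it]:>+10.2f}{str(report.ci_overlap[it]):>12}"
        )
    lines.append("")
    lines.append(f"Reversed orderings: {len(report.reversed_pairs)}")
    for a, b in report.reversed_pairs:
        lines.append(f"  {a} <-> {b}")
    for k, v in report.qc_deltas.items():
        lines.append(f"{k}: {v:+.3f}" if isinstance(v, float) else f"{k}: {v:+d}")
    lines.append(f"Actions: {', '.join(report.triggered_actions)}")
    for r in report.reasons:
        lines.append(f"  - {r}")
    return "\n".join(lines)
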