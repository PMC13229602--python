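"""Synthetic forced-choice responders with controllable degradation.

The simulator generates responses with exactly the statistical structure
the analysis assumes: each item holds a latent score s, a trial comparing
A and B picks A with probability sigma((s_A - s_B) / tau) (logistic choice
noise — the Bradley-Terry generative family, so pipeline runs on simulated
data are clean self-consistency tests), and reported confidence is a noisy
affine function of the latent distance |s_A - s_B|, clipped to integers in
[0, 100].  Degradation modes emulate a misbehaving responder: swapping two
anchors' latent scores (producing anchor-order violations downstream),
boosting tau (lowering repeatability), and decalibrating confidence
(weakening the confidence-distance correlation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .panel_design import PanelSpec, TrialRecord
from .response_io import ResponseRecord

__all__ = [
    "ConfidenceModel",
    "Degradation",
    "LatentProfile",
    "simulate_responses",
    "make_default_profiles",
    "default_true_scores",
]

# Confidence decalibration: how the confidence link is corrupted when
# Degradation.confidence_decalibration is set.
DECAL_GAIN_FACTOR = 0.2
DECAL_MIN_NOISE_SD = 25.0


@dataclass(frozen=True)
class ConfidenceModel:
    """confidence = round(clip(gain * |s_A - s_B| + offset + N(0, sd), 0, 100))"""

    gain: float = 0.7
    offset: float = 12.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class Degradation:
    """Optional failure modes layered onto a profile."""

    anchor_inversion: tuple[tuple[str, str], ...] = ()  # item-id pairs to swap
    repeat_noise_boost: float = 1.0  # multiplies tau
    confidence_decalibration: bool = False

    def __post_init__(self) -> None:
        if self.repeat_noise_boost < 1.0:
            raise ValueError("repeat_noise_boost must be >= 1")


@dataclass(frozen=True)
class LatentProfile:
    """A simulated responder: latent scores plus choice/confidence noise."""

    true_scores: dict[str, float]
    choice_temperature: float = 1.0  # tau, latent units per logit
    confidence_model: ConfidenceModel = field(default_factory=ConfidenceModel)
    degradation: Degradation | None = None

    def __post_init__(self) -> None:
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")

    # -- degradation-resolved views --------------------------------------

    def effective_scores(self) -> dict[str, float]:
        s = dict(self.true_scores)
        if self.degradation:
            for a, b in self.degradation.anchor_inversion:
                if a not in s or b not in s:
                    raise KeyError(f"anchor_inversion names unknown item: {a!r}/{b!r}")
                s[a], s[b] = s[b], s[a]
        return s

    def effective_temperature(self) -> float:
        boost = self.degradation.repeat_noise_boost if self.degradation else 1.0
        return self.choice_temperature * boost

    def effective_confidence_model(self) -> ConfidenceModel:
        cm = self.confidence_model
        if self.degradation and self.degradation.confidence_decalibration:
            return ConfidenceModel(
                gain=cm.gain * DECAL_GAIN_FACTOR,
                offset=cm.offset,
                noise_sd=max(cm.noise_sd, DECAL_MIN_NOISE_SD),
            )
        return cm

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "true_scores": self.true_scores,
            "choice_temperature": self.choice_temperature,
            "confidence_model": vars(self.confidence_model).copy(),
        }
        if self.degradation:
            d["degradation"] = {
                "anchor_inversion": [list(p) for p in self.degradation.anchor_inversion],
                "repeat_noise_boost": self.degradation.repeat_noise_boost,
                "confidence_decalibration": self.degradation.confidence_decalibration,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LatentProfile":
        deg = None
        if "degradation" in d:
            dd = d["degradation"]
            deg = Degradation(
                anchor_inversion=tuple(tuple(p) for p in dd.get("anchor_inversion", [])),
                repeat_noise_boost=dd.get("repeat_noise_boost", 1.0),
                confidence_decalibration=dd.get("confidence_decalibration", False),
            )
        return cls(
            true_scores={k: float(v) for k, v in d["true_scores"].items()},
            choice_temperature=float(d["choice_temperature"]),
            confidence_model=ConfidenceModel(**d["confidence_model"]),
            degradation=deg,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LatentProfile":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def simulate_responses(
    plan: Sequence[TrialRecord], profile: LatentProfile, seed: int
) -> list[ResponseRecord]:
    """Draw one response per trial; bit-reproducible given (plan, profile, seed)."""
    s = profile.effective_scores()
    tau = profile.effective_temperature()
    cm = profile.effective_confidence_model()
    for t in plan:
        for it in (t.item_a, t.item_b):
            if it not in s:
                raise KeyError(f"trial {t.trial_id}: item {it!r} has no latent score")
    rng = np.random.default_rng(seed)
    out: list[ResponseRecord] = []
    for t in plan:
        d = s[t.item_a] - s[t.item_b]
        p_a = float(expit(d / tau))
        choice = "A" if rng.random() < p_a else "B"
        conf = cm.gain * abs(d) + cm.offset + rng.normal(0.0, cm.noise_sd)
        conf_i = int(np.clip(round(conf), 0, 100))
        out.append(ResponseRecord(t.trial_id, choice, conf_i))
    return out


def default_true_scores(spec: PanelSpec | None = None) -> dict[str, float]:
    """Latent truth for the stock hardness panel.

    Anchors follow their canonical order on a 0-100 latent axis with the
    two pinned anchors at the endpoints; concepts sit at plausible
    interleaved positions (soft concepts low, hard concepts high).  The
    axis endpoints equal the anchoring convention, so these latent values
    are already "true anchored scores" for recovery checks.
    """
    return {
        "marshmallow": 0.0,
        "life": 6.0,
        "kindness": 14.0,
        "silence": 21.0,
        "oak_hardwood": 29.0,
        "abs_plastic_block": 34.0,
        "polycarbonate_sheet": 39.0,
        "acrylic_sheet": 44.0,
        "aluminum_plate": 49.0,
        "dry_bone": 55.0,
        "window_glass": 61.0,
        "porcelain": 67.0,
        "justice": 76.0,
        "death": 87.0,
        "steel": 100.0,
    }


def make_default_profiles() -> tuple[LatentProfile, LatentProfile]:
    """(clean, degraded) reference responders.

    Clean: canonical latent order, tau = 0.5 latent units.  The smallest
    adjacent gap is ~5 units, so even the closest pair is chosen
    consistently with probability ~1 - 5e-5: over a 190-trial run the
    responder is effectively deterministic, which is how a well-behaved
    frontier responder presents (perfect repeat agreement, classification
    accuracy ~1).

    Degraded: Polycarbonate sheet and Steel latent scores swapped (an
    anchor-order violation by construction), tau boosted 16x (effective
    tau 8 puts typical repeat agreement near 0.90, below the 0.95 flag
    threshold), confidence decalibrated (weak confidence-distance
    correlation) — the profile of a responder that warrants review.
    """
    scores = default_true_scores()
    clean = LatentProfile(
        true_scores=scores,
        choice_temperature=0.5,
        confidence_model=ConfidenceModel(gain=0.7, offset=12.0, noise_sd=5.0),
    )
    degraded = replace(
        clean,
        degradation=Degradation(
            anchor_inversion=(("polycarbonate_sheet", "steel"),),
            repeat_noise_boost=16.0,
            confidence_decalibration=True,
        ),
    )
    return clean, degraded
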