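"""Bradley-Terry scaling on an anchored 0-100 axis.

The model: each item carries a latent strength beta, and
P(i beats j) = sigma(beta_i - beta_j) with sigma the logistic function.
Strengths are estimated by maximizing the L2-penalized log-likelihood

    sum_obs log sigma(beta_winner - beta_loser) - lambda * sum_i beta_i**2

(no intercept; the penalty fixes the otherwise unidentified origin and
keeps estimates finite under separated data, which near-deterministic
responders routinely produce).  Fitted strengths are reported mean-centered
and then linearly rescaled so the axis's low anchor sits at 0 and its high
anchor at 100; other items may land outside [0, 100].  Uncertainty comes
from a parametric bootstrap: redraw every observation's winner from the
fitted probabilities, refit, rescale, and take percentile bounds — so the
two pinned anchors have degenerate intervals by construction.

The penalized objective is smooth and strictly convex for lambda > 0, so a
damped Newton iteration converges fast; the solver is batched over
bootstrap replicates (same pairs, different outcome vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_design import AxisSpec
from .response_io import ComparisonDataset

__all__ = [
    "BTFit",
    "FittedScale",
    "FitError",
    "AnchoringError",
    "BootstrapError",
    "fit_bradley_terry",
    "anchor_rescale",
    "fit_metrics",
    "bootstrap_ci",
    "fit_scale",
]

GRAD_TOL = 1e-8  # convergence: max-norm of the penalized gradient
MAX_ITER = 200


class FitError(RuntimeError):
    """The Bradley-Terry fit could not be computed."""


class AnchoringError(RuntimeError):
    """The two pinned anchors have (numerically) equal strengths.

    This is itself a QC finding: the run gives the anchors no separation,
    so an anchored scale is undefined.
    """


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to refit."""


@dataclass(frozen=True)
class BTFit:
    """Fitted latent strengths (mean-centered, log-strength scale)."""

    items: tuple[str, ...]
    beta: np.ndarray
    l2_lambda: float
    converged: bool
    n_obs: int

    def beta_of(self, item_id: str) -> float:
        return float(self.beta[self.items.index(item_id)])

    def win_probability(self, item_i: str, item_j: str) -> float:
        d = self.beta_of(item_i) - self.beta_of(item_j)
        return float(1.0 / (1.0 + np.exp(-d)))


@dataclass(frozen=True)
class FittedScale:
    """Anchored scores with bootstrap uncertainty and fit summaries."""

    items: tuple[str, ...]
    scores: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    accuracy: float
    log_loss: float
    l2_lambda: float
    bootstrap_reps: int
    bootstrap_seed: int
    axis_id: str
    low_anchor: str
    high_anchor: str

    def to_frame(self, roles: dict[str, str] | None = None):
        import pandas as pd

        rows = [
            {
                "item": it,
                "role": (roles or {}).get(it, ""),
                "score": self.scores[it],
                "ci_low": self.ci_low[it],
                "ci_high": self.ci_high[it],
            }
            for it in self.items
        ]
        return pd.DataFrame(rows).sort_values("score").reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "scores": self.scores,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "accuracy": self.accuracy,
            "log_loss": self.log_loss,
            "l2_lambda": self.l2_lambda,
            "bootstrap_reps": self.bootstrap_reps,
            "bootstrap_seed": self.bootstrap_seed,
            "axis_id": self.axis_id,
            "low_anchor": self.low_anchor,
            "high_anchor": self.high_anchor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedScale":
        return cls(
            items=tuple(d["items"]),
            scores={k: float(v) for k, v in d["scores"].items()},
            ci_low={k: float(v) for k, v in d["ci_low"].items()},
            ci_high={k: float(v) for k, v in d["ci_high"].items()},
            accuracy=float(d["accuracy"]),
            log_loss=float(d["log_loss"]),
            l2_lambda=float(d["l2_lambda"]),
            bootstrap_reps=int(d["bootstrap_reps"]),
            bootstrap_seed=int(d["bootstrap_seed"]),
            axis_id=d["axis_id"],
            low_anchor=d["low_anchor"],
            high_anchor=d["high_anchor"],
        )


# ---------------------------------------------------------------------------
# Penalized-likelihood solver (batched damped Newton)
# ---------------------------------------------------------------------------


def _encode(dataset: ComparisonDataset) -> tuple[np.ndarray, np.ndarray]:
    index = {it: k for k, it in enumerate(dataset.items)}
    win = np.array([index[o.winner] for o in dataset.observations], dtype=np.intp)
    lose = np.array([index[o.loser] for o in dataset.observations], dtype=np.intp)
    return win, lose


def _newton_batch(
    win: np.ndarray, lose: np.ndarray, lam: float, m: int, batch: int
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize the penalized NLL for `batch` outcome vectors sharing pairs.

    Each replicate's outcomes are encoded directly in (win, lose) index
    arrays of shape (batch, n_obs).  Returns (beta, converged) with beta
    mean-centered per replicate.
    """
    n_obs = win.shape[-1]
    beta = np.zeros((batch, m))
    rows = np.arange(batch)[:, None]
    converged = np.zeros(batch, dtype=bool)

    win2 = win if win.ndim == 2 else np.broadcast_to(win, (batch, n_obs))
    lose2 = lose if lose.ndim == 2 else np.broadcast_to(lose, (batch, n_obs))

    def value(b: np.ndarray) -> np.ndarray:
        d = np.take_along_axis(b, win2, axis=1) - np.take_along_axis(b, lose2, axis=1)
        return np.logaddexp(0.0, -d).sum(axis=1) + lam * (b**2).sum(axis=1)

    f = value(beta)
    eye = np.eye(m)
    for _ in range(MAX_ITER):
        d = np.take_along_axis(beta, win2, axis=1) - np.take_along_axis(beta, lose2, axis=1)
        p = 1.0 / (1.0 + np.exp(-d))  # P(observed winner), per obs
        # gradient of NLL: -(1-p) on winner, +(1-p) on loser, + 2 lam beta
        g = np.zeros((batch, m))
        np.add.at(g, (rows, win2), -(1.0 - p))
        np.add.at(g, (rows, lose2), (1.0 - p))
        g += 2.0 * lam * beta
        gmax = np.abs(g).max(axis=1)
        newly = gmax <= GRAD_TOL
        converged |= newly
        if converged.all():
            break
        # Hessian: sum p(1-p) (e_w - e_l)(e_w - e_l)^T + 2 lam I
        w = p * (1.0 - p)
        H = np.zeros((batch, m, m))
        np.add.at(H, (rows, win2, win2), w)
        np.add.at(H, (rows, lose2, lose2), w)
        np.add.at(H, (rows, win2, lose2), -w)
        np.add.at(H, (rows, lose2, win2), -w)
        H += 2.0 * lam * eye
        try:
            step = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover - lam>0 keeps H PD
            raise FitError(f"singular Hessian: {exc}") from exc
        # damped: halve the step until the objective does not increase
        t = np.ones(batch)
        active = ~converged
        for _ls in range(40):
            trial = beta - t[:, None] * step
            f_new = value(trial)
            bad = active & (f_new > f + 1e-12)
            if not bad.any():
                break
            t[bad] *= 0.5
        improve = active & (f_new <= f + 1e-12)
        beta[improve] = trial[improve]
        f[improve] = f_new[improve]
        if not np.isfinite(beta).all():
            raise FitError("optimizer state became non-finite")
    else:
        # loop exhausted; converged flags stay as computed
        pass
    beta -= beta.mean(axis=1, keepdims=True)
    return beta, converged


def fit_bradley_terry(dataset: ComparisonDataset, l2_lambda: float = 0.1) -> BTFit:
    """Fit latent strengths by penalized maximum likelihood.

    ``l2_lambda`` must be > 0: it makes the objective strictly convex (one
    global maximizer regardless of start) and keeps estimates finite when
    the win graph is separated.
    """
    if len(dataset.observations) < 1:
        raise FitError("empty dataset: need at least one observation")
    if len(dataset.items) < 2:
        raise FitError("need at least two items")
    if l2_lambda <= 0:
        raise FitError("l2_lambda must be > 0")
    win, lose = _encode(dataset)
    beta, conv = _newton_batch(win, lose, l2_lambda, len(dataset.items), 1)
    if not np.isfinite(beta).all():
        raise FitError("non-finite strengths after optimization")
    return BTFit(
        items=tuple(dataset.items),
        beta=beta[0],
        l2_lambda=l2_lambda,
        converged=bool(conv[0]),
        n_obs=len(dataset.observations),
    )


# ---------------------------------------------------------------------------
# Anchoring and fit metrics
# ---------------------------------------------------------------------------


def anchor_rescale(fit: BTFit, axis: AxisSpec) -> dict[str, float]:
    """Map strengths linearly so low anchor -> 0 and high anchor -> 100.

    score_i = 100 * (beta_i - beta_low) / (beta_high - beta_low); values
    outside [0, 100] are legitimate (an item ranked beyond the anchors).
    """
    b_low = fit.beta_of(axis.low_anchor)
    b_high = fit.beta_of(axis.high_anchor)
    if abs(b_high - b_low) < 1e-12:
        raise AnchoringError(
            f"anchors {axis.low_anchor!r} and {axis.high_anchor!r} have equal "
            f"fitted strengths; anchored scale undefined"
        )
    scale = 100.0 / (b_high - b_low)
    scores = {it: float((b - b_low) * scale) for it, b in zip(fit.items, fit.beta)}
    # the anchors are exact by definition; remove float round-off
    scores[axis.low_anchor] = 0.0
    scores[axis.high_anchor] = 100.0
    return scores


def fit_metrics(fit: BTFit, dataset: ComparisonDataset) -> tuple[float, float]:
    """(classification accuracy, log loss) against the observed winners.

    Accuracy counts an observation correct when the winner's strength is
    strictly higher; exact ties contribute 0.5.  Log loss is the negative
    mean log fitted probability of each observed winner.
    """
    if set(dataset.items) != set(fit.items):
        raise FitError("dataset items do not match the fitted item index")
    if not dataset.observations:
        raise FitError("empty dataset")
    index = {it: k for k, it in enumerate(fit.items)}
    win = np.array([index[o.winner] for o in dataset.observations])
    lose = np.array([index[o.loser] for o in dataset.observations])
    d = fit.beta[win] - fit.beta[lose]
    correct = np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0))
    accuracy = float(correct.mean())
    log_loss = float(np.logaddexp(0.0, -d).mean())
    return accuracy, log_loss


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    fit: BTFit,
    dataset: ComparisonDataset,
    axis: AxisSpec,
    n_reps: int = 1000,
    seed: int = 0,
    max_failure_frac: float = 0.10,
    _batch: int = 250,
) -> tuple[dict[str, float], dict[str, float], int]:
    """Percentile CIs on the anchored scale via parametric bootstrap.

    Every replicate redraws each observation's winner Bernoulli from the
    fitted probability, refits with the same penalty, and rescales; the
    2.5/97.5 percentiles of each item's replicate scores are returned along
    with the number of successful replicates.  Replicates whose refit fails
    (non-convergence or degenerate anchors) are dropped and counted; more
    than ``max_failure_frac`` failures aborts.
    """
    if n_reps < 2:
        raise BootstrapError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    index = {it: k for k, it in enumerate(fit.items)}
    m = len(fit.items)
    i_idx = np.array([index[o.winner] for o in dataset.observations])
    j_idx = np.array([index[o.loser] for o in dataset.observations])
    p_obs = 1.0 / (1.0 + np.exp(-(fit.beta[i_idx] - fit.beta[j_idx])))

    lo_k, hi_k = index[axis.low_anchor], index[axis.high_anchor]
    all_scores: list[np.ndarray] = []
    n_failed = 0
    done = 0
    while done < n_reps:
        b = min(_batch, n_reps - done)
        u = rng.random((b, p_obs.size))
        keep = u < p_obs  # observed winner retained
        win = np.where(keep, i_idx, j_idx)
        lose = np.where(keep, j_idx, i_idx)
        beta, conv = _newton_batch(win, lose, fit.l2_lambda, m, b)
        denom = beta[:, hi_k] - beta[:, lo_k]
        ok = conv & (np.abs(denom) >= 1e-12)
        n_failed += int((~ok).sum())
        if ok.any():
            sc = 100.0 * (beta[ok] - beta[ok, lo_k][:, None]) / denom[ok][:, None]
            sc[:, lo_k] = 0.0  # pinned by definition in every replicate
            sc[:, hi_k] = 100.0
            all_scores.append(sc)
        done += b
    if n_failed > max_failure_frac * n_reps:
        raise BootstrapError(
            f"{n_failed}/{n_reps} bootstrap replicates failed to refit"
        )
    scores = np.vstack(all_scores)
    lo = np.percentile(scores, 2.5, axis=0)
    hi = np.percentile(scores, 97.5, axis=0)
    ci_low = {it: float(lo[k]) for it, k in index.items()}
    ci_high = {it: float(hi[k]) for it, k in index.items()}
    return ci_low, ci_high, scores.shape[0]


# ---------------------------------------------------------------------------
# One-call pipeline
# ---------------------------------------------------------------------------


def fit_scale(
    dataset: ComparisonDataset,
    axis: AxisSpec,
    l2_lambda: float = 0.1,
    n_reps: int = 1000,
    seed: int = 0,
) -> FittedScale:
    """Fit, anchor, and bootstrap in one call; the usual entry point."""
    fit = fit_bradley_terry(dataset, l2_lambda)
    scores = anchor_rescale(fit, axis)
    accuracy, log_loss = fit_metrics(fit, dataset)
    ci_low, ci_high, n_ok = bootstrap_ci(fit, dataset, axis, n_reps=n_reps, seed=seed)
    return FittedScale(
        items=fit.items,
        scores=scores,
        ci_low=ci_low,
        ci_high=ci_high,
        accuracy=accuracy,
        log_loss=log_loss,
        l2_lambda=l2_lambda,
        bootstrap_reps=n_ok,
        bootstrap_seed=seed,
        axis_id=axis.axis_id,
        low_anchor=axis.low_anchor,
        high_anchor=axis.high_anchor,
    )
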