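"""Power-utility curvature estimation from certainty equivalents.

Money enters every later stage through a power utility U(x) = x^alpha
(gain domain only).  A subject's alpha is identified by the certainty
equivalents (CE) of binary lotteries (x with probability p, else y) via

    CE^alpha = p * x^alpha + (1 - p) * y^alpha,

equivalently CE = (p x^a + (1-p) y^a)^(1/a).  alpha < 1 is risk-averse,
alpha > 1 risk-seeking.  Estimation minimises the money-space residual
sum of squares over alpha within box bounds, from a deterministic ladder
of starting values; an option to minimise in transformed (utility) space
is provided for matching other codebases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["UtilityParams", "power_utility", "predicted_ce", "estimate_alpha"]

ALPHA_BOUNDS = (0.05, 10.0)
ALPHA_STARTS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class UtilityParams:
    alpha: float
    rss: float
    n_points: int
    converged: bool


def power_utility(x, alpha: float):
    """U(x) = x**alpha on the gain domain (x >= 0, alpha > 0)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("power utility is defined for gains only (x >= 0)")
    out = np.power(x, alpha)
    return float(out) if out.ndim == 0 else out


def predicted_ce(x: float, y: float, p: float, alpha) -> float | np.ndarray:
    """Certainty equivalent of the lottery (x, p; y, 1-p) under curvature alpha.

    Always lies in [y, x]; equals the expected value when alpha = 1.
    """
    if not (x > y >= 0):
        raise ValueError(f"need x > y >= 0, got x={x}, y={y}")
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    eu = p * np.power(x, alpha) + (1.0 - p) * np.power(y, alpha)
    ce = np.power(eu, 1.0 / alpha)
    return float(ce) if ce.ndim == 0 else ce


def _residuals(alpha, obs: Sequence[dict], space: str) -> np.ndarray:
    alpha = float(np.asarray(alpha).ravel()[0])  # least_squares passes a 1-vector
    if space == "money":
        return np.array([o["ce"] - predicted_ce(o["x"], o["y"], o["p"], alpha) for o in obs])
    # transformed space: CE^a - (p x^a + (1-p) y^a)
    return np.array(
        [o["ce"] ** alpha - (o["p"] * o["x"] ** alpha + (1 - o["p"]) * o["y"] ** alpha)
         for o in obs]
    )


def estimate_alpha(
    ce_observations: Sequence[dict],
    bounds: tuple[float, float] = ALPHA_BOUNDS,
    starts: Sequence[float] = ALPHA_STARTS,
    residual_space: str = "money",
) -> UtilityParams:
    """Nonlinear least squares for alpha over a list of {x, y, p, ce} dicts.

    Each start on the ladder is run to convergence and the best objective
    wins; the procedure is fully deterministic.  Failure of every start is
    reported via ``converged=False`` rather than an exception.
    """
    if len(ce_observations) < 2:
        raise ValueError("need at least 2 certainty-equivalent observations")
    if residual_space not in ("money", "transformed"):
        raise ValueError(f"unknown residual space {residual_space!r}")
    for o in ce_observations:
        if not (o["y"] <= o["ce"] <= o["x"]):
            raise ValueError(
                f"certainty equivalent {o['ce']} outside the outcome range "
                f"[{o['y']}, {o['x']}]"
            )

    best: tuple[float, float] | None = None  # (rss, alpha)
    any_ok = False
    for a0 in starts:
        try:
            res = least_squares(
                _residuals, x0=a0, bounds=bounds, args=(ce_observations, residual_space),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        any_ok = True
        rss = float(np.sum(res.fun ** 2))
        cand = (rss, float(res.x[0]))
        if best is None or cand < best:
            best = cand
    if not any_ok or best is None:
        return UtilityParams(alpha=1.0, rss=float("inf"),
                             n_points=len(ce_observations), converged=False)
    return UtilityParams(alpha=best[1], rss=best[0],
                         n_points=len(ce_observations), converged=True)
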