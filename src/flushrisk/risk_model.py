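"""Analytic flush-distance risk model for ground-nesting birds.

An incubating bird that leaves ("flushes from") its nest as a predator
approaches emits a strong visual cue to the nest location.  Two quantities
govern the resulting risk:

* **Detection probability** — the chance a predator that witnesses the flush
  pinpoints the nest.  It is 1 at very short flush distances (at or below
  ``f_close``) and 0 at very long ones (at or beyond ``f_long``), declining
  in between.
* **Flush probability** — the chance the bird flushes at all, given a
  predator somewhere within a reference radius ``r_ref`` of the nest.  A bird
  flushes when the predator enters the circle of its threshold distance, so
  for an area-uniform predator position this grows with the *square* of the
  threshold: ``(r / r_ref)**2``, capped at 1.

The risk attributable to flushing is the product of the two.  It vanishes at
both tails — birds that sit tight are rarely flushed, birds that flush very
far are not pinpointed — and peaks at intermediate distances, which is the
model's central prediction.  With a linear detection decline the maximum on
``[f_close, f_long]`` has the closed form ``2 * f_long / 3`` (when
``f_close <= 2 * f_long / 3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DETECTION_SHAPES",
    "RiskModelParams",
    "RiskCurve",
    "detection_probability",
    "flush_probability",
    "risk",
    "risk_curve",
    "argmax_risk",
    "high_risk_band",
]

#: Supported families for the detection decline between f_close and f_long.
DETECTION_SHAPES = ("linear", "smoothstep", "logistic")


@dataclass(frozen=True)
class RiskModelParams:
    """Constants of the flush-risk model.

    Parameters
    ----------
    f_close
        Distance (m) at or below which a flush guarantees nest detection.
    f_long
        Distance (m) at or beyond which a flush carries no detection risk.
    r_ref
        Reference radius (m): the flush probability is conditioned on a
        predator being present somewhere within this radius of the nest.
    detection_shape
        Functional family of the detection decline on ``(f_close, f_long)``.
        The endpoints are pinned at 1 and 0 for every family; only the
        curvature in between differs.
    """

    f_close: float = 5.0
    f_long: float = 100.0
    r_ref: float = 125.0
    detection_shape: str = "linear"

    def __post_init__(self) -> None:
        if not (0 < self.f_close < self.f_long <= self.r_ref):
            raise ValueError(
                "require 0 < f_close < f_long <= r_ref, got "
                f"f_close={self.f_close}, f_long={self.f_long}, r_ref={self.r_ref}"
            )
        if self.detection_shape not in DETECTION_SHAPES:
            raise ValueError(
                f"unknown detection_shape {self.detection_shape!r}; "
                f"choose one of {DETECTION_SHAPES}"
            )


@dataclass(frozen=True)
class RiskCurve:
    """Tabulated detection, flush and risk probabilities on a distance grid."""

    distances: np.ndarray
    detection_prob: np.ndarray
    flush_prob: np.ndarray
    risk: np.ndarray
    params: RiskModelParams = field(default_factory=RiskModelParams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_m": self.distances,
                "p_detect": self.detection_prob,
                "p_flush": self.flush_prob,
                "risk": self.risk,
            }
        )


def _check_distance(d) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("distances must be finite and >= 0")
    return arr


def detection_probability(d, params: RiskModelParams = RiskModelParams()):
    """Probability the predator locates the nest given a flush at distance ``d``.

    Equals 1 on ``[0, f_close]``, 0 on ``[f_long, inf)`` and declines
    strictly and continuously in between according to
    ``params.detection_shape``.  Accepts scalars or arrays.
    """
    arr = _check_distance(d)
    # s in [0, 1]: normalised position between f_close and f_long
    s = np.clip((arr - params.f_close) / (params.f_long - params.f_close), 0.0, 1.0)
    if params.detection_shape == "linear":
        p = 1.0 - s
    elif params.detection_shape == "smoothstep":
        p = 1.0 - (3.0 * s**2 - 2.0 * s**3)
    elif params.detection_shape == "logistic":
        # logistic in distance, rescaled so the endpoints hit exactly 1 and 0
        k = 10.0
        raw = 1.0 / (1.0 + np.exp(k * (s - 0.5)))
        lo = 1.0 / (1.0 + np.exp(k * 0.5))
        hi = 1.0 / (1.0 + np.exp(-k * 0.5))
        p = (raw - lo) / (hi - lo)
    else:  # pragma: no cover - blocked by RiskModelParams validation
        raise ValueError(f"unknown detection_shape {params.detection_shape!r}")
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(d) or np.ndim(d) == 0 else p


def flush_probability(r, params: RiskModelParams = RiskModelParams()):
    """Probability of flushing for threshold ``r``, predator within ``r_ref``.

    Area-uniform predator position gives the capped square law
    ``min((r / r_ref)**2, 1)``.
    """
    arr = _check_distance(r)
    p = np.minimum((arr / params.r_ref) ** 2, 1.0)
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def risk(d, params: RiskModelParams = RiskModelParams()):
    """Flush-attributable predation risk: detection times flush probability."""
    p = detection_probability(d, params) * flush_probability(d, params)
    return float(p) if np.isscalar(d) or np.ndim(d) == 0 else p


def risk_curve(params: RiskModelParams = RiskModelParams(), grid_step: float = 1.0) -> RiskCurve:
    """Evaluate the model on the grid ``0, grid_step, ... , r_ref``."""
    if not grid_step > 0:
        raise ValueError("grid_step must be > 0")
    distances = np.arange(0.0, params.r_ref + grid_step / 2.0, grid_step)
    det = detection_probability(distances, params)
    fl = flush_probability(distances, params)
    return RiskCurve(distances, det, fl, det * fl, params)


def argmax_risk(params: RiskModelParams = RiskModelParams(), tolerance: float = 0.01) -> float:
    """Flush distance maximising the risk product, to within ``tolerance``.

    Deterministic fine-grid scan over ``[0, r_ref]`` followed by bounded
    scalar refinement.  For the linear shape with ``f_close <= 2 f_long / 3``
    this agrees with the closed form ``2 f_long / 3``.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    step = min(tolerance, params.r_ref / 1000.0)
    grid = np.arange(0.0, params.r_ref + step / 2.0, step)
    values = risk(grid, params)
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda d: -risk(float(d), params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tolerance / 10.0},
    )
    return float(res.x)


def high_risk_band(
    params: RiskModelParams = RiskModelParams(), fraction: float = 0.5
) -> Tuple[float, float]:
    """Connected interval around the risk maximum where risk >= fraction * max.

    For the linear shape the risk restricted to ``[f_close, f_long]`` is
    unimodal, so the level set is a single interval; its endpoints are found
    by bisection against ``fraction * max``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    d_star = argmax_risk(params)
    r_max = risk(d_star, params)
    if fraction == 1.0:
        return (d_star, d_star)
    level = fraction * r_max

    def g(d: float) -> float:
        return risk(d, params) - level

    # risk(0) = 0 < level and risk(f_long) = 0 < level, so sign changes exist
    lo = brentq(g, 0.0, d_star, xtol=1e-6) if g(0.0) < 0 else 0.0
    hi = brentq(g, d_star, params.f_long, xtol=1e-6) if g(params.f_long) < 0 else params.f_long
    return (float(lo), float(hi))
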