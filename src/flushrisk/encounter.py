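"""Monte Carlo predator-nest encounter simulation.

Brute-force counterpart of :mod:`flushrisk.risk_model`: each trial places (or
walks) a predator in a disk-shaped arena around one nest, decides whether the
incubating bird flushes (predator inside the bird's threshold circle) and, if
it does, whether the predator pinpoints the nest (a Bernoulli draw at the
model's detection probability, evaluated at the threshold distance — the bird
departs the instant its circle is crossed).

Two predator geometries:

``stationary_uniform``
    The predator is a point placed area-uniformly in the arena (radial
    coordinate ``R * sqrt(u)``).  This is exactly the conditioning of the
    analytic square law, so flush/detection frequencies converge on
    ``(r/R)**2`` and the analytic risk product; the simulator is the oracle
    for the closed forms.

``transect``
    The predator walks a straight chord of the arena: a uniform random
    bearing plus a uniform perpendicular offset in ``(-R, R)``.  This mimics
    a searcher walking past the nest at constant speed.  The bird flushes iff
    the chord's closest approach is within its threshold.  Note this chord
    convention is part of the model definition — other conventions give
    different flush frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .risk_model import RiskModelParams, detection_probability, risk

__all__ = [
    "PREDATOR_MODELS",
    "EncounterConfig",
    "BirdStrategy",
    "TrialOutcome",
    "simulate_encounter",
    "simulate_trials",
    "estimate_risk_curve",
    "draw_thresholds",
    "simulate_population",
    "observer_discovery_filter",
]

PREDATOR_MODELS = ("stationary_uniform", "transect")


@dataclass(frozen=True)
class EncounterConfig:
    """Settings for a batch of simulated predator encounters."""

    params: RiskModelParams = field(default_factory=RiskModelParams)
    arena_radius: Optional[float] = None  # defaults to params.r_ref
    n_trials: int = 10_000
    seed: int = 0
    predator_model: str = "stationary_uniform"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.predator_model not in PREDATOR_MODELS:
            raise ValueError(
                f"unknown predator_model {self.predator_model!r}; "
                f"choose one of {PREDATOR_MODELS}"
            )
        if self.arena_radius is not None and not self.arena_radius > 0:
            raise ValueError("arena_radius must be > 0")

    @property
    def radius(self) -> float:
        return self.params.r_ref if self.arena_radius is None else self.arena_radius


@dataclass(frozen=True)
class BirdStrategy:
    """A bird's nest-defence strategy: when it flushes and what it does next.

    ``deception_category`` uses the ordinal field scale (1 pure flush /
    passive deception, 2 distraction display, 3 display with calling,
    4 attention flights).  It is carried through population simulations but
    plays no part in the encounter geometry.
    """

    flush_threshold: float
    deception_category: int = 1

    def __post_init__(self) -> None:
        if self.flush_threshold < 0:
            raise ValueError("flush_threshold must be >= 0")
        if self.deception_category not in (1, 2, 3, 4):
            raise ValueError("deception_category must be in {1, 2, 3, 4}")


@dataclass(frozen=True)
class TrialOutcome:
    """One encounter: approach distance, whether flushed, whether detected."""

    predator_nest_distance: float
    flushed: bool
    detected: bool

    def __post_init__(self) -> None:
        if self.detected and not self.flushed:
            raise ValueError("detected implies flushed")


def _trial_distances(config: EncounterConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Predator-nest distances: placement (stationary) or closest approach (transect)."""
    R = config.radius
    if config.predator_model == "stationary_uniform":
        return R * np.sqrt(rng.random(n))
    # transect: bearing is irrelevant by symmetry; perpendicular offset
    # uniform on (-R, R) -> closest approach |offset|
    return np.abs(rng.uniform(-R, R, n))


def simulate_trials(
    strategy: BirdStrategy, config: EncounterConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Vectorised batch of ``config.n_trials`` encounters for one strategy.

    Returns a data frame with columns ``predator_nest_distance``, ``flushed``,
    ``detected``; bitwise-reproducible for a given (config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    dist = _trial_distances(config, rng, n)
    flushed = dist <= strategy.flush_threshold
    p_det = detection_probability(min(strategy.flush_threshold, config.params.f_long), config.params)
    detected = flushed & (rng.random(n) < p_det)
    return pd.DataFrame(
        {"predator_nest_distance": dist, "flushed": flushed, "detected": detected}
    )


def simulate_encounter(
    strategy: BirdStrategy, config: EncounterConfig, rng: Optional[np.random.Generator] = None
) -> TrialOutcome:
    """A single encounter drawn from the configured predator geometry."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = float(_trial_distances(config, rng, 1)[0])
    flushed = d <= strategy.flush_threshold
    detected = False
    if flushed:
        p_det = detection_probability(
            min(strategy.flush_threshold, config.params.f_long), config.params
        )
        detected = bool(rng.random() < p_det)
    return TrialOutcome(d, bool(flushed), detected)


def estimate_risk_curve(thresholds: Sequence[float], config: EncounterConfig) -> pd.DataFrame:
    """Monte Carlo flush/detection frequencies across a grid of thresholds.

    One independent batch of ``config.n_trials`` encounters per threshold
    (n_trials >= 1e4 recommended for meaningful binomial standard errors).
    Columns: threshold, flush frequency and SE, detection frequency and SE,
    and the analytic expectations for reference.
    """
    thresholds = list(thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold list must be non-empty")
    rng = np.random.default_rng(config.seed)
    rows = []
    n = config.n_trials
    for r in thresholds:
        trials = simulate_trials(BirdStrategy(flush_threshold=float(r)), config, rng)
        p_fl = trials["flushed"].mean()
        p_det = trials["detected"].mean()
        rows.append(
            {
                "threshold_m": float(r),
                "flush_freq": p_fl,
                "flush_se": np.sqrt(p_fl * (1 - p_fl) / n),
                "detect_freq": p_det,
                "detect_se": np.sqrt(p_det * (1 - p_det) / n),
                "n_trials": n,
                "analytic_risk": risk(float(r), config.params),
            }
        )
    return pd.DataFrame(rows)


def draw_thresholds(
    sampler: Dict, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw flush thresholds from a named distribution.

    ``sampler`` is ``{"name": ..., **params}`` with name one of ``constant``
    (value), ``uniform`` (low, high), ``lognormal`` (mean, sd — *arithmetic*
    moments), ``gamma`` (shape, scale).
    """
    name = sampler.get("name")
    if name == "constant":
        return np.full(n, float(sampler["value"]))
    if name == "uniform":
        return rng.uniform(float(sampler["low"]), float(sampler["high"]), n)
    if name == "lognormal":
        mean, sd = float(sampler["mean"]), float(sampler["sd"])
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), n)
    if name == "gamma":
        return rng.gamma(float(sampler["shape"]), float(sampler["scale"]), n)
    raise ValueError(f"unknown threshold sampler {name!r}")


def simulate_population(
    n_birds: int,
    threshold_sampler: Dict,
    config: EncounterConfig,
    encounters_per_nest: int = 1,
) -> pd.DataFrame:
    """Simulate nest fates for a population of flush strategies.

    Each bird draws a threshold from ``threshold_sampler``; its nest is
    depredated if any of ``encounters_per_nest`` independent encounters ends
    in detection.  The default single encounter matches the per-encounter
    scale of the analytic model.  Output columns ``flush_threshold`` and
    ``depredated`` feed the analysis stage directly.
    """
    if n_birds < 1 or encounters_per_nest < 1:
        raise ValueError("n_birds and encounters_per_nest must be >= 1")
    rng = np.random.default_rng(config.seed)
    thresholds = draw_thresholds(threshold_sampler, n_birds, rng)
    R = config.radius
    depredated = np.zeros(n_birds, dtype=bool)
    for _ in range(encounters_per_nest):
        dist = _trial_distances(config, rng, n_birds)
        flushed = dist <= thresholds
        p_det = detection_probability(np.minimum(thresholds, config.params.f_long), config.params)
        detected = flushed & (rng.random(n_birds) < p_det)
        depredated |= detected
    return pd.DataFrame({"flush_threshold": thresholds, "depredated": depredated})


def observer_discovery_filter(
    records: pd.DataFrame,
    conspicuousness_model: RiskModelParams = RiskModelParams(),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    threshold_column: str = "flush_threshold",
) -> pd.DataFrame:
    """Thin a simulated population the way walking nest-searchers would.

    Observers who find nests by flushing incubating birds preferentially
    discover nests whose flush behaviour is conspicuous — the same
    detection-times-flush product that drives predation.  Each nest is
    retained with probability proportional to the risk product at its
    threshold, renormalised so the most conspicuous strategy has retention 1.
    The retention probability used is recorded per row.
    """
    if len(records) == 0:
        raise ValueError("records table must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    thresholds = records[threshold_column].to_numpy(dtype=float)
    from .risk_model import argmax_risk  # local import to avoid cycle at module load

    r_max = risk(argmax_risk(conspicuousness_model), conspicuousness_model)
    p_keep = risk(thresholds, conspicuousness_model) / r_max
    keep = rng.random(len(records)) < p_keep
    out = records.loc[keep].copy()
    out["retention_prob"] = p_keep[keep]
    return out
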