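"""Statistical pipeline for nest-defence field data.

Implements the analysis stages applied to nest records: a Monte Carlo dip
test of unimodality on flush distances, a proportional-odds ordinal
regression of defence category on species and flush distance, a quadratic
binomial logistic regression of nest fate on flush distance, a two-sample
t-test of flush distance between species, OLS R-squared checks, and the
descriptive summaries (per-species moments, defence-category proportions,
pooled distance-bin proportions, apparent hatch success).

Model fits delegate to statsmodels; the dip statistic is the in-package
implementation (:mod:`flushrisk.dip`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .dip import DipResult, dip_null_table, dip_statistic, dip_test
from .synthetic import records_to_frame

__all__ = [
    "DipResult",
    "OrdinalFit",
    "LogisticFit",
    "TTestResult",
    "SummaryStats",
    "dip_statistic",
    "dip_test",
    "dip_null_table",
    "fit_ordinal",
    "fit_fate_logistic",
    "predicted_fate_curve",
    "two_sample_t",
    "linreg_r2",
    "summarize",
]

#: Pooled flush-distance bins: below 5 m, 5-20 m inclusive, above 20 m.
DEFAULT_BINS: Tuple[float, float] = (5.0, 20.0)

_LL_TOL = 1e-9
_MAXITER = 200


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


class SeparationError(RuntimeError):
    """Raised when a regression outcome is perfectly separated or single-class."""


@dataclass(frozen=True)
class OrdinalFit:
    """Proportional-odds fit of defence category on species + flush distance.

    ``coefficients`` are on the latent logistic scale (positive = shift
    toward higher categories); ``term_chi_squares`` maps each predictor to a
    drop-one statistic ``(chi2, df, p)`` — likelihood-ratio by default.
    Phalarope is the reference species level.
    """

    cutpoints: Tuple[float, ...]
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    log_likelihood: float
    term_chi_squares: Dict[str, Tuple[float, int, float]]
    converged: bool
    n: int


@dataclass(frozen=True)
class LogisticFit:
    """Quadratic logistic regression of hatching on flush distance."""

    intercept: float
    beta_flush: float
    beta_flush_sq: float
    standard_errors: Dict[str, float]
    wald_p_values: Dict[str, float]
    log_likelihood: float
    converged: bool
    n: int

    @property
    def predation_peak(self) -> float:
        """Vertex of the quadratic: flush distance of minimal hatching odds."""
        if self.beta_flush_sq <= 0:
            raise ValueError("no interior predation peak: quadratic coefficient <= 0")
        return -self.beta_flush / (2.0 * self.beta_flush_sq)


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    group_means: Dict[str, float]


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summaries of a nest-record table."""

    per_species_n: Dict[str, int]
    per_species_mean: Dict[str, float]
    per_species_sd: Dict[str, float]
    category_proportions: Dict[str, Dict[int, float]]
    bin_proportions: Dict[str, float]
    bin_edges: Tuple[float, float]
    hatch_success: Dict[str, float]


def _fit_ordered(endog, exog) -> "OrderedModel":
    model = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=_MAXITER, disp=0, gtol=1e-8)
    return res


def fit_ordinal(records, chi_square: str = "lr") -> OrdinalFit:
    """Proportional-odds logistic regression of defence category.

    Predictors are a sandpiper indicator (phalarope reference) and flush
    distance.  Per-term chi-squares are drop-one likelihood-ratio statistics
    (``chi_square='lr'``, 1 df each) or Wald (``chi_square='wald'``).

    Raises
    ------
    ValueError
        Fewer than two observed categories, or missing flush distances.
    SeparationError
        The optimiser diverges (coefficients running to infinity).
    """
    if chi_square not in ("lr", "wald"):
        raise ValueError("chi_square must be 'lr' or 'wald'")
    df = _as_frame(records)
    if df["flush_distance_m"].isna().any():
        raise ValueError("missing flush distances among records used for the ordinal fit")
    if df["defence_category"].nunique() < 2:
        raise ValueError("need at least 2 observed defence categories")
    endog = pd.Categorical(df["defence_category"], ordered=True)
    exog = pd.DataFrame(
        {
            "species_sandpiper": (df["species"] == "sandpiper").astype(float),
            "flush_distance_m": df["flush_distance_m"].astype(float),
        },
        index=df.index,
    )
    # drop a constant predictor (single-species data): its term is untestable
    terms = [c for c in exog.columns if exog[c].nunique() > 1]
    exog = exog[terms]
    res = _fit_ordered(endog, exog)
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params[: len(terms)]) > 50):
        raise SeparationError("ordinal fit diverged; data may be perfectly separated")

    bse = np.asarray(res.bse)
    coefs = {t: float(params[i]) for i, t in enumerate(terms)}
    ses = {t: float(bse[i]) for i, t in enumerate(terms)}
    thresholds = res.model.transform_threshold_params(params)[1:-1]
    chi = {}
    for i, t in enumerate(terms):
        if chi_square == "lr":
            reduced_terms = [u for u in terms if u != t]
            if reduced_terms:
                red = _fit_ordered(endog, exog[reduced_terms])
                ll0 = red.llf
            else:
                red = _fit_ordered(endog, None)
                ll0 = red.llf
            stat = max(0.0, 2.0 * (res.llf - ll0))
        else:
            stat = (params[i] / bse[i]) ** 2
        chi[t] = (float(stat), 1, float(stats.chi2.sf(stat, 1)))
    return OrdinalFit(
        cutpoints=tuple(float(v) for v in thresholds),
        coefficients=coefs,
        standard_errors=ses,
        log_likelihood=float(res.llf),
        term_chi_squares=chi,
        converged=bool(res.mle_retvals.get("converged", True)),
        n=len(df),
    )


def fit_fate_logistic(records) -> LogisticFit:
    """ML logistic regression of hatching (vs depredated) on flush + flush^2.

    Records with unknown fate are excluded.  Hatched is coded 1, so the
    flush-distance log-odds curve opens upward (positive quadratic term)
    when predation peaks at intermediate distances.
    """
    df = _as_frame(records)
    known = df[df["fate"].isin(["hatched", "depredated"])]
    y = (known["fate"] == "hatched").astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise SeparationError("fate regression needs both hatched and depredated outcomes")
    d = known["flush_distance_m"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(d), d, d**2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=_MAXITER, tol=_LL_TOL)
    params = np.asarray(res.params)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(params) > 50):
        raise SeparationError("fate regression diverged; outcomes may be separated")
    names = ("intercept", "flush", "flush_sq")
    return LogisticFit(
        intercept=float(params[0]),
        beta_flush=float(params[1]),
        beta_flush_sq=float(params[2]),
        standard_errors={n_: float(s) for n_, s in zip(names, res.bse)},
        wald_p_values={n_: float(p) for n_, p in zip(names, res.pvalues)},
        log_likelihood=float(res.llf),
        converged=converged,
        n=len(known),
    )


def predicted_fate_curve(
    fit: LogisticFit,
    distances: Optional[np.ndarray] = None,
    peak_range: Tuple[float, float] = (0.0, 100.0),
) -> Tuple[pd.DataFrame, float]:
    """Predicted hatching probability over a distance grid, plus the
    flush distance of maximum predicted predation within ``peak_range``.

    Predation probability is 1 minus the predicted hatching probability, so
    its maximum is the hatching minimum: the quadratic's vertex
    ``-beta_flush / (2 beta_flush_sq)`` when that lies inside the range and
    the parabola opens upward, otherwise the better endpoint.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if distances is None:
        distances = np.linspace(peak_range[0], peak_range[1], 201)
    d = np.asarray(distances, dtype=float)
    logit = fit.intercept + fit.beta_flush * d + fit.beta_flush_sq * d**2
    p_hatch = 1.0 / (1.0 + np.exp(-logit))
    curve = pd.DataFrame({"distance_m": d, "p_hatch": p_hatch, "p_predation": 1.0 - p_hatch})

    lo, hi = peak_range
    candidates = [lo, hi]
    if fit.beta_flush_sq > 0:
        vertex = -fit.beta_flush / (2.0 * fit.beta_flush_sq)
        if lo <= vertex <= hi:
            candidates = [vertex]
    def hatch_at(z: float) -> float:
        return fit.intercept + fit.beta_flush * z + fit.beta_flush_sq * z**2
    peak = min(candidates, key=hatch_at)
    return curve, float(peak)


def two_sample_t(records, variant: str = "pooled") -> TTestResult:
    """Two-sided t-test of flush distance between the two species.

    ``pooled`` (Student, df = n1 + n2 - 2) by default; ``welch`` by flag.
    The statistic's sign follows sandpiper minus phalarope.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    df = _as_frame(records)
    a = df.loc[df["species"] == "sandpiper", "flush_distance_m"].to_numpy(dtype=float)
    b = df.loc[df["species"] == "phalarope", "flush_distance_m"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each species needs at least 2 records")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    dof = float(res.df) if variant == "welch" else float(len(a) + len(b) - 2)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=dof,
        p_value=float(res.pvalue),
        variant=variant,
        group_means={"sandpiper": float(a.mean()), "phalarope": float(b.mean())},
    )


def linreg_r2(x, y) -> float:
    """Ordinary least squares coefficient of determination of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def summarize(records, bin_edges: Tuple[float, float] = DEFAULT_BINS) -> SummaryStats:
    """Descriptive summaries of a nest-record table.

    Flush-distance moments use the sample SD (n-1).  The pooled distance
    bins are [0, lo), [lo, hi], (hi, inf) with edges (5, 20) by default.
    Apparent hatch success is hatched / all nests (unknown fates count in
    the denominator, as in field summaries of nests found).
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("records table is empty")
    lo, hi = bin_edges
    per_n, per_mean, per_sd, cats, hatch = {}, {}, {}, {}, {}
    for sp, grp in df.groupby("species"):
        d = grp["flush_distance_m"].astype(float)
        per_n[sp] = int(len(grp))
        per_mean[sp] = float(d.mean())
        per_sd[sp] = float(d.std(ddof=1)) if len(grp) > 1 else float("nan")
        vc = grp["defence_category"].value_counts(normalize=True)
        cats[sp] = {k: float(vc.get(k, 0.0)) for k in (1, 2, 3, 4)}
        hatch[sp] = float((grp["fate"] == "hatched").mean())
    d_all = df["flush_distance_m"].to_numpy(dtype=float)
    bins = {
        "below": float(np.mean(d_all < lo)),
        "mid": float(np.mean((d_all >= lo) & (d_all <= hi))),
        "above": float(np.mean(d_all > hi)),
    }
    return SummaryStats(
        per_species_n=per_n,
        per_species_mean=per_mean,
        per_species_sd=per_sd,
        category_proportions=cats,
        bin_proportions=bins,
        bin_edges=(float(lo), float(hi)),
        hatch_success=hatch,
    )
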