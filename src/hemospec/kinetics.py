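"""Deoxyhemoglobin-transition kinetics.

During closed-tube storage the deoxyhemoglobin fraction rises along a
sigmoidal course as dissolved oxygen is consumed.  The transition is modelled
with a Normal cumulative distribution function,

    y(t) = base + (plateau − base) · Φ((t − tm) / σ),

where tm is the mean transition time (the day the curve crosses its midpoint)
and σ the transition width in days.  The deoxyhemoglobin formation rate is
reported as 1/tm; the maximum slope of the fitted curve is exposed separately
as ``peak_slope_pct_per_day``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import curve_fit
from scipy.special import ndtr, ndtri

from .errors import (
    DegenerateSeriesError,
    NonConvergenceError,
    UndefinedRateError,
    UnreachableThresholdError,
    ValidationError,
)

__all__ = [
    "KineticSeries",
    "CdfFit",
    "fit_cdf",
    "rate",
    "time_to_threshold",
    "cdf_model",
]

_FLAT_TOL_PCT = 1e-6
_N_RESTARTS = 8


@dataclass(frozen=True)
class KineticSeries:
    """A deoxyhemoglobin-percentage time course for one storage condition."""

    times: np.ndarray  # days
    hb_pct: np.ndarray  # mean % per time point
    sd_pct: np.ndarray | None = None  # optional per-point SD for weighting
    condition: dict = field(default_factory=dict)  # e.g. {"sts_pct": 0, "tube": "closed"}

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.hb_pct, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("times and hb_pct must be matching 1-D arrays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        if np.any((y < 0) | (y > 100)):
            raise ValidationError("hb_pct must lie in [0, 100]")
        sd = self.sd_pct
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != t.shape or np.any(sd <= 0):
                raise ValidationError("sd_pct must be positive and match times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "hb_pct", y)
        object.__setattr__(self, "sd_pct", sd)
        object.__setattr__(self, "condition", dict(self.condition))


def cdf_model(t, base, plateau, tm, sigma):
    """base + (plateau − base)·Φ((t − tm)/σ)."""
    return base + (plateau - base) * ndtr((np.asarray(t, float) - tm) / sigma)


@dataclass(frozen=True)
class CdfFit:
    """Fitted Normal-CDF transition parameters.

    ``tm_days`` is the transition midpoint; ``rate_per_day`` its reciprocal.
    ``time_to_50pct_days`` is the day the fitted curve crosses the absolute
    50% level when that level lies inside (base, plateau), else NaN.
    """

    base_pct: float
    plateau_pct: float
    tm_days: float
    sigma_days: float
    se: dict
    converged: bool
    n_points: int
    sse: float

    def __post_init__(self) -> None:
        if not (0 <= self.base_pct <= self.plateau_pct <= 100):
            raise ValidationError(
                f"need 0 <= base ({self.base_pct:.3g}) <= plateau "
                f"({self.plateau_pct:.3g}) <= 100"
            )
        if self.sigma_days <= 0:
            raise ValidationError("sigma_days must be positive")

    @property
    def rate_per_day(self) -> float:
        return rate(self)

    @property
    def peak_slope_pct_per_day(self) -> float:
        """Maximum slope of the fitted curve, (plateau−base)/(σ√(2π))."""
        return (self.plateau_pct - self.base_pct) / (
            self.sigma_days * np.sqrt(2 * np.pi)
        )

    @property
    def time_to_50pct_days(self) -> float:
        try:
            return time_to_threshold(self, 50.0)
        except UnreachableThresholdError:
            return float("nan")

    def predict(self, t):
        return cdf_model(t, self.base_pct, self.plateau_pct, self.tm_days, self.sigma_days)

    def to_dict(self) -> dict:
        return {
            "base_pct": self.base_pct,
            "plateau_pct": self.plateau_pct,
            "tm_days": self.tm_days,
            "sigma_days": self.sigma_days,
            "se": dict(self.se),
            "rate_per_day": self.rate_per_day,
            "peak_slope_pct_per_day": self.peak_slope_pct_per_day,
            "time_to_50pct_days": self.time_to_50pct_days,
            "converged": self.converged,
            "n_points": self.n_points,
            "sse": self.sse,
            "bounds": "0 <= base <= plateau <= 100; sigma in (0, t_span]",
        }


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    base, plateau = float(y.min()), float(y.max())
    mid = 0.5 * (base + plateau)
    # first crossing of the midpoint, linearly interpolated
    above = y >= mid
    tm = float(t[-1])
    for i in range(1, t.size):
        if above[i] and not above[i - 1]:
            frac = (mid - y[i - 1]) / (y[i] - y[i - 1])
            tm = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            break
    else:
        if above[0]:
            tm = float(t[0])
    sigma = (t[-1] - t[0]) / 4.0
    return np.array([base, plateau, tm, sigma])


def fit_cdf(series: KineticSeries, max_restarts: int = _N_RESTARTS) -> CdfFit:
    """Least-squares Normal-CDF fit of a kinetic series.

    Weighted by 1/sd² when per-point SDs are given.  Starts from a
    deterministic data-driven guess (base = min, plateau = max, tm at the
    interpolated midpoint crossing, σ = span/4) with a small number of
    deterministic perturbed restarts; raises ``NonConvergenceError`` carrying
    the best attempt if none converges, and ``DegenerateSeriesError`` for a
    flat series.
    """
    t, y = series.times, series.hb_pct
    if t.size < 4:
        raise ValidationError(f"need >= 4 time points, got {t.size}")
    if np.ptp(y) < _FLAT_TOL_PCT:
        raise DegenerateSeriesError(
            "series is flat; the transition model is unidentifiable"
        )
    span = float(t[-1] - t[0])
    p0 = _initial_guess(t, y)
    lower = np.array([0.0, 0.0, t[0] - span, 1e-9])
    upper = np.array([100.0, 100.0, t[-1] + span, span])
    rng = np.random.default_rng(0)  # deterministic restart jitter

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 * (1 + 0.2 * rng.standard_normal(4)), lower + 1e-9, upper
        )
        try:
            popt, pcov = curve_fit(
                cdf_model,
                t,
                y,
                p0=start,
                sigma=series.sd_pct,
                bounds=(lower, upper),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - cdf_model(t, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
        if sse <= (best[0] if best else np.inf) and attempt >= 1 and best[0] < 1e-12:
            break

    if best is None:
        raise NonConvergenceError(
            f"CDF fit failed after {max_restarts + 1} starts", best_fit=None
        )
    sse, popt, pcov = best
    base, plateau, tm, sigma = (float(v) for v in popt)
    if base > plateau:  # model symmetric under swap with mirrored σ sign
        base, plateau = plateau, base
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    se = {
        "base_pct": float(perr[0]),
        "plateau_pct": float(perr[1]),
        "tm_days": float(perr[2]),
        "sigma_days": float(perr[3]),
    }
    return CdfFit(
        base_pct=base,
        plateau_pct=plateau,
        tm_days=tm,
        sigma_days=sigma,
        se=se,
        converged=True,
        n_points=int(t.size),
        sse=sse,
    )


def rate(fit: CdfFit | float) -> float:
    """Deoxyhemoglobin formation rate, 1/tm (day⁻¹).

    Accepts a fit or a bare tm in days.  The reporting layer rounds to two
    decimals; this function returns the exact reciprocal.
    """
    tm = fit.tm_days if isinstance(fit, CdfFit) else float(fit)
    if tm <= 0:
        raise UndefinedRateError(f"rate undefined for tm = {tm:g} days")
    return 1.0 / tm


def time_to_threshold(fit: CdfFit, threshold_pct: float) -> float:
    """Day on which the fitted curve crosses ``threshold_pct``.

    Analytic inversion: t = tm + σ·Φ⁻¹((threshold − base)/(plateau − base)).
    The threshold must lie strictly between base and plateau.
    """
    base, plateau = fit.base_pct, fit.plateau_pct
    if not (base < threshold_pct < plateau):
        raise UnreachableThresholdError(
            f"threshold {threshold_pct:g}% outside open interval "
            f"({base:g}, {plateau:g})%"
        )
    q = (threshold_pct - base) / (plateau - base)
    return float(fit.tm_days + fit.sigma_days * ndtri(q))
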