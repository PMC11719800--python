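"""Constrained bi-exponential tumor-regrowth kinetics.

After irradiation a xenograft tumor typically shrinks (killed cells resorb)
and then regrows from the surviving clonogenic fraction.  The normalized
volume curve is modeled as

    f(t) = V(t)/V0 = A1*exp(-alpha1*t) + A2*exp(alpha2*t)

with A1 + A2 = 1 and A1 >= 0, A2 > 0, alpha1 > 0, alpha2 > 0.  The shrinking
term carries the irradiation-killed fraction A1; the growing term the
surviving fraction A2.  From a fit we derive the curve's global-minimum time
(nadir), the regrowth-start day (first measurement day after the nadir) and
the tripling time (time to reach 3*V0, the humane endpoint).

Fitting minimizes squared residuals on the normalized V/V0 scale with bound
constraints handled exactly (A2 eliminated as 1-A1) and a deterministic
multi-start grid guarding against local minima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "GrowthMeasurement",
    "MouseRecord",
    "RegrowthParams",
    "RegrowthFit",
    "ellipsoid_volume",
    "eval_regrowth",
    "fit_regrowth",
    "fit_regrowth_pooled",
    "global_min_time",
    "regrowth_start",
    "tripling_time",
    "InsufficientDataError",
]

ARMS = ("control", "CRT", "MBRT", "MRT")


class InsufficientDataError(ValueError):
    """Raised when a record has fewer usable measurements than parameters."""


def ellipsoid_volume(length_mm: float, breadth_mm: float) -> float:
    """Caliper tumor volume, (pi/6) * length * breadth^2, in mm^3.

    By caliper convention breadth is the smaller axis; swapped inputs are
    corrected with a warning.
    """
    if length_mm <= 0 or breadth_mm <= 0:
        raise ValueError("caliper axes must be positive")
    if breadth_mm > length_mm:
        warnings.warn(
            "breadth exceeds length; swapping (caliper convention: breadth "
            "is the smaller axis)",
            stacklevel=2,
        )
        length_mm, breadth_mm = breadth_mm, length_mm
    return math.pi / 6.0 * length_mm * breadth_mm * breadth_mm


@dataclass(frozen=True)
class GrowthMeasurement:
    """One caliper measurement: day since irradiation and tumor size.

    Either both caliper axes or a pre-computed volume must be given; the
    volume is derived from the axes when absent.
    """

    day: float
    length_mm: float | None = None
    breadth_mm: float | None = None
    volume_mm3: float | None = None

    def __post_init__(self) -> None:
        if self.volume_mm3 is None:
            if self.length_mm is None or self.breadth_mm is None:
                raise ValueError("need caliper axes or an explicit volume")
            object.__setattr__(
                self, "volume_mm3", ellipsoid_volume(self.length_mm, self.breadth_mm)
            )
        if not self.volume_mm3 > 0:
            raise ValueError("volume must be positive")


@dataclass
class MouseRecord:
    """One animal's longitudinal volume series.

    ``v0`` is the volume at the time of irradiation (day 0); animals are
    euthanized when the observed volume first reaches
    ``endpoint_multiple * v0`` (``reached_endpoint`` set), otherwise followed
    to ``last_followup_day``.
    """

    mouse_id: str
    arm: str
    v0: float
    measurements: list[GrowthMeasurement] = field(default_factory=list)
    reached_endpoint: bool = False
    last_followup_day: float | None = None
    endpoint_multiple: float = 3.0

    def __post_init__(self) -> None:
        if not self.v0 > 0:
            raise ValueError("v0 must be positive")
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")
        if self.reached_endpoint and self.measurements:
            final = self.measurements[-1].volume_mm3
            if final < self.endpoint_multiple * self.v0 - 1e-9:
                raise ValueError(
                    "endpoint flagged but final volume is below "
                    f"{self.endpoint_multiple}x v0"
                )
            post = [m for m in self.measurements if m.day > self.measurements[-1].day]
            if post:
                raise ValueError("measurements recorded after the endpoint day")

    def post_irradiation(self) -> list[GrowthMeasurement]:
        return [m for m in self.measurements if m.day > 0]

    def normalized_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(days, V/V0) for post-irradiation measurements."""
        post = self.post_irradiation()
        t = np.array([m.day for m in post], dtype=float)
        y = np.array([m.volume_mm3 / self.v0 for m in post], dtype=float)
        return t, y


@dataclass(frozen=True)
class RegrowthParams:
    """Bi-exponential parameter set (A1, A2, alpha1, alpha2).

    A1 + A2 = 1 (normalization at t=0); rates in 1/day.
    """

    a1: float
    a2: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if abs(self.a1 + self.a2 - 1.0) > 1e-9:
            raise ValueError("A1 + A2 must equal 1")
        if self.a1 < 0:
            raise ValueError("A1 must be non-negative")
        if not self.a2 > 0:
            raise ValueError("A2 must be positive")
        if not (self.alpha1 > 0 and self.alpha2 > 0):
            raise ValueError("rates must be positive")

    @classmethod
    def from_free(cls, a1: float, alpha1: float, alpha2: float) -> "RegrowthParams":
        return cls(a1, 1.0 - a1, alpha1, alpha2)

    @classmethod
    def pure_exponential(cls, alpha2: float) -> "RegrowthParams":
        """Monotone growth with no killed fraction (A1 = 0)."""
        return cls(0.0, 1.0, 1.0, alpha2)


@dataclass(frozen=True)
class RegrowthFit:
    """Result of fitting one normalized volume series."""

    params: RegrowthParams
    sse: float
    t_min: float
    regrowth_start_day: float | None
    n_points: int

    def __post_init__(self) -> None:
        if self.sse < 0 or self.t_min < 0:
            raise ValueError("sse and t_min must be non-negative")
        if self.regrowth_start_day is not None and not (
            self.regrowth_start_day > self.t_min
        ):
            raise ValueError("regrowth_start_day must exceed t_min")


def eval_regrowth(params: RegrowthParams, t):
    """Normalized volume f(t) = A1*e^(-alpha1*t) + A2*e^(alpha2*t); f(0)=1."""
    tt = np.asarray(t, dtype=float)
    out = params.a1 * np.exp(-params.alpha1 * tt) + params.a2 * np.exp(
        params.alpha2 * tt
    )
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def global_min_time(params: RegrowthParams) -> float:
    """Day of the curve's global minimum on t >= 0 (the nadir).

    f'(t) = 0 gives t_min = ln(A1*alpha1 / (A2*alpha2)) / (alpha1 + alpha2)
    when A1*alpha1 > A2*alpha2; otherwise the curve is non-decreasing and
    the minimum sits at t = 0.
    """
    num = params.a1 * params.alpha1
    den = params.a2 * params.alpha2
    if num <= den:
        return 0.0
    return math.log(num / den) / (params.alpha1 + params.alpha2)


# Deterministic multi-start grid: coarse coverage of plausible killed
# fractions and shrink/regrow rates for subcutaneous xenografts.
_START_A1 = (0.1, 0.3, 0.5, 0.7, 0.9)
_START_ALPHA1 = (0.03, 0.1, 0.3)
_START_ALPHA2 = (0.01, 0.03, 0.06)

_A1_HI = 1.0 - 1e-6
_RATE_LO, _RATE_HI = 1e-4, 1.0


def _fit_points(t: np.ndarray, y: np.ndarray) -> tuple[RegrowthParams, float]:
    """Bounded multi-start least squares on normalized points (t, y)."""

    def residuals(x: np.ndarray) -> np.ndarray:
        a1, r1, r2 = x
        return a1 * np.exp(-r1 * t) + (1.0 - a1) * np.exp(r2 * t) - y

    lb = np.array([0.0, _RATE_LO, _RATE_LO])
    ub = np.array([_A1_HI, _RATE_HI, _RATE_HI])
    best = None
    for a1 in _START_A1:
        for r1 in _START_ALPHA1:
            for r2 in _START_ALPHA2:
                x0 = np.array([a1, r1, r2])
                try:
                    res = least_squares(
                        residuals, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    )
                except Exception:  # pragma: no cover - defensive
                    continue
                if best is None or res.cost < best.cost - 0.0:
                    best = res
    if best is None:
        raise RuntimeError("regrowth fit failed from every start")
    a1, r1, r2 = best.x
    sse = float(2.0 * best.cost)  # least_squares cost = 0.5 * SSE
    return RegrowthParams.from_free(float(a1), float(r1), float(r2)), sse


def regrowth_start(t_min: float, measurement_days) -> float | None:
    """First scheduled measurement day strictly after the nadir.

    Regrowth is observable only on measurement days, so "the day after the
    global minimum" maps to the next scheduled day.  Returns None (censored)
    when no measurement day follows ``t_min``.
    """
    days = sorted(float(d) for d in measurement_days)
    if not days:
        raise ValueError("measurement_days must be nonempty")
    for d in days:
        if d > t_min:
            return d
    return None


def fit_regrowth(record: MouseRecord) -> RegrowthFit:
    """Fit the bi-exponential model to one animal's normalized series.

    Pre-irradiation measurements are excluded; the model itself enforces
    f(0) = 1, so no pseudo-point at the origin is added.  Requires at least
    4 post-irradiation measurements (free parameters + 1).
    """
    t, y = record.normalized_series()
    if t.size < 4:
        raise InsufficientDataError(
            f"{record.mouse_id}: {t.size} post-irradiation points; need >= 4"
        )
    params, sse = _fit_points(t, y)
    t_min = global_min_time(params)
    start = regrowth_start(t_min, t)
    return RegrowthFit(params, sse, t_min, start, int(t.size))


def fit_regrowth_pooled(records: list[MouseRecord]) -> RegrowthFit:
    """Fit one curve to the concatenated normalized points of an arm.

    The per-group analogue of :func:`fit_regrowth`: all animals' (day, V/V0)
    points are pooled and a single parameter set is fitted.  The regrowth
    start day uses the union of the animals' measurement schedules.
    """
    ts, ys = [], []
    for rec in records:
        t, y = rec.normalized_series()
        ts.append(t)
        ys.append(y)
    t = np.concatenate(ts) if ts else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if t.size < 4:
        raise InsufficientDataError("pooled series has fewer than 4 points")
    order = np.argsort(t, kind="stable")
    params, sse = _fit_points(t[order], y[order])
    t_min = global_min_time(params)
    start = regrowth_start(t_min, np.unique(t))
    return RegrowthFit(params, sse, t_min, start, int(t.size))


def _model_tripling(params: RegrowthParams, multiple: float = 3.0) -> float:
    """Smallest t > 0 with f(t) = multiple, by bracketed root search."""
    t_min = global_min_time(params)
    lo = 0.0
    # f(0) = 1 < multiple and f is eventually increasing without bound,
    # so the crossing is unique and lies beyond the nadir.
    hi = max(t_min, 1.0)
    while eval_regrowth(params, hi) < multiple:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - alpha2 >= 1e-4 precludes this
            raise RuntimeError("tripling time beyond 1e6 days")
    f = lambda t: eval_regrowth(params, t) - multiple
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16))


def tripling_time(
    record: MouseRecord | None,
    method: str = "raw",
    fit: RegrowthFit | None = None,
    params: RegrowthParams | None = None,
    multiple: float = 3.0,
) -> float | None:
    """Time after treatment to reach ``multiple`` (default 3x) times V0.

    method="raw"
        First crossing of the piecewise-linear interpolant of the recorded
        (day, V/V0) points, anchored at (0, 1); None (censored) if the
        threshold is never reached within follow-up.
    method="model"
        Smallest t with f(t) = multiple on the fitted (or supplied) curve,
        solved by bracketed bisection to <1e-6 days.
    """
    if method == "model":
        if params is None:
            if fit is not None:
                params = fit.params
            else:
                raise ValueError("model-based tripling time needs a fit or params")
        return _model_tripling(params, multiple)
    if method != "raw":
        raise ValueError(f"unknown method {method!r}")
    if record is None:
        raise ValueError("raw tripling time needs a MouseRecord")
    t, y = record.normalized_series()
    t = np.concatenate(([0.0], t))
    y = np.concatenate(([1.0], y))
    above = np.nonzero(y >= multiple)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:  # pragma: no cover - ratio 1 < multiple always
        return 0.0
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (multiple - y0) / (y1 - y0) * (t1 - t0))
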