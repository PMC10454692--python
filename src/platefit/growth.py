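r"""Logistic growth-curve fitting and derived growth parameters.

The model is the standard logistic

.. math:: N(t) = \frac{K}{1 + A e^{-rt}}, \qquad A = \frac{K - N_0}{N_0},

with carrying capacity :math:`K` (in OD600 units), initial population
:math:`N_0 = N(0)` and intrinsic growth rate :math:`r` (per hour). Three
parameters summarize each curve:

* ``od_max`` — the fitted asymptote :math:`K` (the observed maximum is kept
  alongside for transparency);
* ``r_max`` — the maximum slope of the fitted curve, analytically
  :math:`rK/4`, attained where :math:`N = K/2`;
* ``auc`` — the integral of the fitted curve over the exponential-phase
  window, the time interval on which the fitted derivative exceeds a
  threshold constant ``c`` (default 0.005 OD600/h).

The window endpoints and the integral both have closed forms: solving
:math:`rN(1-N/K) = c` gives :math:`N_\pm = \tfrac{K}{2}(1 \pm
\sqrt{1-4c/(rK)})`, mapped to times through :math:`t(N) =
\tfrac1r\ln\!\big(\frac{AN}{K-N}\big)`, and the antiderivative of the
logistic is :math:`F(t) = \tfrac{K}{r}\ln(e^{rt} + A)`.

Time is in hours throughout; the threshold ``c`` is therefore in OD600 per
hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError
from .preprocess import CorrectedCurve

#: default derivative threshold defining the exponential phase, OD600 per hour
DERIV_THRESHOLD = 0.005
#: curves whose corrected OD never exceeds this are treated as no-growth
NO_GROWTH_FLOOR = 0.02
#: floor used when seeding N0 and when taking logs of near-zero OD values
N0_FLOOR = 1e-3
#: multi-start restarts attempted before declaring non-convergence
N_RESTARTS = 3


def logistic(t: np.ndarray | float, K: float, N0: float, r: float) -> np.ndarray:
    """Evaluate the logistic curve N(t) = K / (1 + A e^(-rt)), A=(K-N0)/N0."""
    A = (K - N0) / N0
    return K / (1.0 + A * np.exp(-r * np.asarray(t, dtype=float)))


@dataclass
class LogisticFit:
    """Estimated logistic parameters and diagnostics for one corrected curve."""

    K: float
    N0: float
    r: float
    A: float
    rss: float
    converged: bool
    t_end: float
    od_obs_max: float
    flags: tuple[str, ...] = ()

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        return self.K / (1.0 + self.A * np.exp(-self.r * np.asarray(t, dtype=float)))

    def derivative(self, t: np.ndarray | float) -> np.ndarray:
        N = self.predict(t)
        return self.r * N * (1.0 - N / self.K)


@dataclass
class NoGrowthResult:
    """Sentinel for curves that never rise above the no-growth floor."""

    od_obs_max: float
    t_end: float


@dataclass
class GrowthWindow:
    """Exponential-phase interval: fitted derivative > c inside it.

    ``t_lo_unclipped``/``t_hi_unclipped`` are the exact roots of
    derivative = c on the whole real line; ``t_start``/``t_end_w`` are those
    roots intersected with the observation interval.
    """

    c: float
    t_start: float
    t_end_w: float
    empty: bool
    t_lo_unclipped: float = math.nan
    t_hi_unclipped: float = math.nan

    @property
    def width(self) -> float:
        if self.empty:
            return 0.0
        return max(self.t_end_w - self.t_start, 0.0)


@dataclass
class GrowthMetrics:
    """The (od_max, r_max, auc) triple plus the window that defined the AUC."""

    od_max: float
    r_max: float
    auc: float
    window: GrowthWindow
    od_obs_max: float
    fit: LogisticFit | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def no_growth(self) -> bool:
        return self.fit is None


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    K0 = float(np.max(y))
    N00 = min(max(float(y[0]), N0_FLOOR), 0.9 * K0) if K0 > 0 else N0_FLOOR
    A0 = min(max((K0 - N00) / N00, 0.0), 1e8)
    # seed r with the log-linear slope over the steepest half of the series
    g = np.gradient(y, t)
    idx = g >= np.median(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        coeffs = np.polyfit(t[idx], np.log(np.clip(y[idx], 0.0, None) + N0_FLOOR), 1)
    r0 = float(coeffs[0]) if np.isfinite(coeffs[0]) else 0.5
    r0 = min(max(r0, 0.05), 5.0)
    return np.array([K0, A0, r0])


def fit_logistic(
    curve: CorrectedCurve | None = None,
    init: np.ndarray | None = None,
    *,
    times: np.ndarray | None = None,
    od: np.ndarray | None = None,
    no_growth_floor: float = NO_GROWTH_FLOOR,
    seed: int = 0,
) -> LogisticFit | NoGrowthResult:
    """Fit the logistic to a corrected curve by bounded least squares.

    Accepts either a :class:`~platefit.preprocess.CorrectedCurve` or raw
    ``times``/``od`` arrays. The optimization runs over (K, A, r) with
    A >= 0, which enforces K >= N0 > 0 by construction. Curves whose maximum
    never exceeds ``no_growth_floor`` return :class:`NoGrowthResult` instead
    of a fit; after the initial attempt, up to three perturbed restarts are
    tried before raising :class:`~platefit.exceptions.FitError`.
    """
    if curve is not None:
        t = np.asarray(curve.times, dtype=float)
        y = np.asarray(curve.od_adj, dtype=float)
    else:
        if times is None or od is None:
            raise ValueError("provide either a CorrectedCurve or times and od arrays")
        t = np.asarray(times, dtype=float)
        y = np.asarray(od, dtype=float)
    if t.size < 10:
        raise FitError(f"need >= 10 time points, got {t.size}")
    ymax = float(np.max(y))
    if ymax < no_growth_floor or np.ptp(y) == 0.0:
        return NoGrowthResult(od_obs_max=ymax, t_end=float(t[-1]))

    # Variable projection: the model is linear in K, so for given (A, r) the
    # optimal K has the closed form (y.g)/(g.g) with g = 1/(1 + A e^{-rt}).
    # The optimization runs over (log A, log r) only, which removes the
    # near-degenerate valley that makes joint (K, A, r) fits of curves far
    # from plateau ill-conditioned.
    def shape(logx: np.ndarray) -> tuple[np.ndarray, float]:
        A, r = np.exp(logx)
        g = 1.0 / (1.0 + A * np.exp(-r * t))
        K = max(float(y @ g) / float(g @ g), 1e-9)
        return g, K

    def resid(logx: np.ndarray) -> np.ndarray:
        g, K = shape(logx)
        return K * g - y

    lb = np.log(np.array([1e-9, 1e-6]))
    ub = np.log(np.array([1e9, 50.0]))
    x_full = _initial_guess(t, y) if init is None else np.asarray(init, float)
    x0 = np.clip(np.log(np.maximum(x_full[1:], 1e-12)), lb, ub)

    rng = np.random.default_rng(seed)
    attempts: list[dict] = []
    best = None
    for k in range(1 + N_RESTARTS):
        start = x0 if k == 0 else np.clip(x0 + rng.normal(0.0, 0.3, 2), lb, ub)
        res = least_squares(
            resid, start, bounds=(lb, ub),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf",
        )
        attempts.append({"x0": start.tolist(), "status": res.status, "cost": res.cost})
        if res.status > 0:
            best = res
            break
    if best is None:
        raise FitError(
            "logistic fit did not converge after restarts",
            diagnostics={"attempts": attempts},
        )
    A, r = (float(v) for v in np.exp(best.x))
    _, K = shape(best.x)
    N0 = K / (1.0 + A)
    flags: tuple[str, ...] = ()
    if N0 > 0.9 * K:
        # curve essentially at plateau from t=0: r is not identifiable
        flags = ("r-unidentifiable",)
    return LogisticFit(
        K=K, N0=N0, r=r, A=A,
        rss=float(2.0 * best.cost),
        converged=True,
        t_end=float(t[-1]),
        od_obs_max=ymax,
        flags=flags,
    )


def logistic_derivative(fit: LogisticFit, t: np.ndarray | float) -> np.ndarray:
    """Slope of the fitted curve, r N(t) (1 - N(t)/K)."""
    return fit.derivative(t)


def max_growth_rate(fit: LogisticFit) -> float:
    """Maximum slope of the fitted logistic: r K / 4 (attained at N = K/2)."""
    return fit.r * fit.K / 4.0


def growth_window(
    fit: LogisticFit,
    c: float = DERIV_THRESHOLD,
    clip_to: tuple[float, float] | None = None,
) -> GrowthWindow:
    """Interval on which the fitted derivative exceeds ``c``.

    Solves r N (1 - N/K) = c in closed form and maps the two roots to times;
    the result is clipped to ``clip_to`` (default: the observation interval
    [0, t_end]). Empty when the curve's maximum derivative rK/4 <= c, or when
    the fit is a flat line (A = 0).
    """
    if c <= 0:
        raise ValueError(f"threshold c must be > 0, got {c}")
    lo, hi = clip_to if clip_to is not None else (0.0, fit.t_end)
    if fit.r * fit.K / 4.0 <= c or fit.A <= 0.0:
        return GrowthWindow(c=c, t_start=math.nan, t_end_w=math.nan, empty=True)
    disc = math.sqrt(1.0 - 4.0 * c / (fit.r * fit.K))
    n_lo = 0.5 * fit.K * (1.0 - disc)
    n_hi = 0.5 * fit.K * (1.0 + disc)

    def t_of_n(n: float) -> float:
        return math.log(fit.A * n / (fit.K - n)) / fit.r

    t_lo, t_hi = t_of_n(n_lo), t_of_n(n_hi)
    t_start = min(max(t_lo, lo), hi)
    t_end_w = min(max(t_hi, lo), hi)
    return GrowthWindow(
        c=c, t_start=t_start, t_end_w=t_end_w, empty=False,
        t_lo_unclipped=t_lo, t_hi_unclipped=t_hi,
    )


def auc_exponential(fit: LogisticFit, window: GrowthWindow) -> float:
    """Integral of the fitted logistic over the growth window (closed form).

    Uses the antiderivative F(t) = (K/r) ln(e^{rt} + A), evaluated through
    ``logaddexp`` for numerical stability at large r t.
    """
    if window.empty or window.width <= 0.0:
        return 0.0

    if fit.A == 0.0:
        return fit.K * window.width

    def F(t: float) -> float:
        return fit.K / fit.r * float(np.logaddexp(fit.r * t, math.log(fit.A)))

    return F(window.t_end_w) - F(window.t_start)


def compute_metrics(
    curve: CorrectedCurve,
    c: float = DERIV_THRESHOLD,
    *,
    no_growth_floor: float = NO_GROWTH_FLOOR,
    seed: int = 0,
) -> GrowthMetrics:
    """Fit one corrected curve and derive (od_max, r_max, auc).

    No-growth curves (maximum below the floor) yield
    ``(od_max = max(od_adj), r_max = 0, auc = 0)`` with an empty window and
    no fit, rather than an error.
    """
    fit = fit_logistic(curve, no_growth_floor=no_growth_floor, seed=seed)
    if isinstance(fit, NoGrowthResult):
        window = GrowthWindow(c=c, t_start=math.nan, t_end_w=math.nan, empty=True)
        return GrowthMetrics(
            od_max=fit.od_obs_max, r_max=0.0, auc=0.0, window=window,
            od_obs_max=fit.od_obs_max, fit=None, flags=("no-growth",),
        )
    window = growth_window(fit, c=c)
    return GrowthMetrics(
        od_max=fit.K,
        r_max=max_growth_rate(fit),
        auc=auc_exponential(fit, window),
        window=window,
        od_obs_max=fit.od_obs_max,
        fit=fit,
        flags=fit.flags,
    )
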