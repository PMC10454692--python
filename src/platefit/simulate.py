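"""Synthetic plate experiments with known ground truth.

The generator emulates the study design the analysis assumes: several
independent experiments (blocks), each carrying replicate wells per growth
medium plus uninoculated blank wells per medium, read every 20 minutes for at
least 15 hours. Each inoculated well's raw signal is

    OD(t) = blank_level + blank_drift * t + logistic(K_w, r_w, N0) + noise,

where (K_w, r_w) are the condition's true parameters scaled by a log-normal
experiment-level multiplier shared by all wells of that experiment
(inter-experiment variation in inoculum and medium acts multiplicatively),
and the noise is additive Gaussian, the usual approximation for plate-reader
error at low optical density. Blank wells carry the same baseline, drift and
noise without the logistic term. Lag phases are not simulated; the fitted
model has no lag term either.

Ground-truth metrics per condition are evaluated *numerically* (grid/root
search for the derivative maximum and window, quadrature for the AUC) so
they are independent of the closed forms in :mod:`platefit.growth` and can
serve as an oracle for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .growth import DERIV_THRESHOLD
from .io import LayoutEntry, PlateLayout, TimeSeriesCurve


@dataclass(frozen=True)
class ConditionSpec:
    """True logistic parameters of one growth medium."""

    label: str
    K_true: float  # carrying capacity, OD600
    r_true: float  # intrinsic growth rate, per hour
    N0_true: float = 0.01  # inoculum optical density, OD600


@dataclass
class ScenarioSpec:
    """Ground-truth parameterization of a synthetic plate experiment."""

    strain_label: str
    conditions: list[ConditionSpec]
    block_sd: float = 0.05  # sd of experiment-level offsets on log K and log r
    noise_sd: float = 0.01  # additive OD600 measurement noise
    blank_level: float = 0.09  # medium baseline OD600
    blank_drift: float = 0.002  # linear blank drift, OD600 per hour
    n_experiments: int = 3
    n_replicates: int = 3
    n_blanks: int = 3
    cadence_min: float = 20.0
    duration_h: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("scenario needs at least one condition")
        for c in self.conditions:
            if min(c.K_true, c.r_true, c.N0_true) <= 0:
                raise ValueError(f"condition {c.label!r}: parameters must be > 0")
            if c.N0_true >= 0.2:
                raise ValueError(
                    f"condition {c.label!r}: N0_true must be < 0.2 "
                    "(wells start below OD600 0.2)"
                )
        if self.noise_sd < 0 or self.block_sd < 0:
            raise ValueError("noise_sd and block_sd must be >= 0")
        if self.blank_level <= 0:
            raise ValueError("blank_level must be > 0")
        if min(self.n_experiments, self.n_replicates, self.n_blanks) < 1:
            raise ValueError("need >= 1 experiment, replicate and blank")
        if self.cadence_min <= 0 or self.duration_h <= 0:
            raise ValueError("cadence and duration must be > 0")

    @property
    def times_h(self) -> np.ndarray:
        n = int(np.floor(self.duration_h * 60.0 / self.cadence_min + 1e-9)) + 1
        return np.arange(n) * (self.cadence_min / 60.0)


@dataclass
class SyntheticTruth:
    """Per-well true parameters and per-condition expected noiseless metrics."""

    per_well: dict[str, dict] = field(default_factory=dict)
    per_condition: dict[str, dict] = field(default_factory=dict)
    block_multipliers: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _logistic_alt(t, K, r, N0):
    # algebraically equivalent but distinct form from platefit.growth.logistic
    return N0 * K / (N0 + (K - N0) * np.exp(-r * t))


def true_metrics(
    K: float, r: float, N0: float, c: float = DERIV_THRESHOLD, t_end: float = 16.0
) -> dict:
    """Numerically evaluated metrics of a noiseless logistic trajectory.

    Derivative maximum by golden-section search on a finite-difference slope,
    window endpoints by bisection on slope - c, AUC by adaptive quadrature.
    Deliberately avoids the closed forms used by :mod:`platefit.growth`.
    """
    h = 1e-6

    def slope(t):
        return (_logistic_alt(t + h, K, r, N0) - _logistic_alt(t - h, K, r, N0)) / (2 * h)

    # bracket the slope maximum on a wide grid around the observation interval
    grid = np.linspace(-4.0 * t_end, 4.0 * t_end, 20001)
    s = slope(grid)
    i = int(np.argmax(s))
    r_max = float(s[i])
    from scipy.optimize import minimize_scalar

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    opt = minimize_scalar(lambda t: -slope(t), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    t_peak = float(opt.x)
    r_max = float(slope(t_peak))
    if r_max <= c:
        return {
            "od_max": K, "r_max": r_max, "auc": 0.0,
            "window": (np.nan, np.nan), "empty": True,
        }
    left_lo = t_peak - 1.0
    while slope(left_lo) > c:
        left_lo -= max(1.0, abs(left_lo))
    right_hi = t_peak + 1.0
    while slope(right_hi) > c:
        right_hi += max(1.0, abs(right_hi))
    t_lo = brentq(lambda t: slope(t) - c, left_lo, t_peak, xtol=1e-12)
    t_hi = brentq(lambda t: slope(t) - c, t_peak, right_hi, xtol=1e-12)
    a = min(max(t_lo, 0.0), t_end)
    b = min(max(t_hi, 0.0), t_end)
    auc = quad(lambda t: _logistic_alt(t, K, r, N0), a, b, epsabs=1e-12, epsrel=1e-12)[0] if b > a else 0.0
    return {
        "od_max": K, "r_max": r_max, "auc": float(auc),
        "window": (a, b), "empty": False,
    }


def generate_experiment(
    spec: ScenarioSpec,
) -> tuple[list[TimeSeriesCurve], PlateLayout, SyntheticTruth]:
    """Simulate a full multi-experiment plate run.

    Deterministic under ``spec.seed``. Returns raw curves (blanks included),
    the matching layout, and the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = spec.times_h
    entries: list[LayoutEntry] = []
    curves: list[TimeSeriesCurve] = []
    truth = SyntheticTruth()

    for cond in spec.conditions:
        truth.per_condition[cond.label] = {
            "K": cond.K_true, "r": cond.r_true, "N0": cond.N0_true,
            **true_metrics(cond.K_true, cond.r_true, cond.N0_true,
                           c=DERIV_THRESHOLD, t_end=float(t[-1])),
        }

    baseline = spec.blank_level + spec.blank_drift * t
    for e in range(1, spec.n_experiments + 1):
        exp_id = f"E{e}"
        mK = float(np.exp(rng.normal(0.0, spec.block_sd)))
        mr = float(np.exp(rng.normal(0.0, spec.block_sd)))
        truth.block_multipliers[exp_id] = {"K": mK, "r": mr}
        for ci, cond in enumerate(spec.conditions):
            K_w = cond.K_true * mK
            r_w = cond.r_true * mr
            for rep in range(1, spec.n_replicates + 1):
                well = f"{exp_id}-{chr(65 + ci)}{rep}"
                entry = LayoutEntry(
                    well_id=well, strain=spec.strain_label, condition=cond.label,
                    experiment_id=exp_id, replicate=rep, is_blank=False,
                )
                od = baseline + _logistic_alt(t, K_w, r_w, cond.N0_true)
                if spec.noise_sd > 0:
                    od = od + rng.normal(0.0, spec.noise_sd, t.size)
                od = np.clip(od, 0.0, None)
                entries.append(entry)
                curves.append(TimeSeriesCurve(well, entry, t.copy(), od))
                truth.per_well[well] = {
                    "experiment": exp_id, "condition": cond.label,
                    "K": K_w, "r": r_w, "N0": cond.N0_true,
                }
            for rep in range(1, spec.n_blanks + 1):
                well = f"{exp_id}-{chr(65 + ci)}B{rep}"
                entry = LayoutEntry(
                    well_id=well, strain="medium-blank", condition=cond.label,
                    experiment_id=exp_id, replicate=rep, is_blank=True,
                )
                od = baseline.copy()
                if spec.noise_sd > 0:
                    od = od + rng.normal(0.0, spec.noise_sd, t.size)
                od = np.clip(od, 0.0, None)
                entries.append(entry)
                curves.append(TimeSeriesCurve(well, entry, t.copy(), od))
    return curves, PlateLayout(entries), truth


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioSpec]:
    """Named scenarios spanning the qualitative response patterns seen in
    prebiotic utilization assays.

    All effect sizes are synthetic choices for testing, not estimates from
    any real strain. Media follow the assay design: a no-carbohydrate
    control, inulin, XOS, and (in the responder preset) a glucose control.
    """
    n0 = 0.01
    return {
        # both prebiotics raise carrying capacity and rate vs control
        "responder-both": ScenarioSpec(
            strain_label="synthetic-responder",
            conditions=[
                ConditionSpec("control", 0.30, 0.40, n0),
                ConditionSpec("inulin", 0.90, 0.80, n0),
                ConditionSpec("XOS", 0.80, 0.70, n0),
                ConditionSpec("glucose", 0.90, 0.90, n0),
            ],
            seed=seed,
        ),
        # XOS slows growth but raises the plateau
        "xos-slow-but-high": ScenarioSpec(
            strain_label="synthetic-xos-slow",
            conditions=[
                ConditionSpec("control", 0.50, 0.80, n0),
                ConditionSpec("inulin", 0.50, 0.80, n0),
                ConditionSpec("XOS", 0.80, 0.40, n0),
            ],
            seed=seed,
        ),
        # no condition effects at all (global null)
        "non-responder": ScenarioSpec(
            strain_label="synthetic-nonresponder",
            conditions=[
                ConditionSpec("control", 0.40, 0.50, n0),
                ConditionSpec("inulin", 0.40, 0.50, n0),
                ConditionSpec("XOS", 0.40, 0.50, n0),
            ],
            seed=seed,
        ),
        # all three metrics greater on inulin than on XOS
        "inulin-preferrer": ScenarioSpec(
            strain_label="synthetic-inulin-preferrer",
            conditions=[
                ConditionSpec("control", 0.30, 0.40, n0),
                ConditionSpec("inulin", 0.80, 0.90, n0),
                ConditionSpec("XOS", 0.50, 0.60, n0),
            ],
            seed=seed,
        ),
    }
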