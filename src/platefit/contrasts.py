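"""Blocked ANOVA, marginal means, and Tukey-adjusted pairwise contrasts.

Per strain and per growth metric, replicate-level observations are modelled
additively as ``value = mu + condition_i + block_j + error`` with the
experiment as a fixed blocking factor (ordinary least squares via
statsmodels). Marginal means average the model prediction for each condition
over the block levels with equal weight, so in a balanced design they equal
the raw condition means; in an unbalanced design they remain the model-based
condition means.

All-pairs comparisons use the Tukey HSD construction on the studentized-range
distribution with parameters (k conditions, residual df): the 95% interval
half-width is ``q(1-alpha; k, df)/sqrt(2) * SE(difference)`` and the adjusted
p-value is ``P(Q >= sqrt(2) |t|)``. With k = 2 this reduces exactly to the
unadjusted t-interval. Significance (p_adj < alpha) and the interval
excluding zero are dual by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DesignError, InferenceError, ReportError

METRICS = ("auc", "od_max", "r_max")


@dataclass
class MetricObservations:
    """Replicate-level values of one metric for one strain."""

    strain: str
    metric: str
    data: pd.DataFrame  # columns: value, condition, block, replicate

    def __post_init__(self) -> None:
        required = {"value", "condition", "block", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if self.data["value"].isna().any():
            raise ValueError("observations contain missing values")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_rows(cls, strain: str, metric: str, rows: list[tuple]) -> "MetricObservations":
        df = pd.DataFrame(rows, columns=["value", "condition", "block", "replicate"])
        return cls(strain=strain, metric=metric, data=df)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def blocks(self) -> list[str]:
        return sorted(self.data["block"].unique())

    @property
    def design_flags(self) -> list[str]:
        flags = []
        if len(self.conditions) < 2:
            flags.append("fewer than 2 conditions")
        if len(self.blocks) < 2:
            flags.append("fewer than 2 blocks")
        return flags


def pre_average_blocks(obs: MetricObservations) -> MetricObservations:
    """Collapse replicates to one mean value per (condition, block).

    Replicate-level analysis is the default; this helper supports the
    alternative convention of averaging within each experiment first.
    """
    g = (
        obs.data.groupby(["condition", "block"], as_index=False)["value"]
        .mean()
        .assign(replicate=1)
    )
    return MetricObservations(strain=obs.strain, metric=obs.metric, data=g)


def _design_matrix(
    cond_idx: np.ndarray, block_idx: np.ndarray, k: int, b: int, coding: str
) -> np.ndarray:
    """Build the additive-model design matrix under the requested coding."""
    n = cond_idx.size
    X = [np.ones(n)]
    if coding == "reference":
        for j in range(1, k):
            X.append((cond_idx == j).astype(float))
        for j in range(1, b):
            X.append((block_idx == j).astype(float))
    elif coding == "sum":
        for j in range(k - 1):
            X.append((cond_idx == j).astype(float) - (cond_idx == k - 1).astype(float))
        for j in range(b - 1):
            X.append((block_idx == j).astype(float) - (block_idx == b - 1).astype(float))
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return np.column_stack(X)


def _condition_rows(k: int, b: int, coding: str) -> np.ndarray:
    """Design rows whose product with beta gives each condition's marginal mean
    (prediction averaged over blocks with equal weight)."""
    cond_idx = np.repeat(np.arange(k), b)
    block_idx = np.tile(np.arange(b), k)
    X = _design_matrix(cond_idx, block_idx, k, b, coding)
    return X.reshape(k, b, -1).mean(axis=1)


@dataclass
class AnovaFit:
    """Fitted additive condition + block model for one metric and strain."""

    strain: str
    metric: str
    conditions: list[str]
    blocks: list[str]
    coding: str
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    df_resid: float
    resid: np.ndarray
    data: pd.DataFrame
    design_balanced: bool

    @property
    def n_groups(self) -> int:
        return len(self.conditions)


def fit_blocked_anova(obs: MetricObservations, coding: str = "reference") -> AnovaFit:
    """OLS fit of value ~ condition + block (both fixed, additive).

    The coding ("reference" or "sum") does not affect marginal means or
    contrasts. A rank-deficient design (e.g. a condition observed in no
    block that identifies it) raises :class:`DesignError`.
    """
    df = obs.data
    conditions, blocks = obs.conditions, obs.blocks
    k, b = len(conditions), len(blocks)
    counts = df.groupby(["condition", "block"]).size()
    for cond in conditions:
        if cond not in counts.index.get_level_values(0):
            raise DesignError(f"condition {cond!r} absent from all blocks")
    cond_idx = df["condition"].map({c: i for i, c in enumerate(conditions)}).to_numpy()
    block_idx = df["block"].map({g: i for i, g in enumerate(blocks)}).to_numpy()
    X = _design_matrix(cond_idx, block_idx, k, b, coding)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            "singular design: conditions and blocks are confounded "
            f"(conditions={conditions}, blocks={blocks})"
        )
    res = sm.OLS(df["value"].to_numpy(dtype=float), X).fit()
    resid = np.asarray(res.resid, dtype=float)
    df_resid = float(res.df_resid)
    sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    cell_counts = counts.values
    balanced = (
        len(counts) == k * b and np.all(cell_counts == cell_counts[0])
    )
    return AnovaFit(
        strain=obs.strain,
        metric=obs.metric,
        conditions=conditions,
        blocks=blocks,
        coding=coding,
        params=np.asarray(res.params, dtype=float),
        cov_params=cov,
        sigma2=sigma2,
        df_resid=df_resid,
        resid=resid,
        data=df,
        design_balanced=bool(balanced),
    )


def marginal_means(fit: AnovaFit) -> pd.DataFrame:
    """Model-based condition means averaged over block effects, with SEs."""
    M = _condition_rows(len(fit.conditions), len(fit.blocks), fit.coding)
    means = M @ fit.params
    ses = np.sqrt(np.einsum("ip,pq,iq->i", M, fit.cov_params, M))
    return pd.DataFrame({"condition": fit.conditions, "mean": means, "se": ses})


@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: float) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference of marginal means with Tukey adjustment."""

    pair: tuple[str, str]  # estimate is pair[0] - pair[1]
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_adj: float
    significant: bool
    alpha: float

    def reversed(self) -> "ContrastResult":
        """Same contrast with the opposite orientation."""
        return replace(
            self,
            pair=(self.pair[1], self.pair[0]),
            estimate=-self.estimate,
            ci_low=-self.ci_high,
            ci_high=-self.ci_low,
        )

    def oriented(self, first: str, second: str) -> "ContrastResult":
        if self.pair == (first, second):
            return self
        if self.pair == (second, first):
            return self.reversed()
        raise ReportError(f"contrast {self.pair} does not involve ({first}, {second})")


def tukey_pairwise(fit: AnovaFit, alpha: float = 0.05) -> list[ContrastResult]:
    """All k(k-1)/2 Tukey-adjusted pairwise condition contrasts."""
    if fit.df_resid < 1:
        raise InferenceError(
            f"df_resid = {fit.df_resid} < 1: no residual degrees of freedom"
        )
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = fit.n_groups
    M = _condition_rows(k, len(fit.blocks), fit.coding)
    q = _q_crit(alpha, k, fit.df_resid)
    out = []
    for i, j in combinations(range(k), 2):
        cvec = M[i] - M[j]
        est = float(cvec @ fit.params)
        se = float(np.sqrt(cvec @ fit.cov_params @ cvec))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            half = 0.0
        else:
            tstat = est / se
            p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(tstat), k, fit.df_resid))
            half = q / np.sqrt(2.0) * se
        out.append(
            ContrastResult(
                pair=(fit.conditions[i], fit.conditions[j]),
                estimate=est,
                se=se,
                df=fit.df_resid,
                ci_low=est - half,
                ci_high=est + half,
                p_adj=p,
                significant=p < alpha,
                alpha=alpha,
            )
        )
    return out


@dataclass
class DeltaTables:
    """Report-oriented views of the pairwise contrasts.

    ``delta_c`` maps each prebiotic label to its (prebiotic - control)
    contrast; ``delta_ix`` is the single (inulin - XOS) contrast, positive
    when growth on inulin exceeds growth on XOS; ``delta_glucose`` maps each
    non-glucose condition to its (condition - glucose) contrast when a
    glucose control is present.
    """

    delta_c: dict[str, ContrastResult]
    delta_ix: ContrastResult
    delta_glucose: dict[str, ContrastResult]


def _find(contrasts: list[ContrastResult], a: str, b: str) -> ContrastResult:
    for c in contrasts:
        if set(c.pair) == {a, b}:
            return c.oriented(a, b)
    raise ReportError(f"no contrast found for pair ({a!r}, {b!r})")


def delta_tables(
    contrasts: list[ContrastResult],
    control_label: str,
    inulin_label: str,
    xos_label: str,
    glucose_label: str | None = None,
) -> DeltaTables:
    """Orient raw contrasts into the standard report tables."""
    labels = {lab for c in contrasts for lab in c.pair}
    for lab in (control_label, inulin_label, xos_label):
        if lab not in labels:
            raise ReportError(f"condition label {lab!r} not present in contrasts")
    delta_c = {
        inulin_label: _find(contrasts, inulin_label, control_label),
        xos_label: _find(contrasts, xos_label, control_label),
    }
    delta_ix = _find(contrasts, inulin_label, xos_label)
    delta_glucose: dict[str, ContrastResult] = {}
    if glucose_label is not None and glucose_label in labels:
        for lab in sorted(labels - {glucose_label}):
            delta_glucose[lab] = _find(contrasts, lab, glucose_label)
    return DeltaTables(delta_c=delta_c, delta_ix=delta_ix, delta_glucose=delta_glucose)


def residual_diagnostics(fit: AnovaFit) -> dict:
    """Advisory checks of the ANOVA assumptions.

    Shapiro-Wilk on the residuals and a median-centred Levene test of
    variance homogeneity across conditions. Degenerate residuals (all equal)
    are flagged rather than raising.
    """
    out: dict = {
        "shapiro_stat": np.nan,
        "shapiro_p": np.nan,
        "levene_stat": np.nan,
        "levene_p": np.nan,
        "flags": [],
    }
    resid = fit.resid
    if np.ptp(resid) < 1e-12:
        out["flags"].append("degenerate-residuals")
        return out
    sw = stats.shapiro(resid)
    out["shapiro_stat"], out["shapiro_p"] = float(sw.statistic), float(sw.pvalue)
    groups = [
        resid[(fit.data["condition"] == c).to_numpy()] for c in fit.conditions
    ]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) >= 2:
        lv = stats.levene(*groups, center="median")
        out["levene_stat"], out["levene_p"] = float(lv.statistic), float(lv.pvalue)
    else:
        out["flags"].append("levene-skipped")
    if out["shapiro_p"] < 0.05:
        out["flags"].append("residual-normality-suspect")
    if np.isfinite(out["levene_p"]) and out["levene_p"] < 0.05:
        out["flags"].append("variance-homogeneity-suspect")
    return out
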