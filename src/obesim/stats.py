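"""Ecological cross-country statistics pipeline.

Operates on a country table (one row per nation) held as a pandas DataFrame
with the canonical lowercase columns in :data:`NUMERIC_COLUMNS`. Provides log
transforms, mixed Pearson/Spearman correlation matrices with pairwise-complete
observations, residual-method partial correlation, OLS and partial-F stepwise
regression (listwise-complete), median splits, exponential curve fits,
Fisher-z comparison of correlations, and the high-MMR x high-obesity
contingency analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

NATION = "nation"
DEVELOPMENT_CLASS = "development_class"
NUMERIC_COLUMNS = (
    "lmdr_1990",
    "mmr_1990",
    "neonatal_mortality_1990",
    "obesity_1990",
    "obesity_2016",
    "gdp_per_capita",
    "calorie_intake",
    "insufficient_physical_activity",
    "antibiotic_consumption",
)
ALL_COLUMNS = (NATION,) + NUMERIC_COLUMNS + (DEVELOPMENT_CLASS,)

DEVELOPMENT_CLASSES = (
    "developed",
    "developing",
    "least_developed",
    "low_income",
    "low_middle_income",
    "other",
)
#: classes pooled when an analysis is restricted to non-developed nations
DEVELOPING_CLASSES = (
    "developing",
    "least_developed",
    "low_income",
    "low_middle_income",
)

PEARSON_ON_LOGS = "pearson_on_logs"
SPEARMAN_ON_RAW = "spearman_on_raw"


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p_value: float
    n: int
    controls: tuple
    df: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit: per-variable beta/SE/p plus fit summary.

    ``params`` is indexed by variable name (including ``const``) with columns
    ``beta``, ``std_error``, ``p``. ``df1`` is the model df (number of
    predictors), ``df2`` the residual df (= n - predictors - 1).
    """

    params: pd.DataFrame
    adjusted_r2: float
    r2: float
    df1: int
    df2: int
    n: int
    response: str = ""


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" or "remove"
    variable: str
    p_value: float


@dataclass(frozen=True)
class StepwiseResult:
    steps: tuple
    selected: tuple
    fit: "RegressionFit | None"


@dataclass(frozen=True)
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of ``ln(y) = intercept + rate * x``."""

    intercept: float
    rate: float
    r: float
    r_squared: float
    n_used: int
    n_dropped: int

    def predict(self, x):
        return np.exp(self.intercept + self.rate * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p_value: float
    sidedness: str


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 MMR-class x obesity-class table with Pearson chi-squared."""

    counts: np.ndarray  # rows: (low_mmr, high_mmr); cols: (high_obesity, low_obesity)
    row_percentages: np.ndarray
    chi_squared: float
    p_value: float
    dof: int
    expected: np.ndarray
    n: int
    mmr_threshold: float = math.nan
    obesity_threshold: float = math.nan
    correction: bool = False

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "row_percentages": self.row_percentages.tolist(),
            "chi_squared": self.chi_squared,
            "p_value": self.p_value,
            "dof": self.dof,
            "expected": self.expected.tolist(),
            "n": self.n,
            "mmr_threshold": self.mmr_threshold,
            "obesity_threshold": self.obesity_threshold,
            "correction": self.correction,
        }


# ---------------------------------------------------------------------------
# transforms


def log_transform(
    table: pd.DataFrame,
    variables: "list[str] | tuple" = NUMERIC_COLUMNS,
    nonpositive: str = "floor",
) -> pd.DataFrame:
    """Natural-log the given columns; returns a new table.

    Values <= 0 cannot be logged. ``nonpositive="floor"`` replaces them with
    half the smallest positive observed value in that column (below-detection
    convention); ``nonpositive="missing"`` sets them to NaN. Counts of
    affected cells are recorded in ``result.attrs["log_transform"]``.
    """
    if nonpositive not in ("floor", "missing"):
        raise ValueError("nonpositive must be 'floor' or 'missing'")
    out = table.copy()
    report: dict = {"variables": list(variables), "nonpositive": nonpositive, "cells": {}}
    for var in variables:
        if var not in out.columns:
            raise KeyError(f"no column {var!r} in table")
        values = pd.to_numeric(out[var], errors="coerce").astype(float)
        bad = values.notna() & (values <= 0)
        n_bad = int(bad.sum())
        if n_bad:
            if nonpositive == "floor":
                positive = values[values > 0]
                if positive.empty:
                    raise ValueError(f"column {var!r} has no positive values to floor against")
                floor = positive.min() / 2.0
                values[bad] = floor
                report["cells"][var] = {"n_floored": n_bad, "floor_value": float(floor)}
            else:
                values[bad] = np.nan
                report["cells"][var] = {"n_set_missing": n_bad}
        out[var] = np.log(values)
    out.attrs = dict(table.attrs)
    out.attrs["log_transform"] = report
    return out


# ---------------------------------------------------------------------------
# correlation


def _pairwise(table: pd.DataFrame, a: str, b: str):
    sub = table[[a, b]].dropna()
    return sub[a].to_numpy(dtype=float), sub[b].to_numpy(dtype=float)


def correlation_matrix(
    table: pd.DataFrame,
    variables: "list[str] | tuple",
    method: str = PEARSON_ON_LOGS,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix with per-pair n and p-values.

    ``pearson_on_logs`` assumes the table has already been log-transformed;
    ``spearman_on_raw`` ranks the raw values. Cells with fewer than 3
    complete pairs are reported as NaN.
    """
    if method not in (PEARSON_ON_LOGS, SPEARMAN_ON_RAW):
        raise ValueError(f"unknown method {method!r}")
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j < i:
                continue
            if a in table.columns and b in table.columns:
                x, y = _pairwise(table, a, b)
            else:
                x = y = np.array([])
            n[i, j] = n[j, i] = len(x)
            if i == j:
                r[i, i] = 1.0 if len(x) else np.nan
                p[i, i] = 0.0 if len(x) else np.nan
                continue
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                continue
            if method == PEARSON_ON_LOGS:
                res = sps.pearsonr(x, y)
            else:
                res = sps.spearmanr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        method=method,
    )


def significance_stars(p_value: float) -> str:
    """Conventional star annotation for a p-value."""
    if not np.isfinite(p_value):
        return ""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def partial_correlation(
    table: pd.DataFrame, x: str, y: str, controls: "list[str] | tuple" = ()
) -> PartialCorrelationResult:
    """Correlation of x and y with the controls partialled out (residual method).

    Both variables are regressed (with intercept) on the controls over
    listwise-complete rows; the Pearson correlation of the two residual
    vectors is returned with a t-based p-value on ``n - k - 2`` df. With no
    controls this reduces to the simple Pearson correlation.
    """
    controls = tuple(controls)
    cols = [x, y, *controls]
    sub = table[cols].dropna()
    n = len(sub)
    k = len(controls)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete rows, got {n}")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"control design matrix is rank-deficient: {controls}")
    beta_x, *_ = np.linalg.lstsq(design, xv, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, yv, rcond=None)
    rx = xv - design @ beta_x
    ry = yv - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrelationResult(r=r, p_value=float(p), n=n, controls=controls, df=df)


# ---------------------------------------------------------------------------
# regression


def _listwise(table: pd.DataFrame, response: str, predictors) -> pd.DataFrame:
    return table[[response, *predictors]].dropna()


def ols_regression(
    table: pd.DataFrame, response: str, predictors: "list[str] | tuple"
) -> RegressionFit:
    """OLS of the response on the predictors over listwise-complete rows."""
    predictors = list(predictors)
    sub = _listwise(table, response, predictors)
    n = len(sub)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need more than {len(predictors) + 1} complete rows, got {n}"
        )
    X = sm.add_constant(sub[predictors].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"collinear predictors: {predictors}")
    model = sm.OLS(sub[response].astype(float), X).fit()
    params = pd.DataFrame(
        {"beta": model.params, "std_error": model.bse, "p": model.pvalues}
    )
    return RegressionFit(
        params=params,
        adjusted_r2=float(model.rsquared_adj),
        r2=float(model.rsquared),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        n=n,
        response=response,
    )


def stepwise_ols(
    table: pd.DataFrame,
    response: str,
    candidates: "list[str] | tuple",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise selection with backward elimination on partial-F p-values.

    At each step the candidate whose partial F-test (equivalently, the
    two-sided t-test of its coefficient in the augmented model) has the
    smallest p-value enters if ``p <= p_enter``; included variables with
    ``p >= p_remove`` are then ejected, worst first. Ties break by smaller p
    then candidate order, making the path deterministic. Rows are restricted
    once to those complete on the response and all candidates, so every
    sub-model sees the same data.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    sub = _listwise(table, response, candidates)
    order = {v: i for i, v in enumerate(candidates)}

    def coef_p(variables: list, target: str) -> float:
        fit = ols_regression(sub, response, variables)
        return float(fit.params.loc[target, "p"])

    selected: list = []
    steps: list = []
    while True:
        changed = False
        remaining = [v for v in candidates if v not in selected]
        entry = []
        for v in remaining:
            trial = selected + [v]
            if len(sub) <= len(trial) + 1:
                continue  # not enough rows to grow further
            entry.append((coef_p(trial, v), order[v], v))
        if entry:
            entry.sort()
            best_p, _, best_v = entry[0]
            if best_p <= p_enter:
                selected.append(best_v)
                steps.append(StepwiseStep("enter", best_v, best_p))
                changed = True
        while len(selected) > 0:
            removal = sorted(
                ((coef_p(selected, v), -order[v], v) for v in selected),
                key=lambda t: (-t[0], t[1]),
            )
            worst_p, _, worst_v = removal[0]
            if worst_p >= p_remove:
                selected.remove(worst_v)
                steps.append(StepwiseStep("remove", worst_v, worst_p))
                changed = True
            else:
                break
        if not changed:
            break
    fit = ols_regression(sub, response, selected) if selected else None
    return StepwiseResult(steps=tuple(steps), selected=tuple(selected), fit=fit)


# ---------------------------------------------------------------------------
# splits and curve fits


def median_split(table: pd.DataFrame, variable: str):
    """Split rows at the median of ``variable`` (ties go below).

    Returns ``(below_table, above_table, median_value)``; rows missing the
    variable are excluded from both halves. The split value is computed from
    the data, not assumed.
    """
    values = pd.to_numeric(table[variable], errors="coerce")
    non_missing = values.dropna()
    if len(non_missing) < 2:
        raise ValueError(f"need >= 2 non-missing values of {variable!r}")
    med = float(non_missing.median())
    present = values.notna()
    below = table[present & (values <= med)]
    above = table[present & (values > med)]
    return below, above, med


def fit_exponential(table: pd.DataFrame, x: str, y: str) -> ExponentialFit:
    """Fit ``y = exp(intercept + rate * x)`` by OLS on ``ln(y)``.

    Rows with missing values or non-positive y are dropped (and counted).
    ``r`` is the Pearson correlation between x and ln(y); ``r_squared`` its
    square (the R^2 of the log-level fit).
    """
    sub = table[[x, y]].dropna()
    yv = sub[y].to_numpy(dtype=float)
    keep = yv > 0
    n_dropped = int(len(table) - keep.sum())
    sub = sub[keep]
    if len(sub) < 3:
        raise ValueError("need >= 3 usable rows")
    xv = sub[x].to_numpy(dtype=float)
    ln_y = np.log(sub[y].to_numpy(dtype=float))
    slope, intercept = np.polyfit(xv, ln_y, 1)
    if np.std(xv) == 0 or np.std(ln_y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(xv, ln_y)[0, 1])
    return ExponentialFit(
        intercept=float(intercept),
        rate=float(slope),
        r=r,
        r_squared=r * r,
        n_used=len(sub),
        n_dropped=n_dropped,
    )


def variance_explained(r: float) -> float:
    """Percent of variance explained by a correlation: ``100 * r**2``."""
    r = float(r)
    if not math.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return 100.0 * r * r


def fisher_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    sidedness: str = "two_sided",
    controls1: int = 0,
    controls2: int = 0,
) -> FisherZResult:
    """Fisher z-test for the difference of two independent correlations.

    For partial correlations pass the number of controls; the standard error
    uses ``1 / (n - 3 - controls)`` per sample. One-sided p is for the
    alternative that ``|r1| > |r2|`` tested via ``|z|`` (half the two-sided
    p); the convention is echoed in the result.
    """
    if sidedness not in ("two_sided", "one_sided"):
        raise ValueError("sidedness must be 'two_sided' or 'one_sided'")
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError(f"degenerate correlation |r| >= 1: {r}")
    d1 = n1 - 3 - controls1
    d2 = n2 - 3 - controls2
    if d1 <= 0 or d2 <= 0:
        raise ValueError("need n > controls + 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / d1 + 1.0 / d2)
    tail = sps.norm.sf(abs(z))
    p = 2.0 * tail if sidedness == "two_sided" else tail
    return FisherZResult(z=float(z), p_value=float(p), sidedness=sidedness)


# ---------------------------------------------------------------------------
# contingency


def row_percentages(counts) -> np.ndarray:
    """Percent of each row total contributed by each cell."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero row total")
    return 100.0 * counts / totals


def contingency_from_counts(
    counts,
    correction: bool = False,
    mmr_threshold: float = math.nan,
    obesity_threshold: float = math.nan,
) -> ContingencyResult:
    """Pearson chi-squared on a 2x2 count table (Yates correction optional)."""
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {counts.shape}")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
    counts = counts.astype(int)
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, p, dof, expected = sps.chi2_contingency(counts, correction=correction)
    return ContingencyResult(
        counts=counts,
        row_percentages=row_percentages(counts),
        chi_squared=float(chi2),
        p_value=float(p),
        dof=int(dof),
        expected=np.asarray(expected),
        n=int(counts.sum()),
        mmr_threshold=mmr_threshold,
        obesity_threshold=obesity_threshold,
        correction=correction,
    )


def classify_and_contingency(
    table: pd.DataFrame,
    mmr_threshold: float = 500.0,
    obesity_threshold: float = 19.5,
    classes: "tuple | list | None" = DEVELOPING_CLASSES,
    correction: bool = False,
) -> ContingencyResult:
    """High-MMR x high-obesity 2x2 analysis on a development-class subset.

    Rows: nations with MMR <= threshold (low) then > threshold (high);
    columns: obesity above the threshold (high) then at-or-below (low).
    ``classes=None`` uses every nation with both values present.
    """
    sub = table
    if classes is not None:
        sub = sub[sub[DEVELOPMENT_CLASS].isin(classes)]
    sub = sub.dropna(subset=["mmr_1990", "obesity_2016"])
    if sub.empty:
        raise ValueError("no rows left after subsetting; cannot build contingency table")
    high_mmr = sub["mmr_1990"].to_numpy(dtype=float) > mmr_threshold
    high_ob = sub["obesity_2016"].to_numpy(dtype=float) > obesity_threshold
    counts = np.array(
        [
            [int((~high_mmr & high_ob).sum()), int((~high_mmr & ~high_ob).sum())],
            [int((high_mmr & high_ob).sum()), int((high_mmr & ~high_ob).sum())],
        ]
    )
    return contingency_from_counts(
        counts,
        correction=correction,
        mmr_threshold=mmr_threshold,
        obesity_threshold=obesity_threshold,
    )
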