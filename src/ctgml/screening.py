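"""Univariable screening of candidate predictors of perinatal asphyxia.

The screen follows standard epidemiological practice for a rare binary
outcome: per-group descriptive statistics, single-variable binary
logistic regressions yielding odds ratios with Wald 95% confidence
intervals and p-values, redundancy pruning of highly rank-correlated
predictors (Spearman |rho| > 0.6, transitively clustered, keeping the
most significant member of each cluster), and a liberal candidate cut of
p < 0.2 for entry into multivariable models.

Missing maternal BMI is imputed with the median BMI of mothers of the
same (integer) age, falling back to the overall median when no same-age
donor exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import COLUMN_KINDS, DESCRIPTIVE_ONLY

__all__ = [
    "UnivariableResult",
    "ScreenReport",
    "UnivariableScreen",
    "AgeMedianBmiImputer",
    "describe",
    "impute_bmi",
    "univariable_blr",
    "spearman_prune",
    "select_candidates",
    "candidate_features",
]

#: Reference level per categorical column when dummy-coding candidates.
REFERENCE_LEVELS = {
    "blood_group": "O",
    "rh": "neg",
    "pregnancy_type": "spontaneous",
    "fetal_presentation": "cephalic",
    "delivery_type": "vaginal",
    "fetal_sex": "female",
}


@dataclass(frozen=True)
class UnivariableResult:
    """Odds ratio, Wald 95% CI and p-value for one candidate predictor.

    ``separated`` flags fits where maximum likelihood diverged (perfect
    separation or singular design); such results carry non-finite CI
    bounds and are excluded from candidate selection.
    """

    variable: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    separated: bool = False


@dataclass
class ScreenReport:
    """Outcome of the univariable screen."""

    results: list[UnivariableResult]
    pruned: list[tuple[str, str, float]]  # (dropped, kept, spearman rho)
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variable": r.variable, "or": r.or_point, "ci_low": r.ci_low,
              "ci_high": r.ci_high, "p_value": r.p_value,
              "separated": r.separated,
              "selected": r.variable in self.selected}
             for r in self.results]
        ).set_index("variable")


def describe(table: pd.DataFrame, group_col: str = "outcome") -> pd.DataFrame:
    """Per-group summaries: median (IQR) for continuous, n (%) otherwise."""
    if table.empty:
        raise ValueError("empty cohort")
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("both outcome groups must be present")
    rows = {}
    for col in table.columns:
        if col == group_col:
            continue
        kind = COLUMN_KINDS.get(col, "continuous" if
                                pd.api.types.is_float_dtype(table[col]) else "count")
        cells = {}
        for g in groups:
            x = table.loc[table[group_col] == g, col]
            label = f"{group_col}={g} (n={len(x)})"
            if kind in ("continuous", "count"):
                q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
                cells[label] = f"{med:g} ({q1:g}-{q3:g})"
            elif kind == "bernoulli":
                n = int((x == 1).sum())
                cells[label] = f"{n} ({100 * n / len(x):.0f}%)"
            else:
                parts = [f"{lvl}: {n} ({100 * n / len(x):.0f}%)"
                         for lvl, n in x.value_counts().items()]
                cells[label] = "; ".join(parts)
        rows[col] = cells
    return pd.DataFrame(rows).T


def impute_bmi(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing BMI with the median BMI of mothers of the same integer age."""
    out = table.copy()
    missing = out["bmi"].isna()
    if not missing.any():
        return out
    if missing.all():
        raise ValueError("all BMI values missing; nothing to impute from")
    donors = out.loc[~missing]
    by_age = donors.groupby(donors["maternal_age"].round().astype(int))["bmi"].median()
    overall = donors["bmi"].median()
    ages = out.loc[missing, "maternal_age"].round().astype(int)
    out.loc[missing, "bmi"] = [by_age.get(a, overall) for a in ages]
    return out


class AgeMedianBmiImputer(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`impute_bmi`.

    ``fit`` learns the per-age median BMI table (and the overall median
    fallback) from the training data; ``transform`` fills missing BMI in
    any table using the learned donors, so the imputation can sit inside
    an sklearn pipeline without leaking test-set information.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "AgeMedianBmiImputer":
        donors = X.loc[X["bmi"].notna()]
        if donors.empty:
            raise ValueError("all BMI values missing; nothing to impute from")
        self.by_age_ = donors.groupby(
            donors["maternal_age"].round().astype(int))["bmi"].median()
        self.overall_ = float(donors["bmi"].median())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        missing = out["bmi"].isna()
        if missing.any():
            ages = out.loc[missing, "maternal_age"].round().astype(int)
            out.loc[missing, "bmi"] = [self.by_age_.get(a, self.overall_)
                                       for a in ages]
        return out


def univariable_blr(x, y, name: str = "x") -> UnivariableResult:
    """Single-predictor binary logistic regression: OR, Wald CI, p-value.

    For a binary predictor the maximum-likelihood OR coincides with the
    contingency-table cross-product ratio.  Perfect separation is flagged
    rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {name!r} is constant")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(method="newton", disp=0,
                                          maxiter=100, tol=1e-12)
        coef = fit.params[1]
        se = fit.bse[1]
        p = fit.pvalues[1]
        if not (np.isfinite(coef) and np.isfinite(se) and se < 1e3):
            raise FloatingPointError("diverged")
    except Exception:
        return UnivariableResult(name, np.nan, np.nan, np.nan, np.nan,
                                 separated=True)
    return UnivariableResult(
        variable=name,
        or_point=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p_value=float(p),
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def spearman_prune(X: pd.DataFrame, results: dict[str, UnivariableResult],
                   threshold: float = 0.6,
                   ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop redundant predictors by Spearman rank correlation.

    Columns with pairwise |rho| > ``threshold`` are clustered by
    transitive closure; within each cluster only the variable with the
    smallest univariable p-value survives (ties broken lexicographically
    by name; flagged/NaN p-values sort last).  Returns ``(kept, audit)``
    with the audit trail as ``(dropped, kept, rho)`` triples.
    """
    cols = list(X.columns)
    missing = [c for c in cols if c not in results]
    if missing:
        raise ValueError(f"no screen result for column(s) {missing}")
    arr = X.to_numpy(float)
    arr = np.where(np.isfinite(arr), arr, np.nan)
    if arr.shape[1] == 1:
        rho = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore"):
            rho = stats.spearmanr(arr, axis=0, nan_policy="omit").statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(rho)
    uf = _UnionFind(cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(rho[i, j]) > threshold:
                uf.union(cols[i], cols[j])
    clusters: dict[str, list[str]] = {}
    for c in cols:
        clusters.setdefault(uf.find(c), []).append(c)

    def sort_key(c):
        p = results[c].p_value
        return (np.isnan(p), p if np.isfinite(p) else np.inf, c)

    kept, audit = [], []
    for members in clusters.values():
        members = sorted(members, key=sort_key)
        winner = members[0]
        kept.append(winner)
        i_w = cols.index(winner)
        for loser in members[1:]:
            audit.append((loser, winner, float(rho[cols.index(loser), i_w])))
    kept.sort(key=cols.index)
    return kept, audit


def select_candidates(results: dict[str, UnivariableResult],
                      alpha: float = 0.2,
                      kept: list[str] | None = None) -> list[str]:
    """Names with univariable p < alpha, restricted to the pruned set."""
    if not results:
        raise ValueError("no screen results")
    pool = kept if kept is not None else list(results)
    return [name for name in pool
            if np.isfinite(results[name].p_value)
            and results[name].p_value < alpha]


def candidate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric candidate matrix from a cohort (+features) table.

    Drops the outcome and newborn outcome descriptors, dummy-codes
    categorical columns against the documented reference levels (the
    male-fetus indicator is named ``male_fetus``), and keeps everything
    else as float.
    """
    X = table.drop(columns=["outcome", *DESCRIPTIVE_ONLY], errors="ignore")
    out = {}
    for col in X.columns:
        if pd.api.types.is_numeric_dtype(X[col]):
            out[col] = X[col].astype(float)
            continue
        ref = REFERENCE_LEVELS.get(col)
        levels = [lvl for lvl in pd.unique(X[col]) if lvl != ref]
        for lvl in sorted(map(str, levels)):
            name = "male_fetus" if (col, lvl) == ("fetal_sex", "male") \
                else f"{col}_{lvl}"
            out[name] = (X[col].astype(str) == lvl).astype(float)
    return pd.DataFrame(out, index=table.index)


class UnivariableScreen(TransformerMixin, BaseEstimator):
    """Univariable logistic screen as an sklearn-style feature selector.

    ``fit(X, y)`` runs one logistic regression per column of the numeric
    candidate frame ``X`` against the binary outcome ``y``, prunes
    redundant columns (Spearman |rho| > ``corr_threshold``) and selects
    those with p < ``alpha``.  ``transform`` restricts a frame to the
    selected columns.

    Attributes
    ----------
    results_ : dict[str, UnivariableResult]
    report_ : ScreenReport
    selected_ : list[str]
    """

    def __init__(self, alpha: float = 0.2, corr_threshold: float = 0.6) -> None:
        self.alpha = alpha
        self.corr_threshold = corr_threshold

    def fit(self, X: pd.DataFrame, y) -> "UnivariableScreen":
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError("outcome must contain both classes")
        results = {}
        usable = []
        for col in X.columns:
            series = X[col].to_numpy(float)
            ok = np.isfinite(series)  # degenerate/flagged values act as missing
            if ok.sum() < 4 or np.ptp(series[ok]) == 0 \
                    or len(np.unique(y[ok])) != 2:
                continue
            results[col] = univariable_blr(series[ok], y[ok], name=col)
            usable.append(col)
        kept, audit = spearman_prune(X[usable], results, self.corr_threshold)
        selected = select_candidates(results, self.alpha, kept)
        self.results_ = results
        self.report_ = ScreenReport(results=list(results.values()),
                                    pruned=audit, selected=selected)
        self.selected_ = selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]
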