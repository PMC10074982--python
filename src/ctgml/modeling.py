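"""Asphyxia risk models and their evaluation under class imbalance.

The positive class is rare (15 of 517 by default), so model training
rebalances the training split — by smoothed-bootstrap oversampling of the
minority class to a target prevalence (default 0.3), random undersampling
of the majority, or a hybrid — while the test split is always left
untouched.  Two classifier families are provided: a binary logistic
regression exposing adjusted odds ratios with Wald intervals, and a
Naive-Bayes classifier with Gaussian class-conditionals for continuous
features and add-one-smoothed frequency tables for categorical ones.

Discrimination is summarised by the rank-based AUC over repeated
stratified 55/45 train/test splits (default 1,000 repetitions), reported
as the mean AUC with a normal-approximation 95% confidence interval of
the mean; a leave-one-out variant pools one held-out score per subject.
Calibration is checked with the Hosmer–Lemeshow decile test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "ResamplingSpec",
    "EvaluationSpec",
    "EvaluationSummary",
    "PrevalenceResampler",
    "LogisticOddsRatio",
    "MixedNaiveBayes",
    "auc",
    "evaluate_repeated",
    "evaluate_loo",
    "hosmer_lemeshow",
    "threshold_screen",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ResamplingSpec:
    """How to rebalance a training set."""

    method: str = "oversample"  # oversample | undersample | hybrid
    target_prevalence: float = 0.3
    jitter_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("oversample", "undersample", "hybrid"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.jitter_fraction < 0:
            raise ValueError("jitter_fraction must be >= 0")


@dataclass(frozen=True)
class EvaluationSpec:
    """Repeated train/test evaluation protocol."""

    train_fraction: float = 0.55
    n_repetitions: int = 1000
    classification_cut: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0.0 < self.classification_cut < 1.0:
            raise ValueError("classification_cut must be in (0, 1)")


@dataclass
class EvaluationSummary:
    """Mean AUC (percent) with a 95% CI of the mean over repetitions."""

    model: str
    mean_auc: float
    ci_low: float
    ci_high: float
    aucs: np.ndarray = field(repr=False)


class PrevalenceResampler(BaseEstimator):
    """Rebalance a two-class training set to a target minority prevalence.

    ``oversample`` duplicates minority rows with replacement (smoothed
    bootstrap: duplicated continuous features are perturbed with Gaussian
    noise of SD ``jitter_fraction`` x the feature's SD; ``jitter_fraction=0``
    gives plain duplication), leaving the majority untouched.
    ``undersample`` randomly drops majority rows.  ``hybrid`` does both,
    holding the total count at the original size.  The achieved prevalence
    is within +/-0.01 of the target.
    """

    def __init__(self, method: str = "oversample",
                 target_prevalence: float = 0.3,
                 jitter_fraction: float = 0.1,
                 random_state: int | None = None) -> None:
        self.method = method
        self.target_prevalence = target_prevalence
        self.jitter_fraction = jitter_fraction
        self.random_state = random_state

    def _spec(self) -> ResamplingSpec:
        return ResamplingSpec(self.method, self.target_prevalence,
                              self.jitter_fraction)

    def fit_resample(self, X: pd.DataFrame, y,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, np.ndarray]:
        spec = self._spec()
        rng = rng or np.random.default_rng(self.random_state)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) != 2:
            raise ValueError("both classes must be present")
        X = pd.DataFrame(X)
        counts = np.bincount(y, minlength=2)
        minority = int(np.argmin(counts))
        p = spec.target_prevalence
        n_min, n_maj = counts[minority], counts[1 - minority]

        if spec.method == "oversample":
            tgt_min, tgt_maj = round(p / (1 - p) * n_maj), n_maj
        elif spec.method == "undersample":
            tgt_min, tgt_maj = n_min, round((1 - p) / p * n_min)
        else:  # hybrid: keep total, split at target prevalence
            total = n_min + n_maj
            tgt_min = round(p * total)
            tgt_maj = total - tgt_min

        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y == 1 - minority)

        if tgt_maj < n_maj:
            maj_keep = rng.choice(maj_idx, size=tgt_maj, replace=False)
        else:
            maj_keep = maj_idx
        extra = max(0, tgt_min - n_min)
        min_extra = rng.choice(min_idx, size=extra, replace=True)

        parts = [X.iloc[maj_keep], X.iloc[min_idx]]
        labels = [np.full(len(maj_keep), 1 - minority),
                  np.full(n_min, minority)]
        if extra:
            synth = X.iloc[min_extra].copy()
            if spec.jitter_fraction > 0:
                for col in synth.columns:
                    vals = X[col]
                    # continuous = float-typed and not integer-coded
                    # (dummies and counts are duplicated untouched)
                    if pd.api.types.is_float_dtype(vals) and not np.all(
                            vals.to_numpy() == np.rint(vals.to_numpy())):
                        sd = float(vals.std(ddof=0))
                        synth[col] = synth[col] + rng.normal(
                            0.0, spec.jitter_fraction * sd, size=len(synth))
            synth.index = [f"{i}*{k}" for k, i in enumerate(synth.index)]
            parts.append(synth)
            labels.append(np.full(extra, minority))
        Xr = pd.concat(parts)
        yr = np.concatenate(labels)
        achieved = float((yr == minority).mean())
        if abs(achieved - p) > 0.011:
            # only reachable when integer rounding cannot get closer
            warnings.warn(
                f"achieved prevalence {achieved:.3f} vs target {p}; "
                "training set too small to hit the target exactly",
                RuntimeWarning)
        return Xr, yr


class LogisticOddsRatio(ClassifierMixin, BaseEstimator):
    """Binary logistic regression exposing odds ratios, Wald CIs, p-values.

    Thin sklearn-style wrapper over a maximum-likelihood GLM fit.  A fit
    that diverges (perfect separation / singular design) is flagged via
    ``separated_`` with non-finite interval bounds; scores remain usable.

    Attributes (after ``fit``)
    --------------------------
    params_ : pd.Series of coefficients (incl. ``const``)
    odds_ratios_, conf_int_, pvalues_ : exponentiated slopes and Wald stats
    separated_ : bool
    """

    def __init__(self, cut: float = 0.5) -> None:
        self.cut = cut

    def fit(self, X: pd.DataFrame, y) -> "LogisticOddsRatio":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) != 2:
            raise ValueError("both classes must be present")
        if X.shape[1] < 1:
            raise ValueError("at least one predictor required")
        design = sm.add_constant(X.astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=200)
        self.variables_ = list(X.columns)
        self.params_ = fit.params
        self.bse_ = fit.bse
        self.pvalues_ = fit.pvalues
        self.separated_ = bool(
            (~np.isfinite(fit.bse)).any() or np.abs(fit.params).max() > 30)
        slopes = fit.params.drop("const")
        se = fit.bse.drop("const")
        if self.separated_:
            se = se * np.nan
        with np.errstate(over="ignore"):  # separated fits overflow to inf
            self.odds_ratios_ = np.exp(slopes)
            self.conf_int_ = pd.DataFrame({
                "ci_low": np.exp(slopes - _Z95 * se),
                "ci_high": np.exp(slopes + _Z95 * se),
            })
        self.classes_ = np.array([0, 1])
        return self

    def summary_frame(self) -> pd.DataFrame:
        out = self.conf_int_.copy()
        out.insert(0, "or", self.odds_ratios_)
        out["p_value"] = self.pvalues_.drop("const")
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise ValueError(f"records lack model variable(s) {missing}")
        design = sm.add_constant(X[self.variables_].astype(float),
                                 has_constant="add")
        eta = design.to_numpy() @ self.params_.to_numpy()
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # A score exactly at the cut counts as positive.
        return (self.predict_proba(X)[:, 1] >= self.cut).astype(int)


class MixedNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes for mixed continuous/categorical features.

    Continuous (float) features get Gaussian class-conditionals;
    categorical/integer-coded features get frequency tables with add-one
    (Laplace) smoothing.  Posteriors are prior x product of per-feature
    likelihoods, normalised per record.  A zero-variance continuous
    feature within a class has its variance floored (with a warning) so
    scoring stays finite.
    """

    def __init__(self, var_floor: float = 1e-9, cut: float = 0.5,
                 categorical: tuple[str, ...] | None = None) -> None:
        self.var_floor = var_floor
        self.cut = cut
        self.categorical = categorical

    def _is_categorical(self, name: str, values: pd.Series) -> bool:
        if self.categorical is not None:
            return name in self.categorical
        if not pd.api.types.is_float_dtype(values):
            return True
        # float-coded 0/1 indicators are categorical, not Gaussian
        return bool(np.isin(values.dropna().unique(), (0.0, 1.0)).all())

    def fit(self, X: pd.DataFrame, y) -> "MixedNaiveBayes":
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present")
        self.variables_ = list(X.columns)
        self.priors_ = {c: float((y == c).mean()) for c in self.classes_}
        self.gaussian_: dict[str, dict[int, tuple[float, float]]] = {}
        self.tables_: dict[str, dict[int, dict]] = {}
        for col in X.columns:
            if self._is_categorical(col, X[col]):
                levels = sorted(map(str, pd.unique(X[col].astype(str))))
                self.tables_[col] = {}
                for c in self.classes_:
                    sub = X.loc[y == c, col].astype(str)
                    counts = sub.value_counts()
                    denom = len(sub) + len(levels)  # add-one smoothing
                    self.tables_[col][c] = {
                        lvl: (counts.get(lvl, 0) + 1) / denom for lvl in levels}
            else:
                overall_var = float(X[col].astype(float).var(ddof=0))
                floor = self.var_floor * max(overall_var, 1.0)
                self.gaussian_[col] = {}
                for c in self.classes_:
                    sub = X.loc[y == c, col].astype(float)
                    mu = float(sub.mean())
                    var = float(sub.var(ddof=0))
                    if var <= 0:
                        warnings.warn(
                            f"zero variance for {col!r} in class {c}; "
                            "flooring", RuntimeWarning)
                        var = floor
                    self.gaussian_[col][c] = (mu, max(var, floor))
        return self

    def _log_likelihood(self, X: pd.DataFrame, c: int) -> np.ndarray:
        ll = np.full(len(X), math.log(self.priors_[c]))
        for col, per_class in self.gaussian_.items():
            mu, var = per_class[c]
            v = X[col].to_numpy(float)
            ll += -0.5 * (math.log(2 * math.pi * var) + (v - mu) ** 2 / var)
        for col, per_class in self.tables_.items():
            table = per_class[c]
            # unseen level -> smoothed pseudo-count mass
            default = 1.0 / (1.0 + len(table))
            probs = X[col].astype(str).map(
                lambda lvl: table.get(lvl, default))
            ll += np.log(probs.to_numpy(float))
        return ll

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise ValueError(f"records lack model variable(s) {missing}")
        ll = np.column_stack(
            [self._log_likelihood(X, c) for c in self.classes_])
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.cut).astype(int)


def auc(scores, labels) -> float:
    """Rank-based AUC in percent: P(random positive outscores a random
    negative), ties counting one half."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return 100.0 * float(roc_auc_score(labels, scores))


def evaluate_repeated(X: pd.DataFrame, y, model: BaseEstimator,
                      eval_spec: EvaluationSpec = EvaluationSpec(),
                      resampling: ResamplingSpec | None = ResamplingSpec(),
                      seed: int = 0, label: str | None = None,
                      ) -> EvaluationSummary:
    """Repeated stratified holdout evaluation.

    Each repetition draws a fresh stratified ``train_fraction`` split,
    rebalances the training rows only (``resampling=None`` skips this),
    fits a clone of ``model``, scores the untouched test rows and records
    the AUC.  The summary is the mean AUC with the 95% normal CI of the
    mean over repetitions.  Fully determined by ``seed``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    master = np.random.SeedSequence(seed)
    aucs = np.empty(eval_spec.n_repetitions)
    resampler = None
    if resampling is not None:
        resampler = PrevalenceResampler(
            resampling.method, resampling.target_prevalence,
            resampling.jitter_fraction)
    for rep, ss in enumerate(master.spawn(eval_spec.n_repetitions)):
        rng = np.random.default_rng(ss)
        for _ in range(100):  # stratification guard: redraw degenerate splits
            split_seed = int(rng.integers(2 ** 31))
            idx_train, idx_test = train_test_split(
                np.arange(len(y)), train_size=eval_spec.train_fraction,
                stratify=y, random_state=split_seed)
            if len(np.unique(y[idx_test])) == 2:
                break
        X_train, y_train = X.iloc[idx_train], y[idx_train]
        if resampler is not None:
            X_train, y_train = resampler.fit_resample(X_train, y_train, rng)
        fitted = clone(model).fit(X_train, y_train)
        scores = fitted.predict_proba(X.iloc[idx_test])[:, 1]
        aucs[rep] = auc(scores, y[idx_test])
    mean = float(aucs.mean())
    half = _Z95 * float(aucs.std(ddof=0)) / math.sqrt(len(aucs))
    return EvaluationSummary(
        model=label or type(model).__name__,
        mean_auc=mean, ci_low=mean - half, ci_high=mean + half, aucs=aucs)


def evaluate_loo(X: pd.DataFrame, y, model: BaseEstimator,
                 n_bootstrap: int = 2000, seed: int = 0,
                 label: str | None = None) -> EvaluationSummary:
    """Leave-one-out evaluation: each subject scored by a model fitted on
    all others (no resampling); one pooled AUC with a bootstrap-over-
    records 95% CI."""
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fitted = clone(model).fit(X.iloc[mask], y[mask])
        scores[i] = fitted.predict_proba(X.iloc[[i]])[0, 1]
    point = auc(scores, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) == 2:
            boots.append(auc(scores[idx], y[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvaluationSummary(model=label or type(model).__name__,
                             mean_auc=point, ci_low=float(lo),
                             ci_high=float(hi), aucs=scores)


def hosmer_lemeshow(scores, labels, n_groups: int = 10
                    ) -> tuple[float, float]:
    """Hosmer-Lemeshow decile-of-risk calibration test.

    Records are binned by score deciles; the statistic is
    sum (O - E)^2 / (E * (1 - E/n_g)) over bins with E the expected event
    count, referred to chi^2 with ``n_groups - 2`` degrees of freedom.
    """
    from scipy import stats as sps

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    try:
        bins = pd.qcut(scores, n_groups, labels=False, duplicates="drop")
    except ValueError as exc:
        raise ValueError("degenerate score binning") from exc
    n_bins = int(bins.max()) + 1
    if n_bins < 2:
        raise ValueError("score ties collapse to fewer than 2 bins")
    stat = 0.0
    for b in range(n_bins):
        mask = bins == b
        n_g = int(mask.sum())
        obs = labels[mask].sum()
        exp = scores[mask].sum()
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    p = float(sps.chi2.sf(stat, df=max(n_groups - 2, 1)))
    return float(stat), p


def threshold_screen(values, labels, threshold: float
                     ) -> tuple[float, float, dict[str, int]]:
    """Single-threshold screen: positive call when value >= threshold.

    Returns (sensitivity %, specificity %, confusion counts).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    call = values >= threshold
    tp = int((call & (labels == 1)).sum())
    fn = int((~call & (labels == 1)).sum())
    tn = int((~call & (labels == 0)).sum())
    fp = int((call & (labels == 0)).sum())
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return sens, spec, {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
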