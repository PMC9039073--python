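"""Statistical validation battery for selected lipid features.

Covers the classical checks run alongside the machine-learning ranking:
two-tailed Welch t tests with confidence intervals and Bonferroni
correction, log2 fold changes, univariate logistic regression, sequential
(forward / backward / floating-forward) multivariate logistic selection
driven by likelihood-ratio tests, and ridge-penalized logistic regression
whose standardized coefficient signs define the reported direction of
effect (positive = higher concentration raises the predicted probability
of being a case).

All group differences are reported with the case - control convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV, Ridge
from sklearn.model_selection import StratifiedKFold

from .core import LipidDataError


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_a: float
    mean_b: float
    conf: float

    @property
    def diff(self) -> float:
        return self.mean_a - self.mean_b


def welch_test(a, b, conf: float = 0.95) -> WelchResult:
    """Two-tailed Welch t test (unequal variances) with Satterthwaite df.

    Returns the test alongside a symmetric ``conf``-level confidence
    interval for the mean difference a - b.  Missing values are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise LipidDataError("each group needs at least 2 non-missing values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0 and vb == 0:
        if ma == mb:
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0,
                               0.0, 0.0, ma, mb, conf)
        raise LipidDataError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(conf)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue),
                       float(ci.low), float(ci.high), float(ma), float(mb), conf)


def bonferroni_threshold(alpha: float, m: int, digits: int | None = 2) -> float:
    """Per-test threshold alpha / m, rounded to ``digits`` significant
    digits as printed in report tables (``digits=None`` for the raw value)."""
    if m < 1:
        raise LipidDataError("m must be >= 1")
    thr = alpha / m
    if digits is None:
        return thr
    return float(f"{thr:.{digits - 1}e}")


def log2_fold_change(case, control) -> float:
    """log2 of the ratio of group means (case over control)."""
    mc = float(np.nanmean(np.asarray(case, dtype=float)))
    mn = float(np.nanmean(np.asarray(control, dtype=float)))
    if mc <= 0 or mn <= 0:
        raise LipidDataError("fold change needs positive group means")
    return float(np.log2(mc / mn))


@dataclass(frozen=True)
class UnivariateLogisticResult:
    coef: float
    se: float | None
    p: float | None
    separated: bool


def univariate_logistic(feature, labels) -> UnivariateLogisticResult:
    """Single-predictor logistic regression with Wald p-value.

    Perfect separation (the feature splits the groups exactly) is flagged
    and no p-value is reported, since the MLE diverges.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise LipidDataError("both outcome levels must be present")
    # monotone separation check for a single predictor
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        sign = 1.0 if x[y == 1].min() > x[y == 0].max() else -1.0
        return UnivariateLogisticResult(sign * np.inf, None, None, True)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
    if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 1e6:
        return UnivariateLogisticResult(float(fit.params[1]), None, None, True)
    return UnivariateLogisticResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), False
    )


# ---------------------------------------------------------------------------
# Sequential multivariate logistic selection


def _logit_llf(X: pd.DataFrame, y: np.ndarray, cols: tuple[str, ...]) -> float:
    """Log-likelihood of the logistic model on the given columns
    (intercept-only when cols is empty)."""
    if not cols:
        p = y.mean()
        n1 = int(y.sum())
        n0 = len(y) - n1
        return float(n1 * np.log(p) + n0 * np.log(1 - p))
    design = sm.add_constant(X[list(cols)].to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200,
                                          warn_convergence=False)
            if np.isfinite(fit.llf):
                return float(fit.llf)
        except Exception:
            pass
        # separation or singular design: a near-unpenalized ridge fit keeps
        # the step well-defined and deterministic
        clf = LogisticRegression(C=1e4, max_iter=5000)
        clf.fit(X[list(cols)].to_numpy(), y)
        proba = np.clip(clf.predict_proba(X[list(cols)].to_numpy())[:, 1],
                        1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(proba) + (1 - y) * np.log(1 - proba)))


def _lr_pvalue(llf_big: float, llf_small: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (llf_big - llf_small))
    return float(sps.chi2.sf(lr, df))


@dataclass
class SelectionStep:
    action: str  # 'add' | 'remove'
    feature: str
    p: float
    llf_before: float
    llf_after: float
    selected_after: tuple[str, ...]


@dataclass
class SequentialSelectionResult:
    method: str
    selected: list[str]
    steps: list[SelectionStep] = field(default_factory=list)
    feature_stats: pd.DataFrame | None = None  # final-model Wald stats


def _final_stats(X: pd.DataFrame, y: np.ndarray,
                 selected: list[str]) -> pd.DataFrame | None:
    if not selected:
        return None
    design = sm.add_constant(X[selected].to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200,
                                          warn_convergence=False)
        except Exception:
            return None
    return pd.DataFrame({
        "feature": selected,
        "coef": fit.params[1:],
        "se": fit.bse[1:],
        "p": fit.pvalues[1:],
    })


def sequential_logistic_selection(
    X: pd.DataFrame,
    labels,
    method: str = "SFS",
    enter_p: float = 0.05,
    remove_p: float = 0.10,
) -> SequentialSelectionResult:
    """Stepwise logistic selection driven by likelihood-ratio tests.

    SFS greedily adds the candidate with the smallest LR p-value while it is
    below ``enter_p``.  SBS starts from the full model and removes the least
    significant feature while its p-value exceeds ``remove_p``.  SFFS adds
    like SFS but after every addition floats: it re-tests the included
    features and drops any that have become dispensable.  Ties are broken by
    column order; the full step log is returned so every decision can be
    replayed.
    """
    y = np.asarray(labels, dtype=int)
    if X.shape[1] < 2:
        raise LipidDataError("need at least 2 candidate features")
    if method not in ("SFS", "SBS", "SFFS"):
        raise LipidDataError(f"unknown method {method!r}")
    cols = list(X.columns)
    steps: list[SelectionStep] = []

    def try_add(selected: list[str]) -> bool:
        llf0 = _logit_llf(X, y, tuple(selected))
        best = None
        for c in cols:
            if c in selected:
                continue
            llf1 = _logit_llf(X, y, tuple(selected + [c]))
            p = _lr_pvalue(llf1, llf0)
            if best is None or p < best[0] - 1e-12:
                best = (p, c, llf1)
        if best is not None and best[0] < enter_p:
            p, c, llf1 = best
            selected.append(c)
            steps.append(SelectionStep("add", c, p, llf0, llf1, tuple(selected)))
            return True
        return False

    def try_remove(selected: list[str], protect: str | None = None) -> bool:
        llf0 = _logit_llf(X, y, tuple(selected))
        worst = None
        for c in selected:
            if c == protect:
                continue
            rest = tuple(f for f in selected if f != c)
            llf1 = _logit_llf(X, y, rest)
            p = _lr_pvalue(llf0, llf1)
            if worst is None or p > worst[0] + 1e-12:
                worst = (p, c, llf1)
        if worst is not None and worst[0] > remove_p:
            p, c, llf1 = worst
            selected.remove(c)
            steps.append(SelectionStep("remove", c, p, llf0, llf1,
                                       tuple(selected)))
            return True
        return False

    selected: list[str]
    if method == "SBS":
        selected = list(cols)
        while len(selected) > 1 and try_remove(selected):
            pass
    else:
        selected = []
        while try_add(selected):
            if method == "SFFS" and len(selected) > 2:
                just_added = selected[-1]
                while len(selected) > 2 and try_remove(selected,
                                                       protect=just_added):
                    pass
    return SequentialSelectionResult(method, selected, steps,
                                     _final_stats(X, y, selected))


def replay_steps(X: pd.DataFrame, labels,
                 result: SequentialSelectionResult) -> bool:
    """Re-score every logged step; True if all recorded log-likelihoods and
    p-values reproduce (the audit-trail contract)."""
    y = np.asarray(labels, dtype=int)
    for step in result.steps:
        after = step.selected_after
        if step.action == "add":
            before = tuple(f for f in after if f != step.feature)
            llf_b, llf_a = _logit_llf(X, y, before), _logit_llf(X, y, after)
            p = _lr_pvalue(llf_a, llf_b)
        else:
            before = after + (step.feature,)
            # recorded llf_before is for the pre-removal model
            llf_b = _logit_llf(X, y, tuple(step.selected_after) + (step.feature,))
            llf_a = _logit_llf(X, y, after)
            p = _lr_pvalue(llf_b, llf_a)
        if not (np.isclose(llf_b, step.llf_before, atol=1e-6)
                and np.isclose(llf_a, step.llf_after, atol=1e-6)
                and np.isclose(p, step.p, atol=1e-9)):
            return False
    return True


# ---------------------------------------------------------------------------
# Ridge direction of effect


@dataclass
class DirectionResult:
    table: pd.DataFrame  # feature, coef (standardized scale), direction
    penalty: float
    model: str  # 'logistic' | 'linear'

    def direction_of(self, feature: str) -> str:
        row = self.table.loc[self.table["feature"] == feature]
        if row.empty:
            raise KeyError(feature)
        return row["direction"].iloc[0]


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = sd.replace(0, 1.0)  # zero-variance column stays zero after centering
    return (X - mu) / sd


def ridge_direction(
    X: pd.DataFrame,
    labels,
    penalty: float | None = None,
    model: str = "logistic",
    seed: int = 0,
) -> DirectionResult:
    """Direction of effect from ridge-penalized regression.

    Features are standardized (zero mean, unit variance) so coefficient
    signs are comparable across concentration scales.  By default a
    penalized logistic model is fit with the penalty chosen by 5-fold
    cross-validated deviance; pass ``penalty`` to fix it, or
    ``model='linear'`` for ridge least squares on the 0/1 outcome.
    Positive means higher values raise the predicted case probability;
    an exactly-zero coefficient is reported as indeterminate.
    """
    y = np.asarray(labels, dtype=int)
    Xs = _standardize(X)
    if model == "linear":
        alpha = penalty if penalty is not None else 1.0
        fit = Ridge(alpha=alpha)
        fit.fit(Xs, y)
        coefs, used_penalty = fit.coef_.ravel(), alpha
    elif model == "logistic":
        if penalty is not None:
            if penalty <= 0:
                raise LipidDataError("penalty must be positive")
            clf = LogisticRegression(C=1.0 / penalty, max_iter=5000)
            clf.fit(Xs, y)
            coefs, used_penalty = clf.coef_.ravel(), penalty
        else:
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            clf = LogisticRegressionCV(
                Cs=np.logspace(-3, 3, 13), cv=cv,
                scoring="neg_log_loss", max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(Xs, y)
            coefs, used_penalty = clf.coef_.ravel(), float(1.0 / clf.C_[0])
    else:
        raise LipidDataError(f"unknown model {model!r}")
    direction = np.where(coefs > 0, "Positive",
                         np.where(coefs < 0, "Negative", "indeterminate"))
    table = pd.DataFrame({"feature": X.columns, "coef": coefs,
                          "direction": direction})
    return DirectionResult(table, float(used_penalty), model)
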