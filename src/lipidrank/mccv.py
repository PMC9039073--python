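"""Monte-Carlo cross-validated random-forest evaluation and variable ranking.

The evaluation scheme is repeated random subsampling: in each repetition a
fraction of subjects (default 20%) is held out for testing; the remaining
training subjects are further split 80:20 into an inner training and
validation set used to tune the forest's hyperparameters by validation AUC.
The tuned configuration is refit on the full outer training set and scored
on the held-out test set.  Metrics (accuracy, TPR, TNR, AUC, case = positive
class) and normalized impurity-decrease importances are averaged across
repetitions.  With the small cohorts this design targets (tens of subjects),
stratified subsampling is the default so every set contains both groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .core import FeatureTable, LipidDataError


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters exposed to tuning."""

    n_estimators: int = 200
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )


def default_grid() -> list[RFConfig]:
    """Trees {200, 500} x features-per-split {sqrt(p), p/3} x min-leaf {1, 5}."""
    return [
        RFConfig(n_estimators=t, max_features=mf, min_samples_leaf=leaf)
        for t in (200, 500)
        for mf in ("sqrt", 1 / 3)
        for leaf in (1, 5)
    ]


def fast_grid() -> list[RFConfig]:
    """Single moderate configuration for quick simulation studies."""
    return [RFConfig(n_estimators=100)]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitRep:
    train: np.ndarray
    test: np.ndarray
    inner_train: np.ndarray
    inner_val: np.ndarray


@dataclass
class SplitPlan:
    reps: list[SplitRep]
    seed: int
    n: int

    @property
    def n_reps(self) -> int:
        return len(self.reps)


def _stratified_pick(labels: np.ndarray, idx: np.ndarray, n_pick: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Pick n_pick of idx with per-group counts proportional to group sizes
    (largest-remainder apportionment)."""
    groups = np.unique(labels[idx])
    quotas = {g: (labels[idx] == g).sum() * n_pick / len(idx) for g in groups}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = n_pick - sum(counts.values())
    for g in sorted(groups, key=lambda g: quotas[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    picked = []
    for g in groups:
        pool = idx[labels[idx] == g]
        picked.append(rng.choice(pool, size=counts[g], replace=False))
    return np.sort(np.concatenate(picked))


def make_split_plan(
    labels: np.ndarray,
    n_reps: int = 200,
    test_frac: float = 0.2,
    inner_frac: float = 0.2,
    stratify: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Draw the repeated train/test (and inner train/validation) partitions.

    Test size is round(test_frac * n); every one of the four sets must
    contain both outcome levels.  Repetition r uses its own generator seeded
    ``seed + r``, so plans are reproducible rep-for-rep.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_reps < 1 or not 0 < test_frac < 1 or not 0 < inner_frac < 1:
        raise LipidDataError("invalid split parameters")
    n_test = max(1, _round_half_up(test_frac * n))
    counts = pd.Series(labels).value_counts()
    if counts.min() < 3:
        raise LipidDataError(
            "a group is too small to appear in every train/validation/test "
            "set; enlarge the cohort or reduce the number of repetitions"
        )
    all_idx = np.arange(n)
    reps = []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        for _attempt in range(100):
            if stratify:
                test = _stratified_pick(labels, all_idx, n_test, rng)
            else:
                test = np.sort(rng.choice(all_idx, size=n_test, replace=False))
            train = np.setdiff1d(all_idx, test)
            n_val = max(1, _round_half_up(inner_frac * len(train)))
            if stratify:
                inner_val = _stratified_pick(labels, train, n_val, rng)
            else:
                inner_val = np.sort(rng.choice(train, size=n_val, replace=False))
            inner_train = np.setdiff1d(train, inner_val)
            sets = (train, test, inner_train, inner_val)
            if all(len(np.unique(labels[s])) == 2 for s in sets):
                reps.append(SplitRep(train, test, inner_train, inner_val))
                break
        else:
            raise LipidDataError(
                f"could not draw a valid split at repetition {r}; "
                "try stratify=True or a larger cohort"
            )
    return SplitPlan(reps, seed, n)


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count one half."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y_true == 1).sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise LipidDataError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks resolve ties at one half
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _metrics(y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5) -> dict:
    pred = (proba >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y_true),
        "tpr": tp / (tp + fn) if tp + fn else np.nan,
        "tnr": tn / (tn + fp) if tn + fp else np.nan,
        "auc": auc_score(y_true, proba),
    }


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: list[RFConfig],
    inner_train: np.ndarray,
    inner_val: np.ndarray,
    seed: int = 0,
) -> RFConfig:
    """Pick the grid configuration with the best validation AUC.

    Ties are broken by validation accuracy, then by grid order.  If the
    validation set degenerates to one class the choice falls back to the
    inner-train out-of-bag score.
    """
    if not grid:
        raise LipidDataError("hyperparameter grid is empty")
    if len(grid) == 1:
        return grid[0]
    Xi, yi = X.iloc[inner_train], y[inner_train]
    Xv, yv = X.iloc[inner_val], y[inner_val]
    degenerate = len(np.unique(yv)) < 2
    if degenerate:
        warnings.warn("single-class validation set; tuning by OOB score",
                      stacklevel=2)
    best = None
    for order, cfg in enumerate(grid):
        if degenerate:
            clf = cfg.build(seed)
            clf.set_params(oob_score=True, bootstrap=True)
            clf.fit(Xi, yi)
            key = (clf.oob_score_, 0.0, -order)
        else:
            clf = cfg.build(seed)
            clf.fit(Xi, yi)
            proba = clf.predict_proba(Xv)[:, list(clf.classes_).index(1)]
            m = _metrics(yv, proba)
            key = (m["auc"], m["accuracy"], -order)
        if best is None or key > best[0]:
            best = (key, cfg)
    return best[1]


@dataclass
class MCCVReport:
    """Per-repetition and aggregate classification metrics plus the
    aggregated variable-importance ranking."""

    per_rep: pd.DataFrame  # columns rep, accuracy, tpr, tnr, auc, config
    importance: pd.DataFrame | None = None  # feature, mean_importance, mean_rank
    features: list[str] = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {k: float(self.per_rep[k].mean())
                for k in ("accuracy", "tpr", "tnr", "auc")}

    def to_dict(self) -> dict:
        out = {"mean": self.mean_metrics,
               "n_reps": int(len(self.per_rep)),
               "features": self.features}
        if self.importance is not None:
            out["importance"] = self.importance.to_dict(orient="records")
        return out


def _run_reps(ft: FeatureTable, plan: SplitPlan, grid: list[RFConfig],
              collect_importance: bool) -> MCCVReport:
    X, y = ft.X, ft.y
    if plan.n != len(y):
        raise LipidDataError("split plan subjects do not match feature table")
    zero_var = X.columns[X.std(axis=0) == 0].tolist()
    if zero_var:
        warnings.warn(f"zero-variance features retained: {zero_var[:5]}",
                      stacklevel=3)
    rows = []
    importances = np.zeros((plan.n_reps, X.shape[1]))
    ranks = np.zeros_like(importances)
    for r, rep in enumerate(plan.reps):
        rep_seed = plan.seed + r
        cfg = tune_hyperparameters(X, y, grid, rep.inner_train, rep.inner_val,
                                   seed=rep_seed)
        clf = cfg.build(rep_seed)
        clf.fit(X.iloc[rep.train], y[rep.train])
        proba = clf.predict_proba(X.iloc[rep.test])[:, list(clf.classes_).index(1)]
        m = _metrics(y[rep.test], proba)
        rows.append({"rep": r, **m, **asdict(cfg)})
        if collect_importance:
            imp = clf.feature_importances_
            total = imp.sum()
            imp = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))
            importances[r] = imp
            ranks[r] = rankdata(-imp)
    per_rep = pd.DataFrame(rows)
    importance = None
    if collect_importance:
        importance = pd.DataFrame({
            "feature": X.columns,
            "mean_importance": importances.mean(axis=0),
            "mean_rank": ranks.mean(axis=0),
        }).sort_values(
            ["mean_importance", "mean_rank", "feature"],
            ascending=[False, True, True],
        ).reset_index(drop=True)
    return MCCVReport(per_rep, importance, features=X.columns.tolist())


def evaluate_classifier(
    ft: FeatureTable, plan: SplitPlan, grid: list[RFConfig] | None = None
) -> MCCVReport:
    """Tune, refit and score the forest over every repetition of the plan."""
    return _run_reps(ft, plan, grid or default_grid(), collect_importance=False)


def rank_variables(
    ft: FeatureTable, plan: SplitPlan, grid: list[RFConfig] | None = None
) -> MCCVReport:
    """Evaluate and aggregate normalized impurity-decrease importances.

    Per repetition the importances are normalized to sum to one, then
    averaged; the ranking table is sorted by mean importance (ties broken by
    mean rank, then name) and includes the covariate columns.
    """
    return _run_reps(ft, plan, grid or default_grid(), collect_importance=True)
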