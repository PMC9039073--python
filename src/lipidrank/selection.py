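"""Two-stage hierarchical feature selection: classes first, then species.

Stage 1 ranks the lipid classes (plus age and sex) by Monte-Carlo
cross-validated random-forest importance and scans top-fractions of the
ranking, keeping the fraction with the best mean AUC.  Stage 2 selects
species either from the full panel (method 1) or restricted to the species
of the stage-1 winning classes (method 2), scanning a grid of top-k sizes.
Covariates always accompany the lipid features in the fitted models.  Every
scan is reported in full so the size choice is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureTable, LipidDataError, LipidTaxonomy
from .mccv import MCCVReport, RFConfig, SplitPlan, evaluate_classifier, rank_variables

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
DEFAULT_K_GRID = tuple(range(5, 26))


@dataclass
class SelectionResult:
    """Outcome of one selection stage: the chosen features, the metrics at
    that choice, and the full size-vs-metrics scan table."""

    stage: str  # 'class' | 'species_m1' | 'species_m2'
    selected: list[str]
    report: MCCVReport
    scan: pd.DataFrame  # one row per scanned size/fraction
    ranking: pd.DataFrame  # full importance ranking the scan was based on
    candidate_pool: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "selected": self.selected,
            "size": self.size,
            "candidate_pool": self.candidate_pool,
            "metrics": self.report.mean_metrics,
            "scan": self.scan.to_dict(orient="records"),
            **self.extras,
        }


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def select_top_fraction(
    ranking: pd.DataFrame, fraction: float, exclude_covariates: bool = True,
    covariates: tuple[str, ...] = ("age", "sex_female"),
) -> list[str]:
    """Top round(fraction * p) lipid features from a ranking table.

    ``ranking`` is sorted descending with a ``feature`` column.  Covariates
    are excluded from both the candidate list and the count p when flagged.
    At least one feature is always returned.  Rounding is half-away-from-zero
    (so 30% of 34 classes is 10, and half of 7 candidates is 4).
    """
    if not 0 < fraction <= 1:
        raise LipidDataError("fraction must be in (0, 1]")
    feats = ranking["feature"].tolist()
    if exclude_covariates:
        feats = [f for f in feats if f not in covariates]
    k = max(1, _round_half_away(fraction * len(feats)))
    return feats[:k]


def _best_row(scan: pd.DataFrame) -> int:
    """Index of the scan row with the best mean AUC; ties go to the smaller
    feature-set size, then to scan order."""
    best = scan["auc"].max()
    tied = scan[scan["auc"] == best]
    return int(tied["size"].idxmin())


def stage1_select_classes(
    class_ft: FeatureTable,
    plan: SplitPlan,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    grid: list[RFConfig] | None = None,
) -> SelectionResult:
    """Rank all classes, then keep the top-fraction with the best mean AUC."""
    if not fractions:
        raise LipidDataError("empty fraction grid")
    ranked = rank_variables(class_ft, plan, grid)
    rows, selections = [], {}
    for frac in fractions:
        selected = select_top_fraction(ranked.importance, frac,
                                       covariates=tuple(class_ft.covariates))
        key = tuple(selected)
        if key in selections:  # identical set already scored (small p)
            rep = selections[key]
        else:
            rep = evaluate_classifier(class_ft.subset(selected), plan, grid)
            selections[key] = rep
        rows.append({"fraction": frac, "size": len(selected),
                     **rep.mean_metrics})
    scan = pd.DataFrame(rows)
    best = _best_row(scan)
    best_sel = select_top_fraction(ranked.importance, scan.loc[best, "fraction"],
                                   covariates=tuple(class_ft.covariates))
    return SelectionResult(
        stage="class",
        selected=best_sel,
        report=selections[tuple(best_sel)],
        scan=scan,
        ranking=ranked.importance,
        candidate_pool=len(class_ft.lipid_features),
        extras={"best_fraction": float(scan.loc[best, "fraction"])},
    )


def _scan_top_k(
    ft: FeatureTable, stage: str, plan: SplitPlan, k_grid: tuple[int, ...],
    grid: list[RFConfig] | None,
) -> SelectionResult:
    ranked = rank_variables(ft, plan, grid)
    candidates = [f for f in ranked.importance["feature"]
                  if f not in ft.covariates]
    if not k_grid:
        raise LipidDataError("empty k grid")
    bad = [k for k in k_grid if not 1 <= k <= len(candidates)]
    if bad:
        raise LipidDataError(f"k values out of range [1, {len(candidates)}]: {bad}")
    rows, selections = [], {}
    for k in sorted(set(k_grid)):
        selected = candidates[:k]
        rep = evaluate_classifier(ft.subset(selected), plan, grid)
        selections[k] = (selected, rep)
        rows.append({"k": k, "size": k, **rep.mean_metrics})
    scan = pd.DataFrame(rows)
    best = _best_row(scan)
    best_k = int(scan.loc[best, "k"])
    selected, rep = selections[best_k]
    return SelectionResult(
        stage=stage,
        selected=selected,
        report=rep,
        scan=scan,
        ranking=ranked.importance,
        candidate_pool=len(candidates),
        extras={"best_k": best_k},
    )


def stage2_method1(
    species_ft: FeatureTable,
    plan: SplitPlan,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    grid: list[RFConfig] | None = None,
) -> SelectionResult:
    """Method 1: rank every species in the panel and scan top-k models
    (top-k species plus age and sex)."""
    return _scan_top_k(species_ft, "species_m1", plan, k_grid, grid)


def stage2_method2(
    species_ft: FeatureTable,
    top_classes: list[str],
    tax: LipidTaxonomy,
    plan: SplitPlan,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    grid: list[RFConfig] | None = None,
) -> SelectionResult:
    """Method 2: restrict candidates to species of the winning classes
    before ranking and scanning top-k models."""
    if not top_classes:
        raise LipidDataError("top_classes must be non-empty")
    pool = [s for s in species_ft.lipid_features
            if tax.class_of.get(s) in set(top_classes)]
    if not pool:
        raise LipidDataError("no species belong to the given classes")
    restricted = species_ft.subset(pool)
    k_grid = tuple(k for k in k_grid if k <= len(pool)) or (len(pool),)
    result = _scan_top_k(restricted, "species_m2", plan, k_grid, grid)
    result.extras["top_classes"] = list(top_classes)
    return result
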