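"""Internal-standard normalization by optimal multiple-IS regression (NOMIS).

Technical variation shared between spiked internal standards (IS) and
analyte peaks is removed by regressing each centered log-peak on the
centered log-intensities of an optimally chosen IS subset.  The subset is
selected by exhaustive search up to ``max_subset`` standards, minimizing the
mean leave-one-out residual variance across features — an honest estimate of
out-of-sample technical variance that guards against overfitting small IS
panels.  All computation is on the natural-log scale; normalized output is
exponentiated back to linear concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, LipidDataError


@dataclass
class NomisModel:
    subset: list[str]
    coefficients: pd.DataFrame  # features x selected IS
    feature_means: pd.Series
    is_means: pd.Series  # training means of the selected IS columns
    criterion: dict[tuple[str, ...], float]  # per candidate subset, for audit
    warnings: list[str] = field(default_factory=list)

    @property
    def is_identity(self) -> bool:
        return not self.subset


def _loo_mean_sq(Z: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of each column of Y on Z (both centered); returns coefficients and
    the mean leave-one-out squared residual across all features."""
    n = Z.shape[0]
    G = np.linalg.pinv(Z.T @ Z)
    B = G @ Z.T @ Y
    E = Y - Z @ B
    # hat diagonal includes the implicit intercept from centering
    h = 1.0 / n + np.einsum("ij,jk,ik->i", Z, G, Z)
    h = np.clip(h, None, 1 - 1e-10)
    E_loo = E / (1 - h)[:, None]
    return B, float(np.nanmean(E_loo**2))


def fit_nomis(
    raw_log: pd.DataFrame, is_log: pd.DataFrame, max_subset: int = 5
) -> NomisModel:
    """Select the IS subset minimizing leave-one-out residual variance.

    Candidate subsets are every combination of the usable (non-constant)
    standards up to ``max_subset``, including the empty subset (centering
    only, i.e. no normalization) so that standards carrying no shared
    technical variance are rejected rather than fit to noise.  Per subset,
    each feature gets its own least-squares slope vector; the selection
    criterion is the mean leave-one-out squared residual pooled over
    features.
    """
    if not raw_log.index.equals(is_log.index):
        raise LipidDataError("raw and IS tables must cover the same samples")
    n = len(raw_log)
    if n < 3:
        raise LipidDataError("need at least 3 samples to fit")
    if max_subset > is_log.shape[1]:
        raise LipidDataError("max_subset exceeds the number of internal standards")

    warns: list[str] = []
    usable = []
    for col in is_log.columns:
        if np.nanstd(is_log[col].to_numpy()) == 0:
            msg = f"internal standard {col!r} is constant; excluded"
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
        else:
            usable.append(col)

    feat_means = raw_log.mean(axis=0, skipna=True)
    if not usable:
        msg = "all internal standards constant; returning identity model"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
        return NomisModel([], pd.DataFrame(index=raw_log.columns), feat_means,
                          pd.Series(dtype=float), {}, warns)

    Yfull = (raw_log - feat_means).to_numpy()
    has_nan = np.isnan(Yfull).any()
    is_means = is_log[usable].mean(axis=0)
    Zfull = (is_log[usable] - is_means).to_numpy()

    criterion: dict[tuple[str, ...], float] = {}
    # the empty subset (centering only, i.e. no normalization) competes too,
    # so useless standards are rejected rather than fit to noise
    n_eff = (~np.isnan(Yfull)).sum(axis=0) if has_nan else n
    loo0 = Yfull * (n_eff / np.maximum(n_eff - 1, 1))
    criterion[()] = float(np.nanmean(loo0**2))
    best: tuple[float, tuple[str, ...], np.ndarray] | None = (
        criterion[()], (), np.zeros((0, Yfull.shape[1])))
    for k in range(1, max_subset + 1):
        for subset in combinations(usable, k):
            idx = [usable.index(s) for s in subset]
            Z = Zfull[:, idx]
            if has_nan:
                # per-feature masked fit for features with missing cells
                B = np.zeros((len(subset), Yfull.shape[1]))
                sq, cnt = 0.0, 0
                for j in range(Yfull.shape[1]):
                    y = Yfull[:, j]
                    ok = ~np.isnan(y)
                    if ok.sum() < len(subset) + 2:
                        continue
                    Bj, crit_j = _loo_mean_sq(Z[ok], y[ok, None])
                    B[:, j] = Bj[:, 0]
                    sq += crit_j
                    cnt += 1
                crit = sq / max(cnt, 1)
            else:
                B, crit = _loo_mean_sq(Z, Yfull)
            criterion[subset] = crit
            if best is None or crit < best[0]:
                best = (crit, subset, B)

    _, subset, B = best
    coef = pd.DataFrame(B.T, index=raw_log.columns, columns=list(subset))
    return NomisModel(list(subset), coef, feat_means, is_means[list(subset)],
                      criterion, warns)


def apply_nomis(
    model: NomisModel, raw_log: pd.DataFrame, is_log: pd.DataFrame | None = None
) -> AbundanceMatrix:
    """Remove the fitted IS component and return linear-scale concentrations.

    normalized log-value = raw log-value - sum_j coef_j * (IS_j - training mean)

    Missing raw entries stay missing; a sample lacking a required IS
    measurement has all its features flagged missing.
    """
    if is_log is None:
        # the model's IS columns may ride along inside the raw table
        missing_cols = [s for s in model.subset if s not in raw_log.columns]
        if missing_cols:
            raise LipidDataError(f"raw table lacks IS columns: {missing_cols}")
        is_log = raw_log[model.subset]
        raw_log = raw_log.drop(columns=model.subset)

    if model.is_identity:
        return AbundanceMatrix(np.exp(raw_log), level="species")

    Zc = is_log[model.subset] - model.is_means
    adjustment = Zc.to_numpy() @ model.coefficients.loc[raw_log.columns].to_numpy().T
    norm_log = raw_log - pd.DataFrame(adjustment, index=raw_log.index,
                                      columns=raw_log.columns)
    bad_sample = Zc.isna().any(axis=1)
    norm_log[bad_sample] = np.nan
    return AbundanceMatrix(np.exp(norm_log), level="species")
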