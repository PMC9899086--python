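"""Design-matrix linear model for ring-neuron subtype contributions.

Each GAL4 driver labels a combination of ellipsoid-body ring-neuron
subtypes (the canonical eleven: R1, R2, R3a, R3d, R3m, R3p, R3w, R4d, R4m,
R5, R6), encoded as a 0/1 row of a drivers x subtypes design matrix.  The
response is the driver's mean change rate of a sleep parameter,
(activation − baseline)/baseline.  An ordinary least-squares fit with an
intercept (the identity-link, normal-error GLM) yields one weight per
subtype; a subtype is called sleep-promoting (positive) or wake-promoting
(negative) for a parameter when its weight has that sign with p < α on a
two-sided t test.  Raw p-values are reported (no cross-subtype correction
by default, with an optional Benjamini–Hochberg adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

CANONICAL_SUBTYPES = (
    "R1", "R2", "R3a", "R3d", "R3m", "R3p", "R3w", "R4d", "R4m", "R5", "R6",
)


@dataclass
class SubtypeDesign:
    """Binary driver x subtype membership matrix."""

    X: pd.DataFrame  # index = drivers, columns = subtypes, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("design entries must be 0 or 1")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate subtype column names")
        if self.X.index.duplicated().any():
            raise ValueError("duplicate driver names")

    @property
    def drivers(self) -> list[str]:
        return list(self.X.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.X.columns)

    @classmethod
    def from_csv(cls, path) -> "SubtypeDesign":
        return cls(pd.read_csv(path, index_col=0))


def _independent_columns(M: np.ndarray) -> list[int]:
    """Greedy earliest-first maximal set of linearly independent columns."""
    kept: list[int] = []
    for j in range(M.shape[1]):
        trial = M[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
    return kept


class SubtypeEffectsGLM(RegressorMixin, BaseEstimator):
    """OLS of driver change rates on binary subtype membership.

    Parameters
    ----------
    alpha : float, significance level for effect classification.
    adjust : {"none", "fdr_bh"}, p-value adjustment across subtypes.

    Attributes
    ----------
    intercept_ : float
    coef_ : pd.Series, weight per subtype (NaN for dropped columns)
    bse_, tvalues_, pvalues_ : pd.Series aligned with coef_
    df_resid_ : int
    dropped_columns_ : list of subtype names dropped for exact collinearity
    results_ : the underlying statsmodels RegressionResults
    """

    def __init__(self, alpha: float = 0.05, adjust: str = "none"):
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, X, y):
        if isinstance(X, SubtypeDesign):
            X = X.X
        X = pd.DataFrame(X)
        if not np.isin(X.to_numpy(), (0, 1)).all():
            raise ValueError("design entries must be 0 or 1")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError(f"y has {len(y)} entries for {len(X)} drivers")
        if not np.isfinite(y).all():
            raise ValueError("y must be finite")
        names = list(X.columns)
        full = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        kept = _independent_columns(full)
        if 0 not in kept:  # intercept always retained (it is column 0, rank 1)
            raise AssertionError("intercept unexpectedly dropped")
        kept_sub = [j - 1 for j in kept if j > 0]
        self.dropped_columns_ = [names[j] for j in range(len(names)) if j not in kept_sub]
        if self.dropped_columns_:
            warnings.warn(
                f"dropping exactly collinear columns: {self.dropped_columns_}",
                UserWarning,
                stacklevel=2,
            )
        design = full[:, kept]
        if len(y) <= design.shape[1]:
            raise ValueError(
                f"no residual degrees of freedom: n={len(y)}, "
                f"retained columns (with intercept)={design.shape[1]}"
            )
        cond = np.linalg.cond(design)
        if cond > 1e8:
            warnings.warn(
                f"design condition number {cond:.2e} > 1e8; estimates unstable",
                UserWarning,
                stacklevel=2,
            )
        res = sm.OLS(y, design).fit()
        self.results_ = res
        self.intercept_ = float(res.params[0])
        idx = pd.Index(names, name="subtype")
        for attr, vals in (
            ("coef_", res.params[1:]),
            ("bse_", res.bse[1:]),
            ("tvalues_", res.tvalues[1:]),
            ("pvalues_", res.pvalues[1:]),
        ):
            s = pd.Series(np.nan, index=idx)
            s.iloc[kept_sub] = vals
            setattr(self, attr, s)
        if self.adjust == "fdr_bh":
            mask = self.pvalues_.notna()
            adj = self.pvalues_.copy()
            adj[mask] = multipletests(self.pvalues_[mask], method="fdr_bh")[1]
            self.pvalues_adj_ = adj
        elif self.adjust == "none":
            self.pvalues_adj_ = self.pvalues_
        else:
            raise ValueError(f"unknown adjust {self.adjust!r}")
        self.df_resid_ = int(res.df_resid)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, SubtypeDesign):
            X = X.X
        X = pd.DataFrame(X)
        coef = self.coef_.fillna(0.0).to_numpy()
        return self.intercept_ + X.to_numpy(dtype=float) @ coef

    def classify_effects(self, alpha: float | None = None) -> pd.Series:
        check_is_fitted(self, "coef_")
        return classify_effects(self.coef_, self.pvalues_adj_, alpha or self.alpha)


def classify_effects(
    weights: pd.Series, pvalues: pd.Series, alpha: float = 0.05
) -> pd.Series:
    """Sign-and-significance call per subtype: positive / negative / none."""
    out = pd.Series("none", index=weights.index, dtype=object)
    sig = (pvalues < alpha) & weights.notna()
    out[sig & (weights > 0)] = "positive"
    out[sig & (weights < 0)] = "negative"
    return out


def fit_subtype_glm(design: SubtypeDesign | pd.DataFrame, y, **kwargs) -> SubtypeEffectsGLM:
    """Thin functional wrapper over :class:`SubtypeEffectsGLM`."""
    return SubtypeEffectsGLM(**kwargs).fit(design, y)


def glm_table(
    design: SubtypeDesign | pd.DataFrame,
    change_rates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit one GLM per (parameter, phase) and tabulate weight, p and effect call.

    ``change_rates`` has columns driver, parameter, phase, value (one row per
    driver per parameter per phase); drivers with undefined values for a
    response are dropped from that fit.
    """
    X = design.X if isinstance(design, SubtypeDesign) else pd.DataFrame(design)
    records = []
    for (parameter, phase), grp in change_rates.groupby(["parameter", "phase"]):
        yser = grp.set_index("driver")["value"].reindex(X.index)
        ok = yser.notna()
        est = SubtypeEffectsGLM(alpha=alpha).fit(X.loc[ok], yser[ok].to_numpy())
        calls = est.classify_effects()
        for subtype in X.columns:
            records.append(
                {
                    "parameter": parameter,
                    "phase": phase,
                    "subtype": subtype,
                    "weight": est.coef_[subtype],
                    "p": est.pvalues_[subtype],
                    "effect": calls[subtype],
                    "n_drivers": int(ok.sum()),
                }
            )
    return pd.DataFrame.from_records(records)
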