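"""Association statistics: OLS, stepwise screening, group tests, ES model
comparison.

Ordinary least squares goes through statsmodels; genotype predictors are
additive dosages (0/1/2 variant alleles). Stepwise selection is the
classic forward-inclusion / backward-elimination loop at a fixed p-value
threshold, iterated to a fixpoint, with ties broken by candidate input
order (the documented panel order) for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .escore import get_model, diplotype_es
from .types import Cyp2d6Error, Diplotype


class DegenerateModelError(Cyp2d6Error):
    pass


class RankDeficientError(Cyp2d6Error):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {self.columns}")


@dataclass(frozen=True)
class FitResult:
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    r_squared: float
    n: int

    def coef(self, name: str) -> float:
        return self.coefficients[name]


def _design(
    d: pd.DataFrame, response: str, predictors: Sequence[str]
) -> Tuple[np.ndarray, pd.DataFrame]:
    data = d[[response, *predictors]].dropna()
    y = data[response].to_numpy(dtype=float)
    X = data[list(predictors)].astype(float)
    return y, X


def ols_fit(
    d: pd.DataFrame, response: str, predictors: Sequence[str]
) -> FitResult:
    """OLS with intercept; two-sided t p-values; R^2 = 1 - RSS/TSS.

    Listwise deletion of missing rows; a rank-deficient design raises
    naming the collinear columns.
    """
    y, X = _design(d, response, predictors)
    if len(y) <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise RankDeficientError(bad)
    res = sm.OLS(y, Xc).fit()
    names = list(Xc.columns)
    return FitResult(
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        p_values=dict(zip(names, res.pvalues)),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    cols = list(X.columns)
    bad = []
    kept: List[str] = []
    for c in cols:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            bad.append(c)
        else:
            kept.append(c)
    return bad


def stepwise_select(
    d: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
    forced: Sequence[str] = (),
) -> List[str]:
    """Forward/backward stepwise screening at p < alpha.

    Forward step: add the candidate with the smallest p-value below alpha
    (ties by input order); backward step: drop any selected predictor whose
    p-value rises to >= alpha; iterate to a fixpoint. May select nothing.

    ``forced`` predictors are always in the model and never dropped — use
    this for a hypothesis variable whose covariates are being screened
    (forward selection alone can stall on a suppressed pair of
    negatively-linked predictors with same-sign effects).
    """
    forced = list(forced)
    selected: List[str] = []
    while True:
        changed = False
        # forward
        best, best_p = None, alpha
        for c in candidates:
            if c in selected or c in forced:
                continue
            try:
                fit = ols_fit(d, response, forced + selected + [c])
            except RankDeficientError:
                continue
            p = fit.p_values[c]
            if p < best_p:
                best, best_p = c, p
        if best is not None:
            selected.append(best)
            changed = True
        # backward
        while len(selected) > 0:
            fit = ols_fit(d, response, forced + selected)
            worst = max(selected, key=lambda c: fit.p_values[c])
            if fit.p_values[worst] >= alpha:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            return forced + selected


def group_compare(values: Sequence[float], groups: Sequence) -> float:
    """Two groups: pooled-variance two-sided t-test; more: one-way ANOVA."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g] for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if len(labels) == 2:
        return float(st.ttest_ind(arrays[0], arrays[1], equal_var=True).pvalue)
    return float(st.f_oneway(*arrays).pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise Cyp2d6Error("undefined correlation: zero variance")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def compare_es_models(
    cohort: pd.DataFrame,
    protein_col: str = "protein",
    models: Iterable[int] = (1, 2, 3),
    population_col: Optional[str] = None,
    diplotype_col: str = "diplotype",
) -> pd.DataFrame:
    """Simple regression of protein on diplotype ES, per model (and group).

    ``cohort`` needs a protein column and either precomputed ``es_model{k}``
    columns or a column of :class:`~cyp2d6es.types.Diplotype` objects to
    score. Returns one row per (model, group) with coefficient, p, R^2
    (percent) and n.
    """
    df = cohort.copy()
    for k in models:
        col = f"es_model{k}"
        if col not in df.columns:
            if diplotype_col not in df.columns:
                raise ValueError(f"missing {col} and no {diplotype_col} column")
            m = get_model(k)
            df[col] = [
                diplotype_es(d, m).diplotype_es for d in df[diplotype_col]
            ]

    groups = [("combined", df)]
    if population_col is not None:
        groups += [(str(g), sub) for g, sub in df.groupby(population_col)]

    rows = []
    for k in models:
        col = f"es_model{k}"
        for gname, sub in groups:
            if sub[col].nunique() <= 1:
                raise DegenerateModelError(
                    f"ES model {k} constant within group {gname}"
                )
            fit = ols_fit(sub, protein_col, [col])
            rows.append(
                {
                    "model": k,
                    "group": gname,
                    "coefficient": fit.coef(col),
                    "p_value": fit.p_values[col],
                    "r_squared_pct": 100.0 * fit.r_squared,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
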