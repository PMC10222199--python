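"""The multi-linear composition-effect route.

A property is modeled as a linear combination of family relative abundances
(with intercept, no interactions); model quality is the small-sample AICc and
irrelevant families are pruned by backward stepwise selection: at each round
every remaining family is tentatively removed, and the removal that most
improves (strictly decreases) the AICc is made permanent, until no removal
improves it.

The route requires more observations than variables (n > p + 1); when an
initial table violates that, the least abundant families are dropped first,
down to p = n - 2, before selection starts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import PropertyVector
from .exceptions import DegeneratePropertyError, DegreesOfFreedomError
from .model import ModelFit, SelectionStep, SelectionTrace, aicc_or_inf

__all__ = ["fit_ols", "backward_select_linear"]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def _as_y(y) -> np.ndarray:
    if isinstance(y, PropertyVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def _rss(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    """Residual sum of squares of the OLS fit on the given columns + intercept."""
    design = np.column_stack([np.ones(len(y))] + [X[:, j] for j in cols])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def fit_ols(X, y, predictor_ids: list[str] | None = None) -> ModelFit:
    """Ordinary least squares of a property on predictor columns.

    Requires n >= p + 2 so the residual degrees of freedom (and the AICc
    correction) are defined.  ``k = p + 1`` counts predictors plus intercept.
    """
    Xm, ids = _as_matrix(X)
    if predictor_ids is not None:
        ids = list(map(str, predictor_ids))
    yv = _as_y(y)
    n, p = Xm.shape
    if len(yv) != n:
        raise ValueError("X and y have different numbers of samples")
    if n < p + 2:
        raise DegreesOfFreedomError(
            f"linear route needs n > p + 1 (and one residual df): n={n}, p={p}"
        )
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0.0:
        raise DegeneratePropertyError("property is constant; R^2 undefined")

    design = sm.add_constant(Xm, has_constant="add")
    res = sm.OLS(yv, design).fit()
    rss = float(res.ssr)
    k = p + 1
    fitted = np.asarray(res.fittedvalues)
    if p >= 1:
        f_ratio = float(res.fvalue)
        coefficients = pd.Series(res.params[1:], index=ids)
        coef_pvalues = pd.Series(res.pvalues[1:], index=ids)
    else:
        f_ratio = float("nan")
        coefficients = pd.Series(dtype=float)
        coef_pvalues = pd.Series(dtype=float)
    return ModelFit(
        route="linear",
        kept=ids,
        fitted=fitted,
        r2=float(res.rsquared),
        f_ratio=f_ratio,
        aicc=aicc_or_inf(rss, n, k),
        k=k,
        df_resid=n - k,
        coefficients=coefficients,
        intercept=float(res.params[0]),
        coef_pvalues=coef_pvalues,
        extras={"rss": rss, "tss": tss},
    )


def backward_select_linear(
    X,
    y,
    predictor_ids: list[str] | None = None,
    abundance_totals: np.ndarray | None = None,
) -> SelectionTrace:
    """Backward stepwise family selection under the AICc.

    At each round, each remaining family is tentatively removed and the AICc
    of the reduced fit recomputed; the removal yielding the lowest AICc is
    accepted if it strictly improves on the current AICc, otherwise selection
    stops.  Ties are broken by family input order, so the procedure is
    deterministic.

    If the initial set violates n > p + 1, the families with the smallest
    ``abundance_totals`` (column sums of X by default) are dropped first until
    p = n - 2; they are recorded in ``trace.predropped``.
    """
    Xm, ids = _as_matrix(X)
    if predictor_ids is not None:
        ids = list(map(str, predictor_ids))
    yv = _as_y(y)
    n = Xm.shape[0]
    p_initial = Xm.shape[1]

    cols = list(range(Xm.shape[1]))
    predropped: list[str] = []
    if abundance_totals is None:
        abundance_totals = Xm.sum(axis=0)
    abundance_totals = np.asarray(abundance_totals, dtype=float)
    while len(cols) > n - 2:
        worst = min(cols, key=lambda j: (abundance_totals[j], -j))
        cols.remove(worst)
        predropped.append(ids[worst])

    current_aicc = aicc_or_inf(_rss(Xm, yv, cols), n, len(cols) + 1)
    steps: list[SelectionStep] = []
    while len(cols) > 0:
        best_j = None
        best_aicc = np.inf
        for j in cols:  # input order; first minimum wins ties
            reduced = [c for c in cols if c != j]
            a = aicc_or_inf(_rss(Xm, yv, reduced), n, len(reduced) + 1)
            if a < best_aicc:
                best_aicc = a
                best_j = j
        if best_j is None or not best_aicc < current_aicc:
            break
        cols.remove(best_j)
        steps.append(
            SelectionStep(
                removed=ids[best_j],
                aicc_before=current_aicc,
                aicc_after=best_aicc,
                n_kept=len(cols),
            )
        )
        current_aicc = best_aicc

    kept_ids = [ids[j] for j in cols]
    final = fit_ols(Xm[:, cols], yv, predictor_ids=kept_ids)
    # study-table convention: initial families entering selection (after any
    # pre-drop) minus kept, minus intercept
    final.reported_df = (p_initial - len(predropped)) - len(cols) - 1
    return SelectionTrace(
        steps=steps, final=final, initial_ids=ids, predropped=predropped
    )
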