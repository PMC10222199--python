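"""Shared model-quality machinery: fit summaries, AICc, selection traces."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import DegreesOfFreedomError, ParameterError

__all__ = ["aicc", "aicc_or_inf", "ModelFit", "SelectionStep", "SelectionTrace"]


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a least-squares fit.

    ``n * ln(rss / n) + 2k + 2k(k + 1) / (n - k - 1)``, where ``k`` counts the
    explanatory variables under the convention of the route using it (families
    plus intercept for the linear route; observed motifs or remaining families
    for the clustering route).  The Gaussian constant and the variance
    parameter are omitted; only within-convention comparisons are meaningful.
    """
    if rss <= 0:
        raise ParameterError(f"rss must be positive, got {rss}")
    if n - k - 1 <= 0:
        raise DegreesOfFreedomError(
            f"AICc small-sample correction undefined for n={n}, k={k} (need n - k - 1 > 0)"
        )
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def aicc_or_inf(rss: float, n: int, k: int) -> float:
    """AICc with sentinel values instead of errors at the domain edges.

    Returns ``+inf`` when the small-sample correction is undefined
    (n - k - 1 <= 0) and ``-inf`` for a perfect fit (rss = 0).  Selection
    procedures start from saturated models where the correction is undefined,
    so they compare against ``+inf`` until enough variables are removed.
    """
    if n - k - 1 <= 0:
        return float("inf")
    if rss <= 0.0:
        return float("-inf")
    return aicc(rss, n, k)


@dataclass
class ModelFit:
    """Summary of one fitted model, from either route.

    ``reported_df`` mirrors the degrees-of-freedom convention of the study's
    summary tables (initial families minus kept, minus one on the linear
    route); ``df_resid`` is the conventional residual df ``n - k``.
    """

    route: str  # "linear" or "clustering"
    kept: list[str]
    fitted: np.ndarray
    r2: float
    f_ratio: float
    aicc: float
    k: int
    reported_df: int | None = None
    df_resid: int | None = None
    coefficients: pd.Series | None = None
    intercept: float | None = None
    coef_pvalues: pd.Series | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def rss(self) -> float:
        return float(self.extras.get("rss", np.nan))

    def summary_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "route": self.route,
            "n_kept": len(self.kept),
            "kept": list(self.kept),
            "r2": self.r2,
            "f_ratio": self.f_ratio,
            "aicc": self.aicc,
            "k": self.k,
        }
        if self.reported_df is not None:
            out["reported_df"] = self.reported_df
        if self.df_resid is not None:
            out["df_resid"] = self.df_resid
        return out


@dataclass
class SelectionStep:
    """One accepted removal during backward stepwise selection."""

    removed: str
    aicc_before: float
    aicc_after: float
    n_kept: int  # variables remaining after the removal


@dataclass
class SelectionTrace:
    """Full record of a backward stepwise selection run."""

    steps: list[SelectionStep]
    final: ModelFit
    initial_ids: list[str]
    predropped: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return [s.removed for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removed": [s.removed for s in self.steps],
                "aicc_before": [s.aicc_before for s in self.steps],
                "aicc_after": [s.aicc_after for s in self.steps],
                "n_kept": [s.n_kept for s in self.steps],
            }
        )
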