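"""Age-effect tests and the rate/duration decomposition of final cell number.

Three questions are answered at the tree level:

1. does a seasonal characteristic (final cell number, onset, end, duration,
   inflection date, maximal or mean rate) trend with stand age? —
   ``age_trend_anova`` regresses the per-tree value on age entered as a
   numeric covariate and reports the 1-df regression ANOVA line (an
   optional classical one-way factor ANOVA is available);

2. how do rate and duration jointly determine the final cell number? —
   ``fit_rate_duration`` fits the ordinary least squares model
   ``Y = alpha0 + alpha1 * rate + alpha2 * duration``;

3. how much of the explained variance does each predictor carry? —
   ``lmg_importance`` computes the LMG relative-importance decomposition:
   each predictor's share is the average, over all orderings in which
   predictors could enter the model, of the increase in R^2 when it enters.
   Shares are non-negative and sum exactly to the full-model R^2.

OLS fits go through statsmodels; the LMG allocation itself is computed from
the subset-R^2 formula with combinatorial weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "RateDurationModel",
    "RelativeImportance",
    "age_trend_anova",
    "fit_rate_duration",
    "lmg_importance",
]


@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA table line: df, SS, MS, F and its p-value."""

    term: str
    df: int
    sum_sq: float
    mean_sq: float
    f_value: float
    p_value: float
    residual_df: int
    residual_sum_sq: float


@dataclass
class RateDurationModel:
    """OLS fit of final cell number on formation rate and duration.

    ``alpha0`` intercept (cells), ``alpha1`` rate coefficient (cells per
    cells/day), ``alpha2`` duration coefficient (cells/day); per-coefficient
    t and p values and the model R^2.
    """

    alpha0: float
    alpha1: float
    alpha2: float
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    x1: np.ndarray = field(repr=False, default=None)
    x2: np.ndarray = field(repr=False, default=None)
    Y: np.ndarray = field(repr=False, default=None)


@dataclass
class RelativeImportance:
    """LMG allocation of a regression's R^2 among its predictors."""

    contributions: dict[str, float]
    total_r_squared: float
    normalized: bool = False

    def normalize(self) -> "RelativeImportance":
        """Return shares scaled to sum to 1 (fractions of explained R^2)."""
        if self.total_r_squared <= 0:
            raise ValueError("cannot normalize: total R^2 is zero")
        return RelativeImportance(
            contributions={k: v / self.total_r_squared
                           for k, v in self.contributions.items()},
            total_r_squared=self.total_r_squared,
            normalized=True,
        )


def age_trend_anova(values: dict[str, float] | pd.Series,
                    ages: dict[str, float] | pd.Series,
                    term: str = "value",
                    mode: str = "numeric") -> AnovaResult:
    """Test for an age trend in a per-tree seasonal characteristic.

    ``mode='numeric'`` (default) treats age as a continuous covariate and
    returns the single-df regression ANOVA line — F is then exactly the
    square of the slope's t statistic.  ``mode='factor'`` runs a classical
    one-way ANOVA across age classes (df = number of classes - 1).
    """
    values = pd.Series(values, dtype=float)
    ages = pd.Series(ages, dtype=float).reindex(values.index)
    if ages.isna().any():
        raise KeyError("ages missing for some trees")
    n = len(values)
    if n < 3 or ages.nunique() < 2:
        raise ValueError("need >= 3 trees across >= 2 distinct ages")
    y = values.to_numpy()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("response is constant; F undefined")
    if mode == "numeric":
        X = sm.add_constant(ages.to_numpy())
        res = sm.OLS(y, X).fit()
        ssr = sst - float(res.ssr)
        df1, df2 = 1, n - 2
        sse = float(res.ssr)
    elif mode == "factor":
        groups = [y[ages.to_numpy() == a] for a in np.unique(ages)]
        means = [g.mean() for g in groups]
        ssr = float(sum(len(g) * (m - y.mean()) ** 2
                        for g, m in zip(groups, means)))
        sse = sst - ssr
        df1, df2 = len(groups) - 1, n - len(groups)
    else:
        raise ValueError(f"mode must be 'numeric' or 'factor', got {mode!r}")
    if df2 <= 0 or sse < 0:
        raise ValueError("insufficient residual degrees of freedom")
    msr, mse = ssr / df1, sse / df2
    f = msr / mse if mse > 0 else math.inf
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return AnovaResult(term=term, df=df1, sum_sq=ssr, mean_sq=msr,
                       f_value=f, p_value=p,
                       residual_df=df2, residual_sum_sq=sse)


def fit_rate_duration(Y, x1, x2) -> RateDurationModel:
    """OLS of final cell number on formation rate (x1) and duration (x2).

    Raises on rank deficiency, naming the offending column (a constant or
    duplicated predictor makes the decomposition meaningless).
    """
    Y = np.asarray(Y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (Y.shape == x1.shape == x2.shape) or Y.ndim != 1:
        raise ValueError("Y, x1, x2 must be equal-length 1-d arrays")
    if Y.size < 4:
        raise ValueError("need at least 4 trees")
    X = np.column_stack([np.ones_like(x1), x1, x2])
    if np.linalg.matrix_rank(X) < 3:
        bad = [name for name, col in (("rate", x1), ("duration", x2))
               if np.ptp(col) == 0]
        detail = f"constant column(s): {bad}" if bad else "rate and duration are collinear"
        raise ValueError(f"rank-deficient design; {detail}")
    res = sm.OLS(Y, X).fit()
    names = ("intercept", "rate", "duration")
    return RateDurationModel(
        alpha0=float(res.params[0]),
        alpha1=float(res.params[1]),
        alpha2=float(res.params[2]),
        t_values=dict(zip(names, map(float, res.tvalues))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        r_squared=float(res.rsquared),
        x1=x1, x2=x2, Y=Y,
    )


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...],
               cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    if not cols:
        r2 = 0.0
    else:
        M = np.column_stack([np.ones_like(y), X[:, cols]])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst
    cache[cols] = r2
    return r2


def lmg_importance(Y, predictors: dict[str, np.ndarray] | pd.DataFrame,
                   normalized: bool = False) -> RelativeImportance:
    """LMG relative importance of each predictor in an OLS regression.

    For predictor ``j`` the LMG share averages, over every subset S of the
    other predictors weighted by how often S precedes j in a random entry
    ordering (weight |S|! (p-|S|-1)! / p!), the R^2 increment of adding j
    to S.  For two predictors this reduces to
    ``0.5 * [R2(x1) + (R2(x1,x2) - R2(x2))]``.  The shares sum exactly to
    the full-model R^2; ``normalized=True`` rescales them to fractions.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(float)
    else:
        names = list(predictors)
        X = np.column_stack([np.asarray(predictors[n], float) for n in names])
    y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("Y and predictors have incompatible shapes")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} predictors")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant")
    # collinear (even duplicated) predictors are allowed: subset R^2 values
    # use least squares, and LMG then splits the shared contribution
    # symmetrically among the collinear columns

    cache: dict[tuple[int, ...], float] = {}
    shares = {}
    for j in range(p):
        others = [i for i in range(p) if i != j]
        total = 0.0
        for size in range(p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for S in combinations(others, size):
                r2_with = _subset_r2(y, X, tuple(sorted(S + (j,))), cache)
                r2_without = _subset_r2(y, X, tuple(sorted(S)), cache)
                total += w * (r2_with - r2_without)
        shares[names[j]] = total
    full = _subset_r2(y, X, tuple(range(p)), cache)
    out = RelativeImportance(contributions=shares, total_r_squared=full)
    return out.normalize() if normalized else out
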