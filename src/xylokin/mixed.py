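"""Gompertz nonlinear mixed-effects estimation with a random asymptote.

Model for the cumulative cell count of tree ``i`` at day ``t``:

    Y_ij = (A + a_i) * exp(-exp(beta - k * t_ij)) + eps_ij,
    a_i ~ N(0, sigma_A^2),   eps_ij ~ N(0, sigma_e^2),

i.e. a single Gompertz curve shared by a stand, with each tree allowed its
own asymptote.  Because the random effect enters the mean linearly (it
multiplies the known-shape curve ``g(t) = exp(-exp(beta - k t))`` once
``beta`` and ``k`` are fixed), the marginal likelihood integrates exactly:
per tree the covariance is ``sigma_e^2 I + sigma_A^2 g g^T``, a rank-one
update handled in closed form.  The population asymptote ``A`` is profiled
out by generalized least squares, and the remaining parameters
``(beta, log k, log sigma_A, log sigma_e)`` are optimized by Nelder-Mead
on the exact marginal (or restricted) log-likelihood — no linearization
error is incurred.

REML adds the usual ``log |X' V^-1 X|`` adjustment, with ``X`` the Jacobian
of the mean with respect to the fixed effects ``(A, beta, k)``.

Starting values are deterministic: ``A0 = 1.05 * max(y)`` and ``(beta0,
k0)`` from ordinary least squares on the linearization
``ln(-ln(Y/A0)) = beta - k t`` restricted to interior observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .gompertz import GompertzParams

__all__ = [
    "GompertzMixedEffects",
    "StandFit",
    "fit_stand",
    "compute_r_squared",
    "predict",
]

_LOG_2PI = math.log(2.0 * math.pi)
_FIXED_NAMES = ("A", "beta", "k")


@dataclass
class StandFit:
    """Result of fitting one stand.

    ``fixed`` holds the population Gompertz parameters; ``sigma_A`` the
    between-tree SD of the asymptote; ``sigma_e`` the residual SD;
    ``tree_effects`` the conditional modes (BLUPs) of each tree's asymptote
    deviation; ``r_squared`` the population-level (fixed-effects-only)
    1 - SSE/SST; ``df = n_obs - 3`` the residual degrees of freedom.
    """

    fixed: GompertzParams
    sigma_A: float
    sigma_e: float
    tree_effects: dict[str, float]
    r_squared: float
    df: int
    n_obs: int
    converged: bool
    log_likelihood: float
    std_errors: dict[str, float] = field(default_factory=dict)
    t_values: dict[str, float] = field(default_factory=dict)
    robust_std_errors: dict[str, float] = field(default_factory=dict)
    method: str = "reml"


def _gcurve(t, beta, k):
    z = np.clip(beta - k * t, -700.0, 700.0)
    return np.exp(-np.exp(z))


class GompertzMixedEffects(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the random-asymptote Gompertz model.

    Parameters
    ----------
    method : {"reml", "ml"}, default "reml"
        Maximize the restricted or the plain marginal log-likelihood.
    tol : float
        Relative function-value tolerance of the outer optimizer.
    max_iter : int
        Outer iteration cap per start.
    n_restarts : int
        Additional jittered restarts attempted if a start fails to converge.
    random_state : int
        Seed for the restart jitter only (the first start is deterministic).

    Attributes (after ``fit``)
    --------------------------
    A_, beta_, k_ : fixed-effect estimates;  sigma_a_, sigma_e_ : variance
    components;  tree_effects_ : dict of per-tree asymptote deviations;
    se_, t_values_ : per fixed effect;  r_squared_, df_, n_obs_,
    converged_, log_likelihood_.
    """

    def __init__(self, method: str = "reml", tol: float = 1e-8,
                 max_iter: int = 500, n_restarts: int = 3, random_state: int = 0):
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- likelihood machinery ------------------------------------------------

    @staticmethod
    def _per_tree(t, y, groups):
        trees = []
        for tree in pd.unique(np.asarray(groups)):
            m = np.asarray(groups) == tree
            trees.append((tree, t[m], y[m]))
        return trees

    @staticmethod
    def _neg2ll(beta, k, sa2, se2, trees, reml, A_fixed=None):
        """Exact -2 log marginal likelihood, with A profiled unless given.

        Returns (value, A_hat).  Uses the rank-one structure
        V_i = se2*I + sa2*g_i g_i' via Sherman-Morrison.
        """
        num = den = 0.0
        pieces = []
        for _, t, y in trees:
            g = _gcurve(t, beta, k)
            gg = float(g @ g)
            d = se2 + sa2 * gg  # scalar saddle term
            if not np.isfinite(d) or d <= 0 or gg <= 1e-300:
                return np.inf, np.nan
            gy = float(g @ y)
            num += gy / d
            den += gg / d
            pieces.append((t, y, g, gg, gy, d))
        if den <= 0 or not np.isfinite(den):
            return np.inf, np.nan
        A = num / den if A_fixed is None else float(A_fixed)

        total = 0.0
        xtvx = np.zeros((3, 3))
        for t, y, g, gg, gy, d in pieces:
            n_i = y.size
            r = y - A * g
            # r' V^-1 r via Sherman-Morrison
            gr = float(g @ r)
            quad = float(r @ r) / se2 - sa2 * gr * gr / (se2 * d)
            logdet = (n_i - 1) * math.log(se2) + math.log(d)
            total += n_i * _LOG_2PI + logdet + quad
            if reml:
                u = np.exp(np.clip(beta - k * t, -700.0, 700.0))
                X = np.column_stack([g, -A * u * g, A * t * u * g])
                Xg = X.T @ g
                xtvx += X.T @ X / se2 - sa2 * np.outer(Xg, Xg) / (se2 * d)
        if reml:
            sign, ld = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return np.inf, A
            total += ld - 3 * _LOG_2PI
        return total, A

    def _objective_factory(self, trees, reml):
        def obj(x):
            beta, logk, logsa, logse = x
            val, _ = self._neg2ll(beta, math.exp(logk),
                                  math.exp(2 * logsa), math.exp(2 * logse),
                                  trees, reml)
            return val
        return obj

    @staticmethod
    def _initial_values(t, y, groups):
        """Deterministic starting values from the log-log linearization."""
        A0 = 1.05 * float(np.max(y))
        frac = np.clip(y / A0, 1e-9, 1 - 1e-9)
        interior = (y > 0.05 * A0) & (y < 0.95 * A0)
        if interior.sum() >= 2:
            z = np.log(-np.log(frac[interior]))
            slope, intercept = np.polyfit(t[interior], z, 1)
            k0 = max(-slope, 1e-4)
            beta0 = float(intercept)
        else:  # pathological spread; neutral mid-season start
            k0, beta0 = 0.01, 0.01 * float(np.median(t))
        g0 = _gcurve(t, beta0, k0)
        resid = y - A0 * g0
        se0 = max(float(np.std(resid)), 1e-2)
        # crude per-tree asymptotes for the random-effect scale
        a_i = []
        for tree in pd.unique(np.asarray(groups)):
            m = np.asarray(groups) == tree
            gm = g0[m]
            if float(gm @ gm) > 1e-12:
                a_i.append(float(gm @ y[m]) / float(gm @ gm))
        sa0 = max(float(np.std(a_i)) if len(a_i) > 1 else 0.0, 0.02 * A0)
        return A0, beta0, k0, sa0, se0

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, groups=None):
        """Fit the model.

        Parameters
        ----------
        X : array-like of shape (n, 1) or (n,)
            Day of year of each observation.
        y : array-like of shape (n,)
            Total (or phase) cell count.
        groups : array-like of shape (n,), optional
            Tree identifier per observation.  With a single tree (or when
            omitted) the model degrades to fixed-effects nonlinear least
            squares with ``sigma_a_ = 0``.
        """
        if self.method not in ("reml", "ml"):
            raise ValueError(f"method must be 'reml' or 'ml', got {self.method!r}")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must have a single column (day of year)")
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y have incompatible shapes")
        if t.size < 4:
            raise ValueError("need at least 4 observations")
        if groups is None:
            groups = np.zeros(t.size, dtype=int)
        groups = np.asarray(groups)
        n_trees = pd.unique(groups).size
        single = n_trees < 2
        if single:
            warnings.warn(
                "fewer than 2 trees: falling back to fixed-effects nonlinear "
                "least squares with sigma_A = 0",
                stacklevel=2,
            )
        trees = self._per_tree(t, y, groups)
        reml = self.method == "reml"
        A0, beta0, k0, sa0, se0 = self._initial_values(t, y, groups)
        x0 = np.array([beta0, math.log(k0),
                       math.log(max(sa0, 1e-8)), math.log(se0)])

        rng = np.random.default_rng(self.random_state)
        best = None
        converged = False
        for attempt in range(1 + self.n_restarts):
            start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.1, size=4)
            if single:
                # optimize (beta, log k, log se) with sigma_A pinned near 0
                def obj3(x3):
                    val, _ = self._neg2ll(x3[0], math.exp(x3[1]), 0.0,
                                          math.exp(2 * x3[2]), trees, reml)
                    return val
                res = optimize.minimize(
                    obj3, start[[0, 1, 3]], method="Nelder-Mead",
                    options={"fatol": self.tol, "xatol": 1e-8,
                             "maxiter": 40 * self.max_iter, "maxfev": 40 * self.max_iter})
                xfull = np.array([res.x[0], res.x[1], -np.inf, res.x[2]])
            else:
                obj = self._objective_factory(trees, reml)
                res = optimize.minimize(
                    obj, start, method="Nelder-Mead",
                    options={"fatol": self.tol, "xatol": 1e-8,
                             "maxiter": 40 * self.max_iter, "maxfev": 40 * self.max_iter})
                xfull = res.x
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                best = (res.fun, xfull)
            if res.success and np.isfinite(res.fun):
                converged = True
                break
        if best is None:
            raise RuntimeError("mixed-model optimization failed from every start")

        fun, x = best
        beta, k = float(x[0]), math.exp(x[1])
        sa2 = 0.0 if not np.isfinite(x[2]) else math.exp(2 * x[2])
        se2 = math.exp(2 * x[3])
        _, A = self._neg2ll(beta, k, sa2, se2, trees, reml)

        self.A_, self.beta_, self.k_ = float(A), beta, float(k)
        self.sigma_a_ = math.sqrt(sa2)
        self.sigma_e_ = math.sqrt(se2)
        self.converged_ = bool(converged)
        self.log_likelihood_ = -0.5 * fun
        self.n_obs_ = int(t.size)
        self.df_ = int(t.size - 3)
        self.tree_effects_ = self._blups(trees, A, beta, k, sa2, se2)
        self.se_, self.t_values_ = self._fixed_se(trees, A, beta, k, sa2, se2)
        self.robust_se_ = self._cluster_robust_se(trees, A, beta, k, sa2, se2)
        self._train_t, self._train_y = t, y
        self.r_squared_ = self._population_r2(t, y)
        self.n_features_in_ = 1
        return self

    def _blups(self, trees, A, beta, k, sa2, se2):
        out = {}
        for tree, t, y in trees:
            g = _gcurve(t, beta, k)
            d = se2 + sa2 * float(g @ g)
            out[tree] = sa2 * float(g @ (y - A * g)) / d
        return out

    def _fixed_se(self, trees, A, beta, k, sa2, se2):
        """Conditional standard errors: numerical Hessian of the negative
        log-likelihood over (A, beta, k) at fixed variance components."""
        def nll(p):
            val, _ = self._neg2ll(p[1], p[2], sa2, se2, trees,
                                  reml=False, A_fixed=p[0])
            return 0.5 * val

        p0 = np.array([A, beta, k])
        h = np.maximum(np.abs(p0) * 1e-4, 1e-7)
        H = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                ei = np.zeros(3); ei[i] = h[i]
                ej = np.zeros(3); ej[j] = h[j]
                if i == j:
                    H[i, i] = (nll(p0 + ei) - 2 * nll(p0) + nll(p0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(p0 + ei + ej) - nll(p0 + ei - ej)
                        - nll(p0 - ei + ej) + nll(p0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = np.clip(np.diag(cov), 0.0, None)
        se = {n: float(math.sqrt(v)) if v > 0 else float("nan")
              for n, v in zip(_FIXED_NAMES, var)}
        tv = {n: (p0[i] / se[n] if se[n] and np.isfinite(se[n]) and se[n] > 0
                  else float("nan"))
              for i, n in enumerate(_FIXED_NAMES)}
        return se, tv

    def _cluster_robust_se(self, trees, A, beta, k, sa2, se2):
        """Tree-clustered sandwich standard errors for the fixed effects.

        H^-1 J H^-1 with J the sum of per-tree score outer products and a
        m/(m-1) small-sample factor.  Robust to heteroscedastic count noise
        (the model assumes a common residual variance); with few trees the
        sandwich itself is noisy, so consumers wanting a conservative
        interval should take the larger of ``se_`` and ``robust_se_``.
        Falls back to the model-based SEs when only one tree is present.
        """
        m = len(trees)
        if m < 2:
            return dict(self.se_)
        p0 = np.array([A, beta, k])
        h = np.maximum(np.abs(p0) * 1e-5, 1e-8)

        def nll_tree(tr, p):
            val, _ = self._neg2ll(p[1], p[2], sa2, se2, [tr],
                                  reml=False, A_fixed=p[0])
            return 0.5 * val

        J = np.zeros((3, 3))
        for tr in trees:
            s = np.zeros(3)
            for i in range(3):
                e = np.zeros(3); e[i] = h[i]
                s[i] = (nll_tree(tr, p0 + e) - nll_tree(tr, p0 - e)) / (2 * h[i])
            if not np.all(np.isfinite(s)):
                # likelihood not differentiable here (boundary/overflow);
                # fall back to the model-based SEs
                return dict(self.se_)
            J += np.outer(s, s)

        def nll(p):
            return sum(nll_tree(tr, p) for tr in trees)

        H = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                ei = np.zeros(3); ei[i] = h[i]
                ej = np.zeros(3); ej[j] = h[j]
                if i == j:
                    H[i, i] = (nll(p0 + ei) - 2 * nll(p0) + nll(p0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        nll(p0 + ei + ej) - nll(p0 + ei - ej)
                        - nll(p0 - ei + ej) + nll(p0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return dict(self.se_)
        try:
            Hi = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hi = np.linalg.pinv(H)
        cov = Hi @ J @ Hi * m / (m - 1)
        var = np.clip(np.diag(cov), 0.0, None)
        return {n: float(math.sqrt(v)) if v > 0 else float("nan")
                for n, v in zip(_FIXED_NAMES, var)}

    def _population_r2(self, t, y):
        pred = self.A_ * _gcurve(t, self.beta_, self.k_)
        sst = float(np.sum((y - np.mean(y)) ** 2))
        if sst <= 0:
            raise ValueError("response has zero variance; R^2 undefined")
        return float(np.clip(1.0 - float(np.sum((y - pred) ** 2)) / sst, 0.0, 1.0))

    @property
    def params_(self) -> GompertzParams:
        return GompertzParams(A=self.A_, beta=self.beta_, k=self.k_)

    def predict(self, X, tree=None):
        """Population prediction, or tree-level if ``tree`` is given."""
        if not hasattr(self, "A_"):
            raise AttributeError("estimator is not fitted")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        A = self.A_
        if tree is not None:
            if tree not in self.tree_effects_:
                raise KeyError(f"unknown tree id {tree!r}")
            A = A + self.tree_effects_[tree]
        return A * _gcurve(t, self.beta_, self.k_)


# ---------------------------------------------------------------------------
# Functional wrappers over the estimator


_PHASE_COLS = {
    "total": "n_total",
    "cambial": "n_cambial",
    "enlarging": "n_enlarging",
    "thickening": "n_thickening",
    "mature": "n_mature",
}


def fit_stand(observations: pd.DataFrame, response: str = "total",
              method: str = "reml") -> StandFit:
    """Fit the random-asymptote Gompertz model to one stand's observations.

    ``observations`` is a long-format frame with ``doy``, ``tree_id`` and
    count columns; ``response`` selects the phase (default the total count).
    """
    col = _PHASE_COLS.get(response, response)
    if col not in observations.columns:
        raise KeyError(f"response column {col!r} not in observations")
    est = GompertzMixedEffects(method=method)
    est.fit(observations["doy"].to_numpy(float),
            observations[col].to_numpy(float),
            groups=observations["tree_id"].to_numpy())
    return StandFit(
        fixed=est.params_,
        sigma_A=est.sigma_a_,
        sigma_e=est.sigma_e_,
        tree_effects=dict(est.tree_effects_),
        r_squared=est.r_squared_,
        df=est.df_,
        n_obs=est.n_obs_,
        converged=est.converged_,
        log_likelihood=est.log_likelihood_,
        std_errors=dict(est.se_),
        t_values=dict(est.t_values_),
        robust_std_errors=dict(est.robust_se_),
        method=method,
    )


def predict(fit: StandFit, doy, tree_id: str | None = None):
    """Predicted counts from a ``StandFit``; tree-level if ``tree_id`` given."""
    A = fit.fixed.A
    if tree_id is not None:
        if tree_id not in fit.tree_effects:
            raise KeyError(f"unknown tree id {tree_id!r}")
        A = A + fit.tree_effects[tree_id]
    t = np.asarray(doy, dtype=float)
    out = A * _gcurve(t, fit.fixed.beta, fit.fixed.k)
    return out if out.ndim else float(out)


def compute_r_squared(fit: StandFit, observations: pd.DataFrame,
                      response: str = "total") -> float:
    """Population-level R^2 = 1 - SSE/SST with fixed-effects predictions."""
    col = _PHASE_COLS.get(response, response)
    y = observations[col].to_numpy(float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("response has zero variance; R^2 undefined")
    pred = predict(fit, observations["doy"].to_numpy(float))
    return float(np.clip(1.0 - float(np.sum((y - pred) ** 2)) / sst, 0.0, 1.0))
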