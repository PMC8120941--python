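"""AB-EMA model fitting: grid-search, shared-solid-index and linear-L variants.

The calibration problem is: given tablets of known porosity ``f`` and measured
effective refractive index ``n_eff``, estimate the material's intrinsic solid
index ``n_s`` and the pore-shape depolarisation factor ``L`` so that porosity
can later be predicted from ``n_eff`` alone.

The canonical fit scans ``L`` over a uniform grid (default step 0.001); for
each candidate ``L`` the solid index implied by each sample is computed in
closed form and the candidate with the smallest standard deviation of those
per-sample values wins — a self-consistency criterion: under the correct
model every sample must imply the same material constant ``n_s``.  The fitted
``n_s`` is the mean of the per-sample values at the winning ``L``.

The modified model (mAB-EMA) replaces the scalar ``L`` by a linear function of
porosity, ``L(f) = a1 f + a2``, fitted with the same objective; ``a1 = 0``
recovers the scalar model, so the scalar model is nested in it.

Estimators follow the scikit-learn protocol (``fit(X, y)`` with ``X`` the
porosity column and ``y = n_eff``; fitted attributes carry a trailing
underscore) and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import ema
from .data import LinearLModel, TabletSet

__all__ = [
    "ABEMAFitError",
    "ABEMAFitResult",
    "ABEMA",
    "ModifiedABEMA",
    "fit_abema",
    "fit_mabema",
    "fit_abema_shared",
    "predict_porosity",
    "goodness",
    "relative_error_ns",
]


class ABEMAFitError(RuntimeError):
    """Raised when no candidate model yields a physical solid index for
    every sample (the grid search is 'unable to fit')."""


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class ABEMAFitResult:
    """Outcome of an AB-EMA or mAB-EMA fit.

    ``L_fit`` holds the scalar depolarisation factor for ``model_kind
    == 'abema'``; for ``'mabema'`` it is None and ``(a1, a2)`` hold the linear
    coefficients of L(f).  ``ns_fit`` is always the mean of
    ``per_sample_ns``.  ``rmse_f_percent`` is the porosity RMSE in percentage
    points (the practically relevant axis, since the calibration is used to
    predict porosity from n_eff).
    """

    model_kind: str
    ns_fit: float
    L_fit: Optional[float]
    a1: Optional[float]
    a2: Optional[float]
    per_sample_ns: np.ndarray
    objective: float
    adj_r2: Optional[float]
    rmse_f_percent: float
    residuals_f: np.ndarray
    f: np.ndarray
    n_eff: np.ndarray

    def L_at(self, f):
        """Depolarisation factor of the fitted model at porosity ``f``."""
        f = np.asarray(f, dtype=float)
        if self.model_kind == "abema":
            return np.full_like(f, self.L_fit)
        return self.a1 * f + self.a2

    def predict_neff(self, f):
        """Forward-model n_eff at porosity ``f`` under the fitted parameters."""
        f = np.asarray(f, dtype=float)
        return ema.neff_forward(f, self.ns_fit, np.clip(self.L_at(f), 0.0, 1.0))

    def predict_porosity(self, n_eff):
        return predict_porosity(self, n_eff)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "ns_fit": self.ns_fit,
            "L_fit": self.L_fit,
            "a1": self.a1,
            "a2": self.a2,
            "objective": self.objective,
            "adj_r2": self.adj_r2,
            "rmse_f_percent": self.rmse_f_percent,
            "per_sample_ns": list(map(float, self.per_sample_ns)),
            "residuals_f": list(map(float, self.residuals_f)),
        }


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single porosity column")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape != y.shape or X.ndim != 1:
        raise ValueError("X and y must be 1-D of equal length")
    return X, y


def _ns_matrix(f, n_eff, L):
    """Per-sample solid index for each row of candidate L values.

    ``L`` has shape (m,) for scalar candidates or (m, n) for per-sample
    (e.g. linear-in-f) candidates; returns shape (m, n) with NaN where the
    implied solid index is non-physical.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    return ema.ns_from_neff(f[None, :], n_eff[None, :], L)


def _objective_rows(ns_mat):
    """Std of per-sample n_s per candidate; NaN rows (non-physical) -> inf."""
    valid = np.all(np.isfinite(ns_mat), axis=1)
    obj = np.full(ns_mat.shape[0], np.inf)
    if np.any(valid):
        obj[valid] = np.std(ns_mat[valid], axis=1)
    return obj, valid


def _goodness(f, n_eff, result: "ABEMAFitResult", n_params: int):
    """Adjusted R^2 (on n_eff, centred, p fitted parameters) and porosity RMSE."""
    n = len(f)
    pred = result.predict_neff(f)
    ss_res = float(np.sum((n_eff - pred) ** 2))
    ss_tot = float(np.sum((n_eff - n_eff.mean()) ** 2))
    if n <= n_params + 1 or ss_tot == 0.0:
        adj = None
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    f_pred = predict_porosity(result, n_eff)
    residuals = f_pred - f
    rmse = float(np.sqrt(np.mean(residuals**2)) * 100.0)
    return adj, rmse, residuals


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class ABEMA(RegressorMixin, BaseEstimator):
    """Grid-search AB-EMA calibration (scalar depolarisation factor).

    Parameters
    ----------
    l_step : float, default 0.001
        Resolution of the uniform L grid over [0, 1].

    Attributes
    ----------
    L_ : float
        Depolarisation factor minimising the std of per-sample n_s.
        Ties are broken towards the smallest L.
    ns_ : float
        Mean of the per-sample solid indices at ``L_``.
    per_sample_ns_ : ndarray
    objective_ : float
        Std of per-sample n_s at the optimum (0 for noiseless consistent data).
    adj_r2_, rmse_f_percent_, residuals_f_ : goodness-of-fit diagnostics.
    result_ : ABEMAFitResult

    ``predict(X)`` returns the forward-modelled n_eff at porosities ``X``;
    ``predict_porosity(n_eff)`` inverts the calibration.
    """

    def __init__(self, l_step: float = 0.001):
        self.l_step = l_step

    def fit(self, X, y):
        f, n_eff = _check_xy(X, y)
        if len(f) < 3 or len(np.unique(f)) < 2:
            raise ValueError("need >= 3 samples spanning >= 2 porosities")
        m = int(round(1.0 / self.l_step))
        grid = np.arange(m + 1) * self.l_step
        ns_mat = _ns_matrix(f, n_eff, grid)
        obj, valid = _objective_rows(ns_mat)
        if not np.any(valid):
            raise ABEMAFitError(
                "unable to fit: every candidate L implies a non-physical "
                "solid index for at least one sample"
            )
        best = int(np.argmin(obj))  # argmin takes the first (smallest L) tie
        self.L_ = float(grid[best])
        self.per_sample_ns_ = ns_mat[best]
        self.ns_ = float(self.per_sample_ns_.mean())
        self.objective_ = float(obj[best])
        result = ABEMAFitResult(
            model_kind="abema",
            ns_fit=self.ns_,
            L_fit=self.L_,
            a1=None,
            a2=None,
            per_sample_ns=self.per_sample_ns_,
            objective=self.objective_,
            adj_r2=None,
            rmse_f_percent=np.nan,
            residuals_f=np.empty(0),
            f=f,
            n_eff=n_eff,
        )
        result.adj_r2, result.rmse_f_percent, result.residuals_f = _goodness(
            f, n_eff, result, n_params=2
        )
        self.adj_r2_ = result.adj_r2
        self.rmse_f_percent_ = result.rmse_f_percent
        self.residuals_f_ = result.residuals_f
        self.result_ = result
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        f = np.asarray(X, dtype=float)
        if f.ndim == 2:
            f = f[:, 0]
        return self.result_.predict_neff(f)

    def predict_porosity(self, n_eff):
        check_is_fitted(self)
        return predict_porosity(self.result_, n_eff)


class ModifiedABEMA(RegressorMixin, BaseEstimator):
    """mAB-EMA calibration with porosity-dependent pore shape L(f) = a1 f + a2.

    Fitted with the same std-of-per-sample-n_s objective as :class:`ABEMA`,
    subject to 0 <= a1 f + a2 <= 1 at every sample porosity.  A coarse grid
    over (a1, a2) (resolution ``a1_step`` / ``a2_step``) locates the basin and
    a Nelder-Mead refinement polishes it.  With ``a1 = 0`` the model reduces
    to the scalar fit, so the optimum is never worse than :class:`ABEMA`'s.
    """

    def __init__(self, a1_step: float = 0.02, a2_step: float = 0.005):
        self.a1_step = a1_step
        self.a2_step = a2_step

    def fit(self, X, y):
        f, n_eff = _check_xy(X, y)
        if len(f) < 4:
            raise ValueError("need >= 4 samples for the linear-L model")
        span = f.max() - f.min()
        if span <= 0:
            raise ValueError("porosities must span a non-zero range")
        # |a1| beyond 1/span cannot keep L inside [0,1] across the samples
        a1_max = 1.0 / span
        a1_grid = np.arange(-a1_max, a1_max + self.a1_step / 2, self.a1_step)
        a2_grid = np.arange(0.0, 1.0 + self.a2_step / 2, self.a2_step)
        A1, A2 = np.meshgrid(a1_grid, a2_grid, indexing="ij")
        pairs = np.column_stack([A1.ravel(), A2.ravel()])
        L = pairs[:, 0:1] * f[None, :] + pairs[:, 1:2]
        feasible = np.all((L >= 0.0) & (L <= 1.0), axis=1)
        if not np.any(feasible):
            raise ABEMAFitError("constraint set 0 <= a1 f + a2 <= 1 is infeasible")
        pairs = pairs[feasible]
        ns_mat = ema.ns_from_neff(f[None, :], n_eff[None, :], L[feasible])
        obj, valid = _objective_rows(ns_mat)
        if not np.any(valid):
            raise ABEMAFitError("unable to fit: no feasible (a1, a2) is physical")
        a1_0, a2_0 = pairs[int(np.argmin(obj))]

        def penalised(theta):
            a1, a2 = theta
            Lf = a1 * f + a2
            pen = np.sum(np.maximum(0.0, -Lf) + np.maximum(0.0, Lf - 1.0))
            if pen > 0:
                return 1e3 * (1.0 + pen)
            ns = ema.ns_from_neff(f, n_eff, Lf)
            if not np.all(np.isfinite(ns)):
                return 1e3
            return float(np.std(ns))

        res = minimize(
            penalised,
            x0=[a1_0, a2_0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        self.a1_, self.a2_ = float(res.x[0]), float(res.x[1])
        Lf = np.clip(self.a1_ * f + self.a2_, 0.0, 1.0)
        self.per_sample_ns_ = ema.ns_from_neff(f, n_eff, Lf)
        self.ns_ = float(np.mean(self.per_sample_ns_))
        self.objective_ = float(np.std(self.per_sample_ns_))
        result = ABEMAFitResult(
            model_kind="mabema",
            ns_fit=self.ns_,
            L_fit=None,
            a1=self.a1_,
            a2=self.a2_,
            per_sample_ns=self.per_sample_ns_,
            objective=self.objective_,
            adj_r2=None,
            rmse_f_percent=np.nan,
            residuals_f=np.empty(0),
            f=f,
            n_eff=n_eff,
        )
        result.adj_r2, result.rmse_f_percent, result.residuals_f = _goodness(
            f, n_eff, result, n_params=3
        )
        self.adj_r2_ = result.adj_r2
        self.rmse_f_percent_ = result.rmse_f_percent
        self.residuals_f_ = result.residuals_f
        self.result_ = result
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        f = np.asarray(X, dtype=float)
        if f.ndim == 2:
            f = f[:, 0]
        return self.result_.predict_neff(f)

    def predict_porosity(self, n_eff):
        check_is_fitted(self)
        return predict_porosity(self.result_, n_eff)


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def fit_abema(tablet_set: TabletSet, l_step: float = 0.001) -> ABEMAFitResult:
    """Grid-search AB-EMA fit of a :class:`~porethz.data.TabletSet`."""
    est = ABEMA(l_step=l_step).fit(tablet_set.f, tablet_set.n_eff)
    return est.result_


def fit_mabema(tablet_set: TabletSet, **kwargs) -> ABEMAFitResult:
    """mAB-EMA (linear L(f)) fit of a :class:`~porethz.data.TabletSet`."""
    est = ModifiedABEMA(**kwargs).fit(tablet_set.f, tablet_set.n_eff)
    return est.result_


def fit_abema_shared(
    sets: Sequence[TabletSet], l_step: float = 0.001, max_iter: int = 100
) -> list[ABEMAFitResult]:
    """Joint AB-EMA fit of several sets of the same material.

    Finds one depolarisation factor per set and a single shared solid index by
    minimising the pooled sum of squared deviations of every per-sample n_s
    from the pooled mean.  Optimised by deterministic coordinate descent over
    the per-set L grids, initialised from the independent fits; for a single
    set this reduces to :func:`fit_abema` (up to tie-breaking).
    """
    if len(sets) < 1:
        raise ValueError("need at least one set")
    m = int(round(1.0 / l_step))
    grid = np.arange(m + 1) * l_step
    mats, valids = [], []
    for ts in sets:
        mat = _ns_matrix(ts.f, ts.n_eff, grid)
        ok = np.all(np.isfinite(mat), axis=1)
        if not np.any(ok):
            raise ABEMAFitError(f"unable to fit set {ts.material!r}")
        mats.append(mat)
        valids.append(ok)
    # initialise from the separate fits
    idx = []
    for mat, ok in zip(mats, valids):
        obj = np.full(len(grid), np.inf)
        obj[ok] = np.std(mat[ok], axis=1)
        idx.append(int(np.argmin(obj)))

    sums = np.array([mats[k][idx[k]].sum() for k in range(len(sets))])
    sqs = np.array([(mats[k][idx[k]] ** 2).sum() for k in range(len(sets))])
    counts = np.array([mats[k].shape[1] for k in range(len(sets))], dtype=float)
    N = counts.sum()
    for _ in range(max_iter):
        changed = False
        for k in range(len(sets)):
            s1o = sums.sum() - sums[k]
            s2o = sqs.sum() - sqs[k]
            cand_s1 = mats[k].sum(axis=1)
            cand_s2 = (mats[k] ** 2).sum(axis=1)
            total = np.full(len(grid), np.inf)
            ok = valids[k]
            mean = (s1o + cand_s1[ok]) / N
            total[ok] = (s2o + cand_s2[ok]) - N * mean**2
            new = int(np.argmin(total))
            if new != idx[k]:
                idx[k] = new
                sums[k] = cand_s1[new]
                sqs[k] = cand_s2[new]
                changed = True
        if not changed:
            break
    ns_shared = float(sums.sum() / N)
    results = []
    for k, ts in enumerate(sets):
        per = mats[k][idx[k]]
        result = ABEMAFitResult(
            model_kind="abema",
            ns_fit=ns_shared,
            L_fit=float(grid[idx[k]]),
            a1=None,
            a2=None,
            per_sample_ns=per,
            objective=float(np.sqrt(np.mean((per - ns_shared) ** 2))),
            adj_r2=None,
            rmse_f_percent=np.nan,
            residuals_f=np.empty(0),
            f=ts.f,
            n_eff=ts.n_eff,
        )
        result.adj_r2, result.rmse_f_percent, result.residuals_f = _goodness(
            ts.f, ts.n_eff, result, n_params=2
        )
        results.append(result)
    return results


def predict_porosity(fit: ABEMAFitResult, n_eff):
    """Porosity predicted from measured n_eff under a fitted model.

    For the scalar model this is the exact closed form; for the mAB-EMA the
    scalar equation in f (with L depending on f) is solved by bracketed
    root-finding on [0, 1].  Values of n_eff outside the attainable range are
    clamped to the nearest endpoint.
    """
    n_eff = np.atleast_1d(np.asarray(n_eff, dtype=float))
    out = np.empty_like(n_eff)
    if fit.model_kind == "abema":
        clipped = np.clip(n_eff, 1.0, fit.ns_fit)
        out = ema.porosity_from_neff(clipped, fit.ns_fit, fit.L_fit)
        out = np.clip(np.atleast_1d(out), 0.0, 1.0)
    else:
        for i, target in enumerate(n_eff):
            def g(x):
                L = min(max(fit.a1 * x + fit.a2, 0.0), 1.0)
                return ema.neff_forward(x, fit.ns_fit, L) - target

            g0, g1 = g(0.0), g(1.0)
            if g0 <= 0:          # n_eff at or above the zero-porosity value
                out[i] = 0.0
            elif g1 >= 0:        # n_eff at or below 1
                out[i] = 1.0
            else:
                out[i] = brentq(g, 0.0, 1.0, xtol=1e-12)
    return out if out.size > 1 else float(out[0])


def goodness(fit: ABEMAFitResult, tablet_set: TabletSet):
    """(adjusted R^2, porosity RMSE in %, per-sample porosity residuals).

    Adjusted R^2 is computed on n_eff against the fitted curve with p = 2
    (scalar) or 3 (linear-L) fitted parameters; the RMSE on the porosity axis,
    since the calibration's purpose is porosity prediction.
    """
    p = 2 if fit.model_kind == "abema" else 3
    return _goodness(tablet_set.f, tablet_set.n_eff, fit, n_params=p)


def relative_error_ns(fit: ABEMAFitResult, ns_true: float, per_sample: bool = False):
    """Relative error of the fitted solid index, |ns_fit - ns_true| / ns_true."""
    if ns_true <= 1:
        raise ValueError("ns_true must exceed 1")
    if per_sample:
        return np.abs(fit.per_sample_ns - ns_true) / ns_true
    return abs(fit.ns_fit - ns_true) / ns_true
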