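"""Wiener bounds, solid-index margins, depolarisation bounds and fit validation.

The Wiener bounds are the extreme effective indices a two-phase mixture can
take (series vs parallel arrangement of the phases); they coincide with the
AB-EMA evaluated at L = 1 and L = 0.  Reading them backwards from the sample
with the *lowest* porosity gives a guaranteed interval ("margins") for the
unknown solid index n_s, and substituting each margin back into the AB-EMA
gives per-sample bounds [L_l, L_u] that the true depolarisation factor must
occupy — a model-free validity check for any AB-EMA fit: a fitted L that
escapes the bounds, or bounds converging towards a steep gradient in
porosity, signal that the constant-pore-shape assumption is broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import ema
from .data import TabletSet
from .fitting import ABEMAFitResult, _check_xy

__all__ = [
    "wiener_bounds",
    "wiener_bounds_multi",
    "NsMargins",
    "ns_margins",
    "LBoundsResult",
    "DepolarisationBounds",
    "l_bounds",
    "bound_tangents",
    "validate_fit",
]


def wiener_bounds(f, n_s):
    """Lower and upper Wiener bound on n_eff for porosity f and solid index n_s.

    n_eff_l**2 = 1 / (f + (1-f)/n_s**2)      (series; AB-EMA at L = 1)
    n_eff_u**2 = f + (1-f) n_s**2            (parallel; AB-EMA at L = 0)

    Both converge to n_s at f = 0 and to 1 at f = 1.
    """
    f = np.asarray(f, dtype=float)
    n_s = np.asarray(n_s, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("porosity must lie in [0, 1]")
    if np.any(n_s < 1):
        raise ValueError("n_s must be >= 1")
    s = n_s**2
    lower = np.sqrt(1.0 / (f + (1.0 - f) / s))
    upper = np.sqrt(f + (1.0 - f) * s)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def wiener_bounds_multi(f, fractions: Sequence[tuple[float, float]]):
    """Wiener bounds for a multicomponent solid phase.

    ``fractions`` is a list of ``(x_j, n_j)`` pairs where the ``x_j`` are the
    volume fractions of the *solid* phase (summing to 1); each component
    occupies ``(1 - f) x_j`` of the compact.  With one component this reduces
    exactly to :func:`wiener_bounds`.
    """
    f = float(f)
    if not 0 <= f <= 1:
        raise ValueError("porosity must lie in [0, 1]")
    x = np.array([p[0] for p in fractions], dtype=float)
    n = np.array([p[1] for p in fractions], dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("solid fractions must sum to 1")
    if np.any(n < 1):
        raise ValueError("all component indices must be >= 1")
    solid = (1.0 - f) * x
    lower = np.sqrt(1.0 / (f + np.sum(solid / n**2)))
    upper = np.sqrt(f + np.sum(solid * n**2))
    return float(lower), float(upper)


@dataclass(frozen=True)
class NsMargins:
    """Guaranteed interval for the solid index from the lowest-porosity sample.

    ns_u**2 = (1 - f1) / (1/n_eff1**2 - f1)   (if that sample had L = 1)
    ns_l**2 = (n_eff1**2 - f1) / (1 - f1)     (if that sample had L = 0)
    """

    ns_l: float
    ns_u: float
    f1: float
    neff1: float


def ns_margins(tablet_set_or_f, n_eff=None) -> NsMargins:
    """Margins for n_s from the minimum-porosity sample of a set.

    Accepts either a :class:`~porethz.data.TabletSet` or two arrays
    ``(f, n_eff)``.  Ties in the minimum porosity are broken towards the
    larger n_eff (the tighter lower margin).
    """
    if n_eff is None:
        f = tablet_set_or_f.f
        n_eff = tablet_set_or_f.n_eff
    else:
        f = np.asarray(tablet_set_or_f, dtype=float)
        n_eff = np.asarray(n_eff, dtype=float)
    if len(f) == 0:
        raise ValueError("empty set")
    fmin = f.min()
    if fmin >= 1:
        raise ValueError("anchor porosity must be below 1")
    cand = np.flatnonzero(f == fmin)
    anchor = cand[np.argmax(n_eff[cand])]
    f1, e1 = float(f[anchor]), float(n_eff[anchor]) ** 2
    if 1.0 / e1 <= f1:
        raise ValueError(
            "upper margin undefined: 1/n_eff1^2 <= f1 (sample violates the "
            "series Wiener bound for any physical solid)"
        )
    ns_u = float(np.sqrt((1.0 - f1) / (1.0 / e1 - f1)))
    ns_l = float(np.sqrt(max((e1 - f1) / (1.0 - f1), 0.0)))
    return NsMargins(ns_l=ns_l, ns_u=ns_u, f1=f1, neff1=float(np.sqrt(e1)))


@dataclass
class LBoundsResult:
    """Per-sample bounds for the depolarisation factor.

    ``flagged`` marks samples whose n_eff fell outside the Wiener interval of
    a margin index, where the bound was clamped to the nearest endpoint.
    ``tangent_l``/``tangent_u`` are the finite-difference slopes dL/df of each
    bound over the two highest-porosity samples.
    """

    f: np.ndarray
    L_l: np.ndarray
    L_u: np.ndarray
    margins: NsMargins
    flagged: np.ndarray
    tangent_l: Optional[float] = None
    tangent_u: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f": self.f, "L_l": self.L_l, "L_u": self.L_u, "flagged": self.flagged}
        )


def _l_bound_one_margin(f, n_eff, n_s):
    """Closed-form L for each sample against one margin index, clamped to [0,1]."""
    e, s = n_eff**2, n_s**2
    e_hi = f + (1.0 - f) * s
    e_lo = s / (1.0 - f + f * s)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = -e * (f * (1.0 - e) + (1.0 - f) * (s - e)) / ((1.0 - e) * (s - e))
    out_of_range = (e > e_hi) | (e < e_lo)
    L = np.where(e >= e_hi, 0.0, L)
    L = np.where(e <= e_lo, 1.0, L)
    return np.clip(L, 0.0, 1.0), out_of_range


class DepolarisationBounds(BaseEstimator):
    """Per-sample depolarisation-factor bounds for a tablet set.

    ``fit(X, y)`` takes the porosity column ``X`` and measured ``y = n_eff``,
    derives the solid-index margins from the lowest-porosity (anchor) sample
    and converts them into per-sample bounds [L_l, L_u].  The anchor sample
    itself carries no shape information and yields (0, 1) by construction.

    Attributes
    ----------
    margins_ : NsMargins
    L_l_, L_u_ : ndarray
    flagged_ : ndarray of bool
        Samples where a bound had to be clamped (n_eff outside the Wiener
        interval of a margin — only possible for noisy data).
    tangent_l_, tangent_u_ : float
        Bound slopes dL/df over the two highest porosities; for data truly
        generated by an AB-EMA with L(f) = a1 f + a2 both approach a1.
    result_ : LBoundsResult
    """

    def __init__(self, tangent_threshold: float = 0.25):
        self.tangent_threshold = tangent_threshold

    def fit(self, X, y):
        f, n_eff = _check_xy(X, y)
        if len(np.unique(np.round(f, 9))) < 2:
            raise ValueError("need >= 2 samples with distinct porosities")
        margins = ns_margins(f, n_eff)
        L_l, flag_l = _l_bound_one_margin(f, n_eff, margins.ns_l)
        L_u, flag_u = _l_bound_one_margin(f, n_eff, margins.ns_u)
        anchor = (f == margins.f1) & (n_eff == margins.neff1)
        L_l = np.where(anchor, 0.0, L_l)
        L_u = np.where(anchor, 1.0, L_u)
        self.margins_ = margins
        self.L_l_, self.L_u_ = L_l, L_u
        self.flagged_ = (flag_l | flag_u) & ~anchor
        self.result_ = LBoundsResult(
            f=f, L_l=L_l, L_u=L_u, margins=margins, flagged=self.flagged_
        )
        non_anchor = ~anchor
        if np.sum(non_anchor) >= 2:
            self.tangent_l_, self.tangent_u_ = bound_tangents(self.result_)
            self.result_.tangent_l = self.tangent_l_
            self.result_.tangent_u = self.tangent_u_
        else:
            self.tangent_l_ = self.tangent_u_ = None
        self.n_features_in_ = 1
        return self

    def validate(self, fit_result: ABEMAFitResult) -> dict:
        check_is_fitted(self)
        return validate_fit(
            fit_result, self.result_, tangent_threshold=self.tangent_threshold
        )


def l_bounds(tablet_set: TabletSet, **kwargs) -> LBoundsResult:
    """Depolarisation bounds of a :class:`~porethz.data.TabletSet`."""
    est = DepolarisationBounds(**kwargs).fit(tablet_set.f, tablet_set.n_eff)
    return est.result_


def bound_tangents(result: LBoundsResult) -> tuple[float, float]:
    """Finite-difference slopes dL/df of both bounds over the two highest
    porosities.  On AB-EMA-consistent data with linear L(f) both slopes
    approach the true gradient a1 as porosity grows."""
    order = np.argsort(result.f)
    top = order[-2:]
    df = result.f[top[1]] - result.f[top[0]]
    if df == 0:
        raise ValueError("two highest porosities coincide")
    slope_l = float((result.L_l[top[1]] - result.L_l[top[0]]) / df)
    slope_u = float((result.L_u[top[1]] - result.L_u[top[0]]) / df)
    return slope_l, slope_u


def validate_fit(
    fit: ABEMAFitResult,
    bounds: LBoundsResult,
    tangent_threshold: float = 0.25,
) -> dict:
    """Check a fitted model against the depolarisation bounds.

    Per sample the fitted L(f) must lie inside [L_l, L_u]; the anchor sample
    (bounds 0 and 1 by construction) is uninformative and skipped for the
    verdict.  The overall verdict is "invalid" if any non-anchor sample
    violates its bounds or if either bound tangent exceeds
    ``tangent_threshold`` in magnitude (steep convergence means the constant-L
    AB-EMA cannot describe the set; default 0.25 per unit porosity).
    """
    L_fit = np.asarray(fit.L_at(bounds.f), dtype=float)
    inside = (L_fit >= bounds.L_l - 1e-12) & (L_fit <= bounds.L_u + 1e-12)
    anchor = (bounds.L_l == 0.0) & (bounds.L_u == 1.0)
    violations = ~inside & ~anchor
    steep = False
    if bounds.tangent_l is not None:
        # the two tangents approach the true dL/df from opposite sides; only
        # once they agree in sign has a common gradient emerged that the
        # threshold can meaningfully judge
        same_sign = bounds.tangent_l * bounds.tangent_u > 0
        steep = same_sign and (
            min(abs(bounds.tangent_l), abs(bounds.tangent_u)) > tangent_threshold
        )
    valid = not violations.any() and not steep
    return {
        "valid": bool(valid),
        "per_sample_inside": inside.tolist(),
        "violations_at": bounds.f[violations].tolist(),
        "steep_tangent": bool(steep),
        "tangent_l": bounds.tangent_l,
        "tangent_u": bounds.tangent_u,
        "tangent_threshold": tangent_threshold,
    }
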