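"""Closed-form solvers for the anisotropic Bruggeman effective-medium model.

The anisotropic Bruggeman effective-medium approximation (AB-EMA) relates the
complex dielectric permittivity of a porous two-phase compact (air pores in a
solid matrix) to its porosity ``f``, the permittivity of the dense solid, and
a depolarisation factor ``L`` describing the spheroidal pore shape relative to
the probing field (``L = 1/3`` for spheres, ``L -> 0`` for needle-like prolate
pores aligned with the wavevector, ``L -> 1`` for flat oblate pores):

    f (1 - e) / (e + L (1 - e)) + (1 - f) (e_s - e) / (e + L (e_s - e)) = 0

where ``e`` is the effective permittivity and ``e_s`` the solid permittivity.
For weakly absorbing materials ``e = n_eff**2`` and ``e_s = n_s**2`` with real
refractive indices; that real form is the workhorse of terahertz porosity
analysis and every inversion below is an exact closed form of it.

All functions are vectorised over NumPy arrays and accept scalars.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "depolarisation_from_aspect",
    "aspect_from_depolarisation",
    "kappa_from_alpha",
    "alpha_from_kappa",
    "neff_forward",
    "ns_from_neff",
    "porosity_from_neff",
    "depolarisation_from_sample",
    "eps_s_from_eps_eff",
    "permittivity_from_refractive",
    "refractive_from_permittivity",
]

SPEED_OF_LIGHT = 299_792_458.0  # m s^-1


def _as_float(x):
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# pore shape <-> depolarisation factor
# ---------------------------------------------------------------------------

def depolarisation_from_aspect(aspect):
    """Depolarisation factor of a spheroidal pore from its axis ratio.

    ``aspect`` is the polar-to-equatorial semi-axis ratio p:q of a spheroid
    whose polar axis is parallel to the wavevector.  The mapping is

        L = 1 / (1 + 1.6 (p:q) + 0.4 (p:q)**2)

    which gives L = 1/3 for a sphere, L -> 0 for long prolate needles and
    L -> 1 for flat oblate discs.

    Parameters
    ----------
    aspect : float or array-like
        Polar-to-equatorial axis ratio, strictly positive.

    Returns
    -------
    float or ndarray
        Depolarisation factor in (0, 1).
    """
    a = _as_float(aspect)
    if np.any(a <= 0):
        raise ValueError("aspect ratio must be strictly positive")
    return 1.0 / (1.0 + 1.6 * a + 0.4 * a**2)


def aspect_from_depolarisation(L):
    """Invert :func:`depolarisation_from_aspect`.

    Solves ``0.4 x**2 + 1.6 x + 1 - 1/L = 0`` for the unique positive root.
    The endpoints L = 0 and L = 1 have no finite aspect ratio.
    """
    L = _as_float(L)
    if np.any((L <= 0) | (L >= 1)):
        raise ValueError("L must lie strictly inside (0, 1)")
    disc = 1.6**2 - 4 * 0.4 * (1.0 - 1.0 / L)
    return (-1.6 + np.sqrt(disc)) / (2 * 0.4)


# ---------------------------------------------------------------------------
# absorption coefficient <-> extinction coefficient
# ---------------------------------------------------------------------------

def kappa_from_alpha(alpha, frequency):
    """Extinction coefficient from the power absorption coefficient.

    kappa = c * alpha / (4 pi nu), with ``alpha`` in cm^-1 and ``frequency``
    in THz (converted to m^-1 and Hz internally).
    """
    a = _as_float(alpha)
    nu = _as_float(frequency)
    if np.any(a < 0):
        raise ValueError("alpha must be non-negative")
    if np.any(nu <= 0):
        raise ValueError("frequency must be positive")
    return SPEED_OF_LIGHT * (a * 100.0) / (4.0 * np.pi * nu * 1e12)


def alpha_from_kappa(kappa, frequency):
    """Inverse of :func:`kappa_from_alpha`; returns alpha in cm^-1."""
    k = _as_float(kappa)
    nu = _as_float(frequency)
    if np.any(k < 0):
        raise ValueError("kappa must be non-negative")
    if np.any(nu <= 0):
        raise ValueError("frequency must be positive")
    return 4.0 * np.pi * nu * 1e12 * k / SPEED_OF_LIGHT / 100.0


# ---------------------------------------------------------------------------
# complex refractive index <-> permittivity
# ---------------------------------------------------------------------------

def permittivity_from_refractive(n, kappa=0.0):
    """Complex permittivity ``(n - i kappa)**2`` (physics sign convention)."""
    n = np.asarray(n, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    return (n - 1j * kappa) ** 2


def refractive_from_permittivity(eps):
    """Return (n, kappa) from a complex permittivity, branch n > 0, kappa >= 0.

    The square root of ``eps`` is taken on the branch consistent with the
    ``n - i kappa`` convention: positive real part, non-negative ``kappa``.
    """
    eps = np.asarray(eps, dtype=complex)
    root = np.sqrt(eps)
    # principal sqrt has Re >= 0; enforce kappa = -Im(root) >= 0
    flip = np.imag(root) > 0
    root = np.where(flip, -root, root)
    return np.real(root), -np.imag(root)


# ---------------------------------------------------------------------------
# the real AB-EMA (Eq. in n_eff, n_s, f, L) and its closed-form inversions
# ---------------------------------------------------------------------------

def neff_forward(f, n_s, L):
    """Effective refractive index of a porous compact from the AB-EMA.

    Solves the real AB-EMA for ``n_eff`` given porosity ``f``, solid index
    ``n_s`` and depolarisation factor ``L``.  In ``e = n_eff**2`` the model is
    the quadratic

        (L - 1) e**2 + [f + (1 - f) s - L (1 + s)] e + L s = 0,   s = n_s**2.

    The physical root is the one inside the Wiener bracket
    ``[1/(f + (1-f)/s), f + (1-f) s]``; at L = 0 and L = 1 the model
    degenerates exactly to the upper and lower Wiener bound, which are used in
    closed form there.

    Parameters are broadcast against each other.
    """
    f, n_s, L = np.broadcast_arrays(_as_float(f), _as_float(n_s), _as_float(L))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("porosity must lie in [0, 1]")
    if np.any(n_s <= 1):
        raise ValueError("n_s must exceed 1")
    if np.any((L < 0) | (L > 1)):
        raise ValueError("L must lie in [0, 1]")
    s = n_s**2
    e_hi = f + (1.0 - f) * s                    # upper Wiener bound, L = 0
    e_lo = s / (1.0 - f + f * s)                # lower Wiener bound, L = 1

    a = L - 1.0
    b = f + (1.0 - f) * s - L * (1.0 + s)
    c = L * s
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
        r1 = (-b + disc) / (2.0 * a)
        r2 = (-b - disc) / (2.0 * a)
    tol = 1e-9 * np.maximum(e_hi, 1.0)
    in1 = (r1 >= e_lo - tol) & (r1 <= e_hi + tol)
    e = np.where(in1, r1, r2)
    # Wiener closed forms at the endpoints (the quadratic degenerates there)
    e = np.where(L == 0.0, e_hi, e)
    e = np.where(L == 1.0, e_lo, e)
    out = np.sqrt(e)
    return out if out.ndim else float(out)


def ns_from_neff(f, n_eff, L, *, allow_nonphysical=False):
    """Solid-phase refractive index implied by one (f, n_eff, L) sample.

    The AB-EMA is linear-fractional in the solid permittivity ``s``, giving
    the closed form ``s = e - A e / (A L + 1 - f)`` with
    ``A = f (1 - e) / (e + L (1 - e))`` and ``e = n_eff**2``.

    Non-physical solutions (``s <= 1``, i.e. a solid no denser optically than
    air) are returned as NaN so that callers can flag or exclude them; pass
    ``allow_nonphysical=True`` to get the raw value of sqrt(|s|)*sign — not
    normally wanted.
    """
    f, n_eff, L = np.broadcast_arrays(_as_float(f), _as_float(n_eff), _as_float(L))
    if np.any(f >= 1):
        raise ValueError("porosity must be strictly below 1")
    e = n_eff**2
    with np.errstate(divide="ignore", invalid="ignore"):
        A = f * (1.0 - e) / (e + L * (1.0 - e))
        s = e - A * e / (A * L + 1.0 - f)
    if allow_nonphysical:
        out = np.sign(s) * np.sqrt(np.abs(s))
    else:
        out = np.where(s > 1.0, np.sqrt(np.abs(s)), np.nan)
    return out if out.ndim else float(out)


def porosity_from_neff(n_eff, n_s, L):
    """Porosity from a measured effective index — the AB-EMA is linear in f.

    With ``A = (1 - e)/(e + L (1 - e))`` and ``B = (s - e)/(e + L (s - e))``
    the model reads ``f A + (1 - f) B = 0``, hence ``f = B / (B - A)``.

    ``n_eff`` must lie in ``[1, n_s]``.
    """
    n_eff, n_s, L = np.broadcast_arrays(
        _as_float(n_eff), _as_float(n_s), _as_float(L)
    )
    if np.any(n_s <= 1):
        raise ValueError("n_s must exceed 1")
    if np.any((n_eff < 1.0 - 1e-12) | (n_eff > n_s + 1e-12)):
        raise ValueError("n_eff must lie within [1, n_s]")
    e, s = n_eff**2, n_s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (1.0 - e) / (e + L * (1.0 - e))
        B = (s - e) / (e + L * (s - e))
        f = B / (B - A)
    f = np.where(np.isclose(e, s, rtol=0, atol=1e-14), 0.0, f)
    f = np.where(np.isclose(e, 1.0, rtol=0, atol=1e-14), 1.0, f)
    out = f
    return out if out.ndim else float(out)


def depolarisation_from_sample(n_eff, n_s, f, *, tol=1e-9):
    """Depolarisation factor implied by one (f, n_eff, n_s) triple.

    Clearing denominators in the real AB-EMA yields the closed form

        L = - e [f (1 - e) + (1 - f)(s - e)] / [(1 - e)(s - e)]

    with ``e = n_eff**2``, ``s = n_s**2``.  When ``n_eff`` sits exactly at
    the upper/lower Wiener bound of (f, n_s) this returns exactly 0/1; values
    within ``tol`` of the bounds are snapped to the endpoints.  ``n_eff``
    outside the Wiener interval raises a ``ValueError``.
    """
    n_eff, n_s, f = np.broadcast_arrays(
        _as_float(n_eff), _as_float(n_s), _as_float(f)
    )
    if np.any(f >= 1):
        raise ValueError("porosity must be strictly below 1")
    e, s = n_eff**2, n_s**2
    e_hi = f + (1.0 - f) * s
    e_lo = s / (1.0 - f + f * s)
    if np.any(e > e_hi * (1 + tol)) or np.any(e < e_lo * (1 - tol)):
        raise ValueError("n_eff lies outside the Wiener bounds of (f, n_s)")
    with np.errstate(divide="ignore", invalid="ignore"):
        L = -e * (f * (1.0 - e) + (1.0 - f) * (s - e)) / ((1.0 - e) * (s - e))
    snap = 1e-12  # float noise at the Wiener endpoints
    L = np.where(e >= e_hi * (1 - snap), 0.0, L)
    L = np.where(e <= e_lo * (1 + snap), 1.0, L)
    L = np.clip(L, 0.0, 1.0)
    return L if L.ndim else float(L)


def eps_s_from_eps_eff(f, eps_eff, L):
    """Solid complex permittivity from the full complex AB-EMA.

    The complex model is linear-fractional in the solid permittivity, so the
    same closed form as :func:`ns_from_neff` applies with complex arithmetic:
    ``eps_s = eps - A eps / (A L + 1 - f)``,
    ``A = f (1 - eps) / (eps + L (1 - eps))``.

    With a purely real ``eps_eff`` this reduces exactly to the real solver.
    Degenerate denominators yield complex NaN rather than raising.
    """
    f = _as_float(f)
    L = _as_float(L)
    eps = np.asarray(eps_eff, dtype=complex)
    if np.any(f >= 1):
        raise ValueError("porosity must be strictly below 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        A = f * (1.0 - eps) / (eps + L * (1.0 - eps))
        out = eps - A * eps / (A * L + 1.0 - f)
    return out if np.ndim(out) else complex(out)
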