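"""Lightweight containers for terahertz porosity data and fit results."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ema

__all__ = [
    "OpticalConstants",
    "SpheroidShape",
    "SolidPhase",
    "PorositySample",
    "LinearLModel",
    "TabletSet",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Measured optical constants of one compact at terahertz frequencies.

    ``kappa_eff`` and ``alpha_eff`` (cm^-1) are redundant given ``frequency``
    (THz): kappa = c alpha / (4 pi nu). If both are supplied they must agree.
    """

    n_eff: float
    kappa_eff: Optional[float] = None
    alpha_eff: Optional[float] = None
    frequency: Optional[float] = None

    def __post_init__(self):
        if self.n_eff < 1:
            raise ValueError("n_eff must be >= 1")
        if self.kappa_eff is not None and self.kappa_eff < 0:
            raise ValueError("kappa_eff must be >= 0")
        if self.alpha_eff is not None and self.alpha_eff < 0:
            raise ValueError("alpha_eff must be >= 0")
        if (
            self.kappa_eff is not None
            and self.alpha_eff is not None
            and self.frequency is not None
        ):
            expect = ema.kappa_from_alpha(self.alpha_eff, self.frequency)
            if not np.isclose(self.kappa_eff, expect, rtol=1e-6, atol=1e-12):
                raise ValueError(
                    "kappa_eff and alpha_eff are inconsistent at this frequency"
                )


@dataclass(frozen=True)
class SpheroidShape:
    """Pore shape as a depolarisation factor with its equivalent axis ratio."""

    L: float
    aspect: float

    def __post_init__(self):
        if not 0 <= self.L <= 1:
            raise ValueError("L must lie in [0, 1]")
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")
        if 0 < self.L < 1:
            expect = ema.depolarisation_from_aspect(self.aspect)
            if not np.isclose(self.L, expect, rtol=0, atol=1e-9):
                raise ValueError("L and aspect are mutually inconsistent")

    @classmethod
    def from_aspect(cls, aspect: float) -> "SpheroidShape":
        return cls(L=float(ema.depolarisation_from_aspect(aspect)), aspect=aspect)

    @classmethod
    def from_depolarisation(cls, L: float) -> "SpheroidShape":
        return cls(L=L, aspect=float(ema.aspect_from_depolarisation(L)))


@dataclass(frozen=True)
class SolidPhase:
    """Intrinsic optical constants of the fully dense solid fraction."""

    n_s: float
    kappa_s: float = 0.0

    def __post_init__(self):
        if self.n_s <= 1:
            raise ValueError("n_s must exceed 1")
        if self.kappa_s < 0:
            raise ValueError("kappa_s must be >= 0")


@dataclass(frozen=True)
class PorositySample:
    """One (porosity, n_eff) observation."""

    f: float
    optics: OpticalConstants
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.f < 1:
            raise ValueError("porosity must lie in [0, 1)")


@dataclass(frozen=True)
class LinearLModel:
    """Depolarisation factor as a linear function of porosity, L(f) = a1 f + a2."""

    a1: float
    a2: float

    def __call__(self, f):
        return self.a1 * np.asarray(f, dtype=float) + self.a2


class TabletSet:
    """Ordered collection of (porosity, n_eff) samples for one material.

    Parameters
    ----------
    f, n_eff : array-like
        Porosities (each in [0, 1), unique) and effective refractive indices.
    alpha_eff, frequency : array-like or float, optional
        Absorption coefficients (cm^-1) and frequency (THz) metadata.
    material : str
        Free-text label.
    true_ns, true_L : optional
        Ground truth for synthetic sets; ``true_L`` may be a scalar or a
        :class:`LinearLModel`.
    """

    def __init__(
        self,
        f: Sequence[float],
        n_eff: Sequence[float],
        *,
        alpha_eff=None,
        frequency=None,
        material: str = "",
        true_ns: Optional[float] = None,
        true_L=None,
    ):
        self.f = np.asarray(f, dtype=float)
        self.n_eff = np.asarray(n_eff, dtype=float)
        if self.f.shape != self.n_eff.shape or self.f.ndim != 1:
            raise ValueError("f and n_eff must be 1-D arrays of equal length")
        if np.any((self.f < 0) | (self.f >= 1)):
            raise ValueError("porosities must lie in [0, 1)")
        if len(np.unique(np.round(self.f, 9))) != len(self.f):
            raise ValueError("porosities must be unique")
        self.alpha_eff = None if alpha_eff is None else np.broadcast_to(
            np.asarray(alpha_eff, dtype=float), self.f.shape
        ).copy()
        self.frequency = frequency
        self.material = material
        self.true_ns = true_ns
        self.true_L = true_L

    def __len__(self) -> int:
        return len(self.f)

    def __repr__(self) -> str:
        return (
            f"TabletSet(n={len(self)}, material={self.material!r}, "
            f"f=[{self.f.min():.3g}..{self.f.max():.3g}])"
        )

    @property
    def samples(self) -> list[PorositySample]:
        out = []
        for i, (fi, ni) in enumerate(zip(self.f, self.n_eff)):
            alpha = None if self.alpha_eff is None else float(self.alpha_eff[i])
            out.append(
                PorositySample(
                    f=float(fi),
                    optics=OpticalConstants(
                        n_eff=float(ni), alpha_eff=alpha, frequency=self.frequency
                    ),
                    label=f"{self.material}-{i}" if self.material else str(i),
                )
            )
        return out

    def true_L_at(self, f=None):
        """Evaluate the ground-truth L at given porosities (default: own f)."""
        if self.true_L is None:
            return None
        f = self.f if f is None else np.asarray(f, dtype=float)
        if callable(self.true_L):
            return self.true_L(f)
        return np.full_like(f, float(self.true_L))

    def to_frame(self) -> pd.DataFrame:
        d = {"f": self.f, "n_eff": self.n_eff}
        if self.alpha_eff is not None:
            d["alpha_cm"] = self.alpha_eff
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "TabletSet":
        return cls(
            df["f"].to_numpy(),
            df["n_eff"].to_numpy(),
            alpha_eff=df["alpha_cm"].to_numpy() if "alpha_cm" in df else None,
            **kwargs,
        )
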