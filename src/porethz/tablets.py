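"""Tablet geometry, spectral band-averaging and tabular I/O.

Porosity of a compact follows from its mass, envelope volume and the true
(helium-pycnometric) density of the powder: f = 1 - M / (V rho_true).  Flat
cylindrical tablets use V = pi D^2 H / 4; biconvex tablets add two spherical
caps of punch depth h and curvature radius C to a cylindrical core of height
H - 2h, each cap contributing pi h^2 (3C - h) / 3.

The effective refractive index entering the AB-EMA analysis is the arithmetic
mean of the measured n_eff spectrum over a frequency band (default
0.4-0.8 THz, inclusive), where pharmaceutical compacts are transparent enough
for transmission spectroscopy and dispersion is weak.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "porosity_flat",
    "porosity_biconvex",
    "Spectrum",
    "average_neff_band",
    "TabletRecord",
    "read_tablet_table",
    "read_spectrum",
    "write_report",
    "tablet_set_from_records",
]

_LENGTH_CM = {"cm": 1.0, "mm": 0.1}
_MASS_G = {"g": 1.0, "mg": 1e-3}


def _convert(mass, lengths, units):
    """Normalise to grams / centimetres. ``units`` is 'cm-g' or 'mm-mg'."""
    try:
        lu, mu = units.split("-")
        return mass * _MASS_G[mu], [x * _LENGTH_CM[lu] for x in lengths]
    except (ValueError, KeyError):
        raise ValueError(f"unknown unit convention {units!r}; use 'cm-g' or 'mm-mg'")


def porosity_flat(mass, diameter, thickness, true_density, units="cm-g"):
    """Porosity of a flat-faced cylindrical tablet.

    f = 1 - 4 M / (pi D^2 H rho_true), with ``true_density`` in g cm^-3 and
    mass/lengths in the units named by ``units`` ('cm-g' default, or 'mm-mg').
    Results outside [0, 1) raise: the inputs are inconsistent.
    """
    if min(mass, diameter, thickness, true_density) <= 0:
        raise ValueError("all inputs must be positive")
    m, (d, h) = _convert(mass, [diameter, thickness], units)
    f = 1.0 - 4.0 * m / (math.pi * d**2 * h * true_density)
    if not 0.0 <= f < 1.0:
        raise ValueError(f"computed porosity {f:.4f} outside [0, 1): "
                         "inconsistent mass/geometry/density")
    return f


def porosity_biconvex(
    mass, diameter, thickness, punch_depth, curvature_radius, true_density,
    units="cm-g",
):
    """Porosity of a biconvex tablet (cylindrical core plus two spherical caps).

    V = pi D^2 (H - 2h) / 4 + 2 pi h^2 (3C - h) / 3, where ``thickness`` H is
    the total face-to-face height including the caps, ``punch_depth`` h the
    cap height and ``curvature_radius`` C the cap radius.  Reduces to
    :func:`porosity_flat` as h -> 0.
    """
    if min(mass, diameter, thickness, true_density) <= 0 or punch_depth < 0:
        raise ValueError("all inputs must be positive")
    if punch_depth > 0 and curvature_radius <= punch_depth:
        raise ValueError("curvature radius must exceed the punch depth")
    if thickness <= 2 * punch_depth:
        raise ValueError("total thickness must exceed twice the punch depth")
    m, (d, H, h, C) = _convert(
        mass, [diameter, thickness, punch_depth, curvature_radius], units
    )
    volume = math.pi * d**2 * (H - 2 * h) / 4.0 + 2.0 * math.pi * h**2 * (3 * C - h) / 3.0
    f = 1.0 - m / (volume * true_density)
    if not 0.0 <= f < 1.0:
        raise ValueError(f"computed porosity {f:.4f} outside [0, 1): "
                         "inconsistent mass/geometry/density")
    return f


class Spectrum:
    """A measured n_eff (and optional absorption) spectrum vs frequency (THz)."""

    def __init__(self, frequency, n_eff, alpha_eff=None):
        self.frequency = np.asarray(frequency, dtype=float)
        self.n_eff = np.asarray(n_eff, dtype=float)
        self.alpha_eff = None if alpha_eff is None else np.asarray(alpha_eff, float)
        if self.frequency.shape != self.n_eff.shape:
            raise ValueError("frequency and n_eff must have equal length")
        if self.alpha_eff is not None and self.alpha_eff.shape != self.frequency.shape:
            raise ValueError("alpha_eff must match the frequency grid")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def average_neff_band(spectrum: Spectrum, f_lo: float = 0.4, f_hi: float = 0.8):
    """Arithmetic mean of n_eff over the closed band [f_lo, f_hi] THz."""
    mask = (spectrum.frequency >= f_lo) & (spectrum.frequency <= f_hi)
    if not mask.any():
        raise ValueError(f"no spectral samples inside [{f_lo}, {f_hi}] THz")
    return float(spectrum.n_eff[mask].mean())


class TabletRecord(BaseModel):
    """One tablet's physical record; dimensions in mm, mass in mg.

    ``porosity`` is computed from geometry when absent.
    """

    id: str
    shape: Literal["flat", "biconvex"]
    mass_mg: float = Field(gt=0)
    diameter_mm: float = Field(gt=0)
    thickness_mm: float = Field(gt=0)
    true_density_g_cm3: float = Field(gt=0)
    n_eff: float = Field(ge=1)
    punch_depth_mm: Optional[float] = Field(default=None, gt=0)
    curvature_radius_mm: Optional[float] = Field(default=None, gt=0)
    porosity: Optional[float] = Field(default=None, ge=0, lt=1)

    @model_validator(mode="after")
    def _check_geometry(self):
        if self.shape == "biconvex":
            if self.punch_depth_mm is None or self.curvature_radius_mm is None:
                raise ValueError(
                    "biconvex tablets require punch_depth_mm and curvature_radius_mm"
                )
        if self.porosity is None:
            if self.shape == "flat":
                self.porosity = porosity_flat(
                    self.mass_mg, self.diameter_mm, self.thickness_mm,
                    self.true_density_g_cm3, units="mm-mg",
                )
            else:
                self.porosity = porosity_biconvex(
                    self.mass_mg, self.diameter_mm, self.thickness_mm,
                    self.punch_depth_mm, self.curvature_radius_mm,
                    self.true_density_g_cm3, units="mm-mg",
                )
        return self


_MANDATORY = [
    "id", "shape", "mass_mg", "diameter_mm", "thickness_mm",
    "true_density_g_cm3", "n_eff",
]


def read_tablet_table(path) -> list[TabletRecord]:
    """Read a tablet CSV into validated records.

    Expected columns: id, shape, mass_mg, diameter_mm, thickness_mm,
    punch_depth_mm, curvature_radius_mm, true_density_g_cm3, n_eff[,
    porosity].  Malformed rows are collected and reported with their line
    numbers in a single ValueError.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        data = {k: v for k, v in row.items() if pd.notna(v)}
        try:
            records.append(TabletRecord(**data))
        except Exception as exc:  # pydantic ValidationError or ValueError
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def read_spectrum(path) -> Spectrum:
    """Read a spectrum CSV with columns frequency_THz, n_eff[, alpha_cm]."""
    df = pd.read_csv(path)
    for col in ("frequency_THz", "n_eff"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return Spectrum(
        df["frequency_THz"].to_numpy(),
        df["n_eff"].to_numpy(),
        df["alpha_cm"].to_numpy() if "alpha_cm" in df.columns else None,
    )


def write_report(path, records: list[TabletRecord]) -> None:
    """Write records (including derived porosity) back to CSV."""
    pd.DataFrame([r.model_dump() for r in records]).to_csv(path, index=False)


def tablet_set_from_records(records: list[TabletRecord], material: str = ""):
    """Assemble a :class:`~porethz.data.TabletSet` from tablet records."""
    from .data import TabletSet

    f = [r.porosity for r in records]
    n = [r.n_eff for r in records]
    return TabletSet(f, n, material=material)
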