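"""Synthetic powder compacts and the three AB-EMA error studies.

Three deterministic, noiseless studies quantify the main systematic error
sources of terahertz AB-EMA porosity analysis:

* **absorption** — neglecting material absorption when extracting the solid
  index: compares the complex-permittivity inversion with the real one over a
  grid of absorption coefficient, effective index, porosity, frequency and
  pore shape;
* **pore shape** — a porosity-dependent pore shape (linear L(f) with gradient
  a1) fitted with the constant-L model: 51 sets whose L endpoints step by
  0.02, mean L fixed at 0.5;
* **density distribution** — biconvex tablets whose centre porosity (the
  column the THz beam probes) deviates a fixed relative fraction from the
  nominal porosity used in the calibration.

Every study returns a :class:`SimulationReport` of tidy tables, suitable for
CSV export; repeated runs are bit-identical (no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ema
from .data import LinearLModel, TabletSet
from .fitting import ABEMAFitError, fit_abema

__all__ = [
    "SimulationReport",
    "gen_set",
    "absorption_study",
    "poreshape_study",
    "density_study",
    "lbounds_demo_sets",
]

# reference solid index of microcrystalline cellulose, the benchmark excipient
MCC_NS = 1.86
DEFAULT_POROSITIES = np.round(np.arange(1, 11) * 0.05, 10)  # 0.05 .. 0.50


@dataclass
class SimulationReport:
    """Gridded outputs of one error study: named tidy tables plus a summary."""

    name: str
    tables: Mapping[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)

    def to_csv(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for key, df in self.tables.items():
            path = outdir / f"{self.name}_{key}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        return written


def gen_set(
    n_s: float,
    L_model,
    porosities: Sequence[float] = DEFAULT_POROSITIES,
    material: str = "synthetic",
) -> TabletSet:
    """Simulate a noiseless tablet set from the AB-EMA forward model.

    ``L_model`` is a constant in [0, 1] or a :class:`~porethz.data.LinearLModel`
    (or any callable of porosity); the true parameters are recorded in the set.
    """
    f = np.asarray(porosities, dtype=float)
    L = L_model(f) if callable(L_model) else np.full_like(f, float(L_model))
    if np.any((L < 0) | (L > 1)):
        raise ValueError("L(f) must stay within [0, 1] over the porosity range")
    n_eff = ema.neff_forward(f, n_s, L)
    return TabletSet(
        f, np.atleast_1d(n_eff), material=material, true_ns=n_s, true_L=L_model
    )


def absorption_study(
    alphas=np.arange(0.0, 51.0, 1.0),
    n_effs=np.round(np.arange(1.0, 5.01, 0.1), 10),
    porosities=np.round(np.arange(0.05, 0.26, 0.05), 10),
    frequencies=(0.2, 1.0),
    aspects=(5.0, 1.0, 1.0 / 5.0),
) -> SimulationReport:
    """Error from neglecting absorption in the solid-index extraction.

    For every grid cell the extinction coefficient kappa = c alpha / (4 pi nu)
    is attached to the measured index, the complex AB-EMA is inverted for the
    solid permittivity, and the real part of its refractive index (n_s,c) is
    compared with the purely real inversion (n_s):
    relative error = |n_s,c - n_s| / n_s,c.

    Cells where either inversion is non-physical are flagged, not dropped, so
    the table stays rectangular.
    """
    Ls = np.array([float(ema.depolarisation_from_aspect(a)) for a in aspects])
    grids = np.meshgrid(
        np.asarray(frequencies, float),
        Ls,
        np.asarray(porosities, float),
        np.asarray(n_effs, float),
        np.asarray(alphas, float),
        indexing="ij",
    )
    nu, L, f, n, alpha = (g.ravel() for g in grids)
    kappa = ema.kappa_from_alpha(alpha, nu)
    eps_eff = ema.permittivity_from_refractive(n, kappa)
    eps_s = ema.eps_s_from_eps_eff(f, eps_eff, L)
    ns_c, kappa_s = ema.refractive_from_permittivity(eps_s)
    ns_real = ema.ns_from_neff(f, n, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(ns_c - ns_real) / ns_c
    flagged = ~np.isfinite(ns_real) | ~np.isfinite(ns_c) | (ns_c <= 1.0)
    rel = np.where(flagged, np.nan, rel)
    aspect_col = np.repeat(
        np.asarray(aspects, float), len(porosities) * len(n_effs) * len(alphas)
    )
    aspect_col = np.tile(aspect_col, len(frequencies))
    df = pd.DataFrame(
        {
            "frequency_THz": nu,
            "aspect": aspect_col,
            "L": L,
            "porosity": f,
            "n_eff": n,
            "alpha_cm": alpha,
            "kappa_eff": kappa,
            "ns_complex": ns_c,
            "kappa_s": kappa_s,
            "ns_real": ns_real,
            "rel_error": rel,
            "flagged": flagged,
        }
    )
    ok = df[~df.flagged]
    by_L = ok.groupby("L")["rel_error"].mean()
    summary = {
        "max_rel_error": float(ok.rel_error.max()),
        "mean_rel_error_by_L": {f"{k:.6f}": float(v) for k, v in by_L.items()},
        "n_flagged": int(df.flagged.sum()),
    }
    return SimulationReport("absorption", {"grid": df}, summary)


def poreshape_study(
    n_s: float = MCC_NS,
    porosities=DEFAULT_POROSITIES,
    l_step: float = 0.001,
    n_sets: int = 51,
) -> SimulationReport:
    """Constant-L fits of sets whose pore shape varies linearly with porosity.

    Set k of the 51 has L = k*0.02 at the highest porosity and 1 - k*0.02 at
    the lowest, linear in between: gradients a1 from -2.2222 to +2.2222 in
    steps of 0.0889, mean L always exactly 0.5.  Each set is fitted with the
    scalar grid-search AB-EMA; per-set results and per-(gradient, porosity)
    porosity residuals are tabulated, with failure flags for sets the grid
    search cannot fit.
    """
    f = np.asarray(porosities, dtype=float)
    span = f.max() - f.min()
    rows, resid_rows = [], []
    for k in range(n_sets):
        L_hi = k * 0.02
        L_lo = 1.0 - L_hi
        a1 = (L_hi - L_lo) / span
        a2 = L_lo - a1 * f.min()
        model = LinearLModel(a1=a1, a2=a2)
        ts = gen_set(n_s, model, f, material=f"gradient_{a1:+.4f}")
        Lf = model(f)
        row = {
            "a1": a1,
            "a2": a2,
            "L_min": float(Lf.min()),
            "L_max": float(Lf.max()),
            "failed": False,
        }
        try:
            fit = fit_abema(ts, l_step=l_step)
        except ABEMAFitError:
            row.update(
                failed=True, L_fit=np.nan, ns_fit=np.nan, adj_r2=np.nan,
                rmse_f_percent=np.nan, rel_error_ns=np.nan,
            )
            rows.append(row)
            continue
        row.update(
            L_fit=fit.L_fit,
            ns_fit=fit.ns_fit,
            adj_r2=fit.adj_r2,
            rmse_f_percent=fit.rmse_f_percent,
            rel_error_ns=abs(fit.ns_fit - n_s) / n_s,
            L_fit_outside_range=not (Lf.min() <= fit.L_fit <= Lf.max()),
        )
        rows.append(row)
        for fi, ri, nsi in zip(f, fit.residuals_f, fit.per_sample_ns):
            resid_rows.append(
                {
                    "a1": a1,
                    "porosity": fi,
                    "residual_f": ri,
                    "ns_at_Lfit": nsi,
                    "rel_error_ns_sample": abs(nsi - n_s) / n_s,
                }
            )
    sets_df = pd.DataFrame(rows)
    resid_df = pd.DataFrame(resid_rows)
    fitted = sets_df[~sets_df.failed]
    summary = {
        "n_sets": n_sets,
        "n_failed": int(sets_df.failed.sum()),
        "min_adj_r2": float(fitted.adj_r2.min()),
        "max_rmse_f_percent": float(fitted.rmse_f_percent.max()),
        "max_rel_error_ns": float(fitted.rel_error_ns.max()),
    }
    return SimulationReport(
        "poreshape", {"sets": sets_df, "residuals": resid_df}, summary
    )


def density_study(
    deviation: float = 0.10,
    n_s: float = MCC_NS,
    L_true: float = 1.0 / 3.0,
    porosities=DEFAULT_POROSITIES,
    l_step: float = 0.001,
) -> SimulationReport:
    """Effect of a radial density distribution in biconvex tablets.

    The transmission measurement probes the axial centre column, whose
    porosity deviates from the nominal (whole-tablet) porosity when density
    is unevenly distributed.  Three sets are simulated with spherical pores
    (L = 1/3): centre porosity equal to, a relative ``deviation`` above, and
    the same below the nominal porosity; n_eff is computed at the centre
    porosity but fitted against the nominal porosities.
    """
    if not 0 <= deviation <= 0.5:
        raise ValueError("deviation must lie in [0, 0.5]")
    f = np.asarray(porosities, dtype=float)
    rows = []
    for label, factor in (("even", 1.0), ("higher_centre", 1.0 + deviation),
                          ("lower_centre", 1.0 - deviation)):
        fc = factor * f
        if np.any(fc >= 1):
            raise ValueError("centre porosity reaches 1; reduce the deviation")
        n_eff = np.atleast_1d(ema.neff_forward(fc, n_s, L_true))
        ts = TabletSet(f, n_eff, material=label, true_ns=n_s, true_L=L_true)
        fit = fit_abema(ts, l_step=l_step)
        rows.append(
            {
                "set": label,
                "centre_factor": factor,
                "L_fit": fit.L_fit,
                "ns_fit": fit.ns_fit,
                "adj_r2": fit.adj_r2,
                "rmse_f_percent": fit.rmse_f_percent,
            }
        )
    df = pd.DataFrame(rows)
    summary = {r["set"]: {"L_fit": r["L_fit"], "adj_r2": r["adj_r2"]} for r in rows}
    return SimulationReport("density", {"sets": df}, summary)


def lbounds_demo_sets(
    n_s: float = MCC_NS, porosities=DEFAULT_POROSITIES
) -> tuple[TabletSet, TabletSet, TabletSet]:
    """The three reference sets for the depolarisation-bounds analysis.

    Set 1: L(f) = 0.5 f + 0.275 (pores flatten with porosity),
    Set 2: L(f) = -0.5 f + 0.55 (pores elongate with porosity),
    Set 3: L = 0.5 constant; all with n_s = 1.86 over f = 0.05..0.5.
    """
    models = [
        ("set1", LinearLModel(0.5, 0.275)),
        ("set2", LinearLModel(-0.5, 0.55)),
        ("set3", LinearLModel(0.0, 0.5)),
    ]
    return tuple(
        gen_set(n_s, m, porosities, material=name) for name, m in models
    )
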