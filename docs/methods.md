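# Methods

## Model

The anisotropic Bruggeman effective-medium approximation (AB-EMA) treats a
tablet as a two-phase composite of air pores (volume fraction `f`, the
porosity) embedded in a solid matrix. Pores are spheroids with their polar
axis aligned with the wavevector; their shape enters through a single
depolarisation factor `L ∈ [0, 1]`:

    f (1 − ε̃_eff)/(ε̃_eff + L(1 − ε̃_eff))
      + (1 − f)(ε̃_s − ε̃_eff)/(ε̃_eff + L(ε̃_s − ε̃_eff)) = 0

with ε̃ = (n − iκ)² the complex permittivity (air = 1). `L = 1/3` is a
sphere (the classical Bruggeman model), `L → 0` a needle-like prolate along
the propagation direction, `L → 1` a flat oblate. `L` maps to the
polar-to-equatorial axis ratio p:q via `L = 1/(1 + 1.6(p:q) + 0.4(p:q)²)`.
Pharmaceutical materials absorb weakly at terahertz frequencies, so the
working form sets κ = 0, giving the real equation in `n_eff`, `n_s`, `f`,
`L` used throughout.

Assumptions worth keeping in mind: two phases only (multiple excipients are
folded into one effective `n_s`); a single shape factor for all pores;
no dispersion of `n_s` over the analysis band; porosity strictly below 1.

## Closed forms

All four inversions of the real equation are exact closed forms — there is
no iterative fitting inside the core:

* **`n_eff`**: the equation is a quadratic in `e = n_eff²`,
  `(L−1)e² + [f + (1−f)s − L(1+s)]e + Ls = 0` with `s = n_s²`. The physical
  root is the one inside the Wiener bracket; exactly one qualifies. At
  `L = 0` and `L = 1` the quadratic degenerates and the Wiener closed forms
  `e = f + (1−f)s` and `e = s/(1−f+fs)` are used directly, avoiding 0/0.
* **`n_s` and the complex ε̃_s**: the equation is linear-fractional in the
  solid permittivity: `s = e − Ae/(AL + 1 − f)` with
  `A = f(1−e)/(e + L(1−e))`; identical algebra with complex arithmetic
  solves the absorbing case, and the complex solver reduces bit-for-bit to
  the real one at κ = 0.
* **`f`**: the equation is linear in `f`.
* **`L`**: clearing denominators gives
  `L = −e[f(1−e) + (1−f)(s−e)] / [(1−e)(s−e)]`, which returns exactly 0/1
  when `n_eff` sits on the upper/lower Wiener bound; values within a 1e−12
  relative band of a bound are snapped to the endpoint to absorb float
  noise.

A solid index is *non-physical* when the implied `s ≤ 1` (a solid optically
no denser than air); such solutions are reported as NaN, never silently.
Closed-form identities are verified at 1e−10 absolute in the tests; the
complex sign convention is ε̃ = (n − iκ)² with `n > 0`, `κ ≥ 0`. Units at
the interface: absorption coefficient in cm⁻¹, frequency in THz; SI
internally with c = 299 792 458 m s⁻¹.

## Calibration fits

**Grid search (`ABEMA`).** `L` is scanned over a uniform grid (default step
0.001, i.e. 1001 candidates). For each candidate the per-sample `n_s` is
evaluated in closed form; the objective is the standard deviation of those
values — under the correct model every tablet must imply the same material
constant. The fitted `n_s` is the mean at the winning `L`. Grid candidates
producing any non-physical sample are excluded; if every candidate is
excluded the fit raises (`ABEMAFitError`, "unable to fit"). Ties break
toward the smallest `L` (deterministic output). For noiseless consistent
data with `L` on the grid the recovery is exact and the objective is 0.

**mAB-EMA (`ModifiedABEMA`).** `L` is replaced by `L(f) = a₁f + a₂`,
fitted with the same objective subject to `0 ≤ a₁f + a₂ ≤ 1` at the sample
porosities (enforced only there; between samples the model is evaluated
clipped). A coarse grid (a₁ step 0.02 over ±1/(f_max−f_min), the widest
feasible gradient; a₂ step 0.005 over [0,1]) locates the basin, then
Nelder-Mead polishes to ~1e−10. The scalar model is nested (a₁ = 0), so the
linear fit's objective never exceeds the grid fit's.

**Shared-`n_s` joint fit.** Several sets of one material are fitted with
one `L` per set and a single global `n_s` by minimising the pooled sum of
squared deviations of all per-sample `n_s` values from their pooled mean.
Deterministic coordinate descent over the per-set `L` grids, initialised
from the independent fits; each sweep is a vectorised exact minimisation,
and iteration stops at the first sweep with no change.

**Goodness of fit.** Adjusted R² is computed on `n_eff` against the fitted
curve (centred, p = 2 parameters for the scalar model, 3 for the linear
one, `1 − (1−R²)(n−1)/(n−p−1)`); this convention reproduces the
density-study reference values to print precision. The RMSE is reported on
the porosity axis, in percentage points, because the calibration is used
to predict porosity from `n_eff`; per-sample porosity residuals accompany
it. Out-of-range `n_eff` in prediction is clamped to the nearest porosity
endpoint; the mAB-EMA inversion solves the scalar equation in `f` by Brent
bracketing on [0, 1] (xtol 1e−12).

## Bounds for L and fit validation

The Wiener bounds (series/parallel phase arrangements) coincide with the
AB-EMA at `L = 1` and `L = 0`. Read backwards at the lowest-porosity sample
`(f₁, n_eff,1)` they give guaranteed margins for the solid index:
`n_s,u² = (1−f₁)/(1/n_eff,1² − f₁)`, `n_s,l² = (n_eff,1² − f₁)/(1−f₁)`.
Substituting each margin into the closed-form `L` inversion yields
per-sample bounds `[L_l, L_u]` that the true depolarisation factor must
occupy. By construction the anchor sample itself yields (0, 1) — it spends
its information on the margins. The anchor is the sample of strictly
minimal porosity, ties broken toward larger `n_eff` (tighter margins).

For noisy data a sample's `n_eff` can cross a margin's Wiener interval;
the affected bound is clamped to its endpoint and flagged rather than
raised, since this is expected behaviour near the bounds.

A fit is declared **invalid** when its `L(f)` leaves `[L_l, L_u]` at any
non-anchor sample, or when the bounds have converged onto a steep common
gradient. The tangents — finite-difference slopes of each bound over the
two highest-porosity samples — approach the true dL/df from opposite
sides, so while they still differ in sign no common gradient has emerged
and no steepness verdict is made (a constant-`L` set away from 0.5 keeps
one large-magnitude tangent long after the other has flattened). Once both
tangents share a sign, the set is steep if the smaller magnitude exceeds a
threshold, default 0.25 per unit porosity — a package choice (roughly half
the gradient at which the simulated `n_s` error reaches 2.5 %), not an
external constant, and configurable.

If the multicomponent Wiener bounds (solid fractions `x_j` with indices
`n_j`) are needed, `wiener_bounds_multi` takes the `x_j` as fractions of
the solid phase summing to 1 and scales them by (1−f) internally; they are
deliberately not used inside the `L`-bounds machinery, which is a strictly
two-phase construction.

## The simulation studies

All three studies are noiseless and deterministic by design — they isolate
*systematic* model error; repeated runs are bit-identical. Problem sizes
are the studies' defining grids and run in seconds on one CPU.

* **Absorption** (62 730 cells): α_eff 0–50 cm⁻¹ step 1 (up to a worst-case
  thin-tablet transmittance), n_eff 1–5 step 0.1, porosity 0.05–0.25 step
  0.05, frequencies 0.2 and 1 THz (the practical dynamic-range limits for
  whole tablets in transmission), pore shapes from aspect ratios 5, 1, 1/5
  (L ≈ 0.053, 1/3, 0.75). Each cell compares the real-part solid index from
  the complex inversion (n_s,c) with the purely real one:
  relative error = |n_s,c − n_s|/n_s,c. Non-physical cells are flagged, not
  dropped, keeping the table rectangular. Spherical pores show the smallest
  error; the 0.2 THz errors dominate the 1 THz ones essentially cell-by-cell
  (a handful of near-degenerate cells with n_eff ≈ 1 flip by < 2·10⁻⁴).
* **Pore-shape gradient sweep** (51 sets × 10 porosities): porosities
  0.05–0.50 step 0.05, n_s = 1.86 (microcrystalline cellulose), L linear in
  f with endpoint values stepping by 0.02 from (1, 0) to (0, 1) — gradients
  a₁ from −2.2222 to +2.2222 in steps of 0.0889, mean L fixed at 0.5. Each
  set is fitted with the constant-L grid search. The fitted n_s acquires a
  bias whose sign follows the gradient's, exceeding 2.5 % for gradient
  magnitudes above ≈0.6–0.7; for most non-zero gradients the fitted L lies
  outside the range of L values actually simulated. The implemented
  "unable to fit" criterion (every grid candidate non-physical) never
  triggers on these noiseless sets — extreme gradients instead drive the
  fitted L to the grid boundary with a visibly degraded adjusted R²
  (down to ≈0.86 at |a₁| = 2.22) and porosity RMSE up to ≈4.2 percentage
  points. The per-set failure flags are recorded regardless.
* **Density distribution** (3 sets × 10 porosities): biconvex tablets probed
  through their axial centre, whose porosity is set a relative ±10 % off
  the nominal porosity (multiplicative, `f_c = 1.1f` / `0.9f`; an additive
  reading would exceed physical porosity at the high end). n_eff is
  generated at the centre porosity with exactly spherical pores (L = 1/3)
  and fitted against the nominal porosities. The mismatch masquerades as a
  pore-shape change: fitted L ≈ 0.499 / 0.158 instead of 1/3, while the
  adjusted R² stays at 0.9993 / 0.9997 — a near-perfect fit with badly
  biased parameters, which is exactly why the bounds-based validity check
  exists.

## What the synthetic generator does and does not emulate

`gen_set` produces exact forward-model data: no measurement noise, no
`n_s` dispersion, no porosity uncertainty from weighing or geometry, and a
single deterministic `n_eff` per tablet rather than a band average over a
spectrum. Passing tests therefore demonstrate correctness of the algebra,
the estimators and the bounds logic, and the *systematic* error mechanisms
above — they do not quantify robustness to experimental noise. The bounds
clamping policy and the "flagged" pathways exist precisely for the noisy
real-data case and are exercised with constructed inputs.

## Numerical and design choices

* Forward solve root selection by the Wiener bracket with a 1e−9 relative
  tolerance; endpoint L handled by the Wiener closed forms.
* Grid tie-breaking toward smaller L; all grids generated as integer
  multiples of the step to avoid accumulation error.
* Geometry: biconvex tablet volume is a cylinder of height H − 2h plus two
  spherical caps, each πh²(3C − h)/3; the thickness H is total face-to-face
  height. True densities are in g cm⁻³. Interfaces accept 'cm-g' or 'mm-mg'
  conventions and results are invariant under the switch.
* Band averaging of spectra uses a closed frequency interval
  (default 0.4–0.8 THz, both edges inclusive).

## Known limitations

* No uncertainty quantification on fitted parameters (no bootstrap or
  profile intervals).
* The mAB-EMA constraint is enforced at sample porosities only; between
  samples extreme gradients could momentarily leave [0, 1] (clipped when
  evaluated).
* The pore-shape sweep's goodness-of-fit at extreme gradients depends on
  the R² convention; the package reports the centred-n_eff convention that
  matches the density-study reference values, and the honest minimum over
  the sweep is far below 0.99 (see above) — a constant-L fit simply cannot
  describe those sets well.
* Dispersion of `n_s` across the band and multi-phase pore structures are
  out of scope.
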