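# Methods

`myostiff` estimates the passive stiffness of left-ventricular (LV)
myocardium from organ-level measurements.  The pipeline has two halves: a
reduced-order forward model that simulates end-diastolic pressure–volume
relationships (EDPVRs) for parameterized heart geometries, and a neural
inverse surrogate trained on simulated (geometry, fiber architecture,
EDPVR) → (stiffness) pairs.  This note records the models, the parameters
that matter, the numerical choices, and the known limitations.

## Constitutive model

Myocardium is modelled as an incompressible, transversely isotropic
hyperelastic solid with stored energy

```
Psi = a/(2b) exp[b (I1 − 3)] + a_f/(2 b_f) { exp[b_f (I4f − 1)^2] − 1 }
```

where `I1 = tr C`, `I4f = f0·(C f0)` is the squared fiber stretch, and
`(a, b, a_f, b_f)` are positive constants (`a`, `a_f` in kPa).  The Cauchy
stress is

```
sigma = a exp[b(I1−3)] B − p I + 2 a_f (I4f−1) exp[b_f (I4f−1)^2] f⊗f .
```

Choices and conventions:

* **Fixed ground matrix.**  `a = 0.22 kPa`, `b = 1.62` are held at healthy
  reference values and only the fiber pair `(a_f, b_f)` varies.  Fitting
  `(a, a_f)` jointly to an EDPVR is ill-posed: stress is linear in the
  stress-like constants, so scaling `(a, a_f)` and the pressure together is
  an exact invariance of the solver, and with `b = b_f` the two terms have
  nearly interchangeable shapes.  `identifiability_report` demonstrates this
  degeneracy (equally good fits, grossly different constants).
* **No tension–compression switch** on the fiber term: the printed stress
  applies for `I4f < 1` as well.  All inflation states used here keep
  `I4f ≥ 1`, so the convention never activates.
* **Exact incompressibility** via `lam_r = 1/(lam_t lam_z)` — the
  semi-analytic solver needs `J = 1` to machine precision, so no penalty
  formulation is used.
* **Energy offset.**  The matrix term is not zero at the reference state;
  `strain_energy` also returns `Psi − Psi(3, 1)` so "zero at reference" is
  well defined.
* The biaxial fit runs on log-parameters (positivity by construction) with
  four starts at the corners of the sampling box; the equibiaxial trace is
  invariant to the in-plane fiber angle (`I4f = lam^2` for any in-plane
  fiber), so transmural angle measurements do not enter it.
* Units: kPa, mm, µl internally; mmHg converted at 1 mmHg = 0.133322 kPa.

## Idealized anatomy

The geometry generator emulates a library of rat-scale biventricular
anatomies.  A *parent* heart is a pair of truncated semi-ellipsoids of
revolution — LV endocardium inside a fixed epicardium — plus a crescent RV
cavity (an angular sector of a band under the epicardium over the basal 80%
of the long axis).  Children resize the LV and RV endocardial surfaces in
the short-axis plane by factors `f_LV`, `f_RV` while the epicardium stays
fixed.  Default parent ranges (mm, rad): `R_epi ∈ (3.6, 4.4)`,
`Z_epi ∈ (11.5, 13.5)`, `R_lv ∈ (1.78, 1.88)`, `Z_lv ∈ (9.3, 10.1)`,
`rv_sector ∈ (1.0, 2.0)`, `rv_thickness_frac ∈ (0.3, 0.5)`.  The tight LV
ranges are deliberate: with `f_LV² ∈ (0.49, 2.56)` they put the unloaded LV
cavity volume span at roughly 30–190 µl, i.e. from ~35 µl to about five
times that, across the library.

Twelve scalar features describe a geometry: LV volume/endocardial area, RV
volume/endocardial area, six equally spaced short-axis slice areas, and
epicardial volume/area.  Slice areas are **epicardium-enclosed**
cross-sections (robust to chamber resizing; the basal slice sits on the
truncation plane, the sixth at 5/6 of the apex distance — the apex point
itself has zero area).  Ellipsoid areas are surfaces of revolution
integrated in an angle parameterization (smooth at the apex, rel. tol.
1e-10); RV quantities use quadrature at rel. tol. 1e-8.  Surface areas are
lateral only (no basal annulus).  The RV is a geometric feature generator
only — it is never pressurized (see Limitations).

Fiber architecture is rule-based: the helix angle turns linearly with
transmural depth from `theta_endo ∈ (0, π/2)` to `theta_epi ∈ (−π/2, 0)`,
discretized into four layers at their midpoint depths.

## Reduced-order inflation solver

For mechanics the LV wall is reduced to an equivalent thick-walled cylinder:
length `L = Z_epi`, inner radius preserving the LV cavity volume, outer
radius preserving the wall volume `Epi_V − LV_V − RV_V`.  With the base
fixed axially (`lam_z = 1`, no torsion) incompressibility gives
`r(R)² = r_i² + R² − R_i²`, and the deformed inner radius at pressure `P`
solves the radial equilibrium integral

```
P = ∫_{R_i}^{R_o} (sigma_tt − sigma_rr) (R / r²) dR .
```

Numerics: 8-point Gauss–Legendre quadrature per fiber layer (piecewise
helix angle), Brent root-finding in `r_i` warm-started along the 100-step
pressure ramp (0.3…30 mmHg), bracket expansion capped at `10 R_i`.  During
bracketing, exponent arguments are clamped at 700 and the integrand at
1e12 so trial radii far beyond equilibrium stay finite; admissible solutions
sit orders of magnitude below both clamps.  Volumes at a given pressure are
independent of the step count (each step is solved to tolerance; the ramp
only seeds brackets), and doubling the quadrature order moves volumes by
less than 0.1%.

Fiber stress curves integrate `sigma_rr` transmurally (cumulative trapezoid
on a 24-point-per-layer profile), recover the pointwise hydrostatic
pressure, and report the transmural maximum of `sigma_ff = f̂·sigma·f̂`
together with the fiber Green strain `E_ff = (I4f − 1)/2` at that point.

The inverse fitter is Levenberg–Marquardt on volume residuals with
log-transformed parameters (xtol 1e-8, ftol 1e-10, ≤200 iterations).  One
caveat: when an initialization drives `b_f` toward zero, the log
parameterization flattens (`∂/∂ log b_f → 0`) and LM can stall at a
spurious point; multi-start fitting surfaces this through the dispersion
reported by `identifiability_report`.

## Sampling and the training corpus

Six design dimensions are sampled by Latin hypercube (one sample per
equal-probability interval per dimension, uniform jitter within the
interval): `f_LV, f_RV ∈ (0.7, 1.6)`, `theta_endo ∈ (0, π/2)`,
`theta_epi ∈ (−π/2, 0)`, `a_f ∈ (0.01, 100) kPa`, `b_f ∈ (0.01, 20)`.
Samples are assigned round-robin over the 25-parent library (preserving the
"25 parents × resizing" structure rather than sampling the parent as a 7th
dimension).  Each example pairs a 114-vector (12 geometric features, 2
fiber angles, 100 EDPVR volumes) with its generating `(a_f, b_f)`.  The
corpus is deterministic given the three seeds (parents, design, split).

## Universal EDPVR and single-point reconstruction

Normalizing each curve by `Vn = (V − V0)/(V30 − V0)` and pooling a log–log
linear fit of `P = An Vn^Bn` (points with `Vn > 0.01`) yields the universal
curve.  A full EDPVR is reconstructed from one end-diastolic point via the
empirical unloaded-volume relation `V0 = V_ED (0.6 − 0.006 P_ED)`, the
universal estimate `V30 = V0 + (V_ED − V0)/ (P_ED/An)^{1/Bn}`, and the
power law `P = alpha V^beta` anchored at `(P_ED, V_ED)` and `(30, V30)`.
The empirical constants (0.6, 0.006, the 0.01 floor) are configuration, not
code.  Two caveats, both measured by the test suite: (i) the absolute-volume
power law can dip below the estimated `V0` at very low pressure, so the
"volumes exceed V0" invariant is a warning rather than an error for
reconstructed curves; (ii) reconstruction accuracy is excellent near the
anchor pressure (≤ ~10% within 15–25 mmHg for every corpus curve) but
degrades to ~40% at 5 mmHg for very stiff chambers, because the empirical
V0 relation presumes compliant ventricles.

## The inverse surrogate

A feed-forward network maps the 114 inputs to `(a_f, b_f)`: ReLU hidden
layers (default 2×1024; the scaled study uses 2×512), inputs standardized
per column with training-row statistics, targets normalized by their
maximum absolute value, mean-absolute-error loss summed over the two
targets, Adam at learning rate 1e-4 with batch size 32.  Ten percent of the
training rows form a validation holdout; the weights with the lowest
validation loss across the epoch budget are kept (best-checkpoint early
stopping — the budget is never cut short, the best epoch is selected after
the fact).  The engine is a compact numpy implementation (float32,
He-normal seeded initialization); training is deterministic given the
configuration seed.  Predictions are clipped below at 0.01 (the sampling
floor) with a warning.

Metrics follow the standard definitions: MAE on normalized targets
(summed over targets, averaged over cases), NMAE as percent of each
target's observed range, and the coefficient of determination R² in
percent.  Structure scans use 10-fold cross-validation on the training
portion with a reduced epoch budget.

Permutation feature importance reports the *degradation* of the MAE score
when one input column is shuffled, averaged over K = 10 seeded repetitions
(positive = important; a formula written with an error score has the
opposite sign, which would render important features negative).  The
feature-reduction workflow retrains with only LV volume/area, the two fiber
angles and the EDPVR block (input width 104) under identical
hyperparameters.

## Study sizes

The bundled study (test suite and `scripts/acceptance.py`) runs 1,200
LHS examples with a 100-example test split and a 2×512 network for 2,000
epochs — about 11 minutes on one CPU for both the full-feature and
reduced-feature trainings.  These sizes are the package's scaled standard
conditions; the full-scale configuration (2,500 examples, 2×1024, 10,000
epochs) is available through `StudyConfig`/`SurrogateConfig`.

## Known limitations

* **Compliance of the reduced-order solver.**  A one-dimensional stretching
  cylinder gains cavity volume only by straining the wall.  A real (or
  finite-element) ventricle also gains volume by shape change and axial
  elongation at nearly constant tissue strain, which keeps its EDPVR
  excursion substantial even when the tissue is stiff.  Consequently, for
  `a_f` above roughly 20 kPa the simulated chambers here inflate by only
  ~10–50% of `V0` over 30 mmHg, the fiber-exponent `b_f` has very little
  leverage on the curve (a 10% change in `b_f` moves volumes by well under
  1% of the curve span), and the surrogate cannot recover `b_f` accurately
  over the stiff majority of the sampling range — held-out R² for `b_f`
  plateaus far below that of `a_f`, and gradient-boosted references trained
  on the same corpus hit the same ceiling.  This is an information limit of
  the corpus, not an optimization failure; it also feeds correlated error
  into `a_f` along the known `a_f`–`b_f` valley.  Forward stress curves are
  insensitive to this degeneracy, which is why predicted-vs-actual stress
  consistency remains excellent even for the worst-predicted cases.  A
  volumetric finite-element stage (or a reduced model with a calibrated
  shape-change mode) would be required to restore `b_f` identifiability at
  high stiffness; inventing such a mode without data to calibrate it was
  deliberately avoided.
* **No RV pressurization and no septal coupling**: the RV contributes
  geometric features only.
* **No torsion, single axial constraint** (`lam_z = 1`) interpreting the
  fixed-base boundary condition; helical fibers would induce a θ–z shear
  reacted at the base.
* The synthetic corpus is noiseless and geometrically idealized; passing
  tests demonstrate correctness of the pipeline and reproduction of the
  study's qualitative structure, not performance on imaging-derived
  anatomies.
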