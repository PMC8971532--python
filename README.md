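# myostiff

Passive myocardial stiffness from pressure–volume data.

`myostiff` is a research library for estimating the passive stiffness of
left-ventricular (LV) myocardium — the fiber constants `(a_f, b_f)` of a
reduced Holzapfel–Ogden model — from measurements that are obtainable in
vivo: a handful of geometric features, two transmural fiber helix angles,
and the end-diastolic pressure–volume relationship (EDPVR).  It is aimed at
cardiovascular biomechanics researchers who want a transparent, fully
scripted alternative to image-based inverse finite-element pipelines for
studying the EDPVR→stiffness inverse problem.

## The model

Myocardium is an incompressible, transversely isotropic hyperelastic solid:

    Ψ = a/(2b) · exp[b(I₁−3)] + a_f/(2b_f) · {exp[b_f(I₄f−1)²] − 1}

with `I₁ = tr C`, `I₄f = f₀·(C f₀)`.  The ground-matrix constants are fixed
(`a = 0.22 kPa`, `b = 1.62`) because `(a, a_f)` are not jointly
identifiable from an EDPVR — the package demonstrates this degeneracy
explicitly — leaving `(a_f, b_f)` as the estimation targets.

Around this constitutive core the package provides:

* an idealized biventricular geometry generator (25-parent library,
  LV/RV resizing, 12 geometric features, rule-based fiber helicity);
* a semi-analytic forward solver — inflation of an equivalent
  fiber-reinforced thick-walled cylinder to 30 mmHg in 100 steps — for
  EDPVRs and transmural fiber-stress curves;
* Latin hypercube sampling and assembly of (geometry, fibers, EDPVR) →
  (a_f, b_f) training corpora;
* a feed-forward neural surrogate (ReLU, Adam, MAE loss, best-validation
  checkpoint) that inverts the forward map, with NMAE/R² metrics and
  ten-fold cross-validation scans;
* Levenberg–Marquardt inverse fitting and parameter-identifiability
  reports;
* a Klotz-style universal EDPVR and single-point curve reconstruction, so
  a full curve (and hence a stiffness estimate) follows from one measured
  (P_ED, V_ED) pair;
* permutation feature importance and a feature-reduction retraining
  workflow.

## A worked example

Recover fiber constants from an equibiaxial stress–stretch test
(`examples/01_biaxial_fit.py`):

```text
true     a_f = 0.806 kPa, b_f = 0.470
recovered a_f = 0.806 kPa, b_f = 0.470 (rms residual 2.03e-17 kPa)
```

Simulate an EDPVR for an idealized rat heart
(`examples/02_simulate_edpvr.py`):

```text
LV cavity volume (unloaded) V0 =    82.1 ul
V( 6.0 mmHg) =   112.0 ul
V(15.0 mmHg) =   146.6 ul
V(30.0 mmHg) =   180.4 ul
```

The 100 simulated volumes are exactly the EDPVR features the surrogate
consumes; stiffer fibers shift every loaded volume downward.

Why only `(a_f, b_f)` are fit (`examples/05_identifiability.py`):

```text
init {'a': 0.05, 'a_f': 50.0} -> a = 1.47e-198 kPa, a_f = 11.8 kPa, relative rms 0.06%
init {'a': 20.0, 'a_f': 0.1} -> a = 6.69 kPa, a_f = 1.13e-48 kPa, relative rms 0.32%
(a, a_f) identifiable: False

init {'a_f': 0.1, 'b_f': 0.1} -> a_f = 5, b_f = 2
init {'a_f': 10.0, 'b_f': 10.0} -> a_f = 5, b_f = 2
(a_f, b_f) identifiable: True (dispersion 4.44e-16)
```

Two `(a, a_f)` fits started far apart both match the target curve to well
under 1% volume error yet land on wildly different constants — equally good
fits, different physics.  The `(a_f, b_f)` pair converges to one answer
from any reasonable start.

The remaining examples cover corpus assembly (`03`), surrogate training
with held-out metrics (`04`), and the single-point clinical pathway (`06`).
A thin CLI mirrors the library (`myostiff --help`): `generate-parents`,
`simulate`, `identify`, `build-dataset`, `train`, `evaluate`, `klotz-fit`,
`klotz-generate`, `importance`, `biaxial-fit`, `run-study`.

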