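"""Reduced Holzapfel-Ogden transversely isotropic hyperelastic model.

The myocardium is modelled as an incompressible solid with one preferred
(myofiber) direction ``f0``.  The stored-energy density is

    Psi = a/(2b) * exp[b (I1 - 3)] + a_f/(2 b_f) * {exp[b_f (I4f - 1)^2] - 1}

with I1 = tr C and I4f = f0 . (C f0).  ``a`` and ``a_f`` carry stress units
(kPa); ``b`` and ``b_f`` are dimensionless.  The ground-matrix constants are
fixed at a = 0.22 kPa, b = 1.62 by default so that only the fiber constants
(a_f, b_f) vary, which removes the a / a_f identifiability degeneracy when
fitting to a pressure-volume curve alone.

The module covers the diagonal-deformation states used throughout the
package (inflation of a cylinder, equibiaxial sheet stretch), the equibiaxial
first-Piola-Kirchhoff trace used for ex-vivo comparison, and nonlinear
least-squares recovery of (a_f, b_f) from biaxial data.

Note the exponential fiber term in the printed stress applies for I4f < 1 as
well (no tension-only switch); the loading states produced by inflation keep
I4f >= 1 so the convention is inert there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MaterialParams",
    "DeformationState",
    "BiaxialData",
    "CauchyStress",
    "BiaxialFit",
    "invariants_from_stretches",
    "strain_energy",
    "cauchy_stress",
    "equibiaxial_trace",
    "fit_biaxial",
    "read_biaxial",
    "write_biaxial",
]

#: Default ground-matrix constants (kPa, -) for healthy LV myocardium.
DEFAULT_A = 0.22
DEFAULT_B = 1.62


@dataclass(frozen=True)
class MaterialParams:
    """The four positive material constants of the reduced model."""

    a: float = DEFAULT_A      # kPa, ground matrix stiffness scale
    b: float = DEFAULT_B      # -, ground matrix exponent
    a_f: float = 1.0          # kPa, fiber stiffness scale
    b_f: float = 1.0          # -, fiber exponent

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_f", "b_f"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"material constant {name} must be strictly positive, got {v}")

    def scaled(self, c: float) -> "MaterialParams":
        """Return params with both stress-like constants scaled by ``c``."""
        return MaterialParams(self.a * c, self.b, self.a_f * c, self.b_f)


def invariants_from_stretches(lam_r: float, lam_t: float, lam_z: float,
                              alpha: float) -> tuple[float, float]:
    """Invariants (I1, I4f) for a shear-free diagonal deformation.

    The fiber lies in the theta-z plane at helix angle ``alpha`` (radians)
    from the circumferential direction:
    I1 = lam_r^2 + lam_t^2 + lam_z^2 and
    I4f = lam_t^2 cos^2(alpha) + lam_z^2 sin^2(alpha).
    """
    lam_r, lam_t, lam_z = float(lam_r), float(lam_t), float(lam_z)
    if min(lam_r, lam_t, lam_z) <= 0:
        raise ValueError("stretches must be strictly positive")
    i1 = lam_r ** 2 + lam_t ** 2 + lam_z ** 2
    c, s = math.cos(alpha), math.sin(alpha)
    i4f = lam_t ** 2 * c * c + lam_z ** 2 * s * s
    return i1, i4f


@dataclass(frozen=True)
class DeformationState:
    """A diagonal (shear-free) incompressible deformation state.

    Principal stretches refer to the (r, theta, z) axes of the cylinder or
    the (thickness, 1, 2) axes of a sheet; the fiber lies in the theta-z
    plane at helix angle ``alpha``.  ``p`` is the hydrostatic pressure (kPa).
    """

    lam_r: float
    lam_t: float
    lam_z: float
    alpha: float = 0.0
    p: float = 0.0

    J_TOL = 1e-12

    def __post_init__(self) -> None:
        if min(self.lam_r, self.lam_t, self.lam_z) <= 0:
            raise ValueError("stretches must be strictly positive")
        if abs(self.J - 1.0) > 1e-8:
            raise ValueError(f"incompressibility violated: J = {self.J!r}")

    @classmethod
    def incompressible(cls, lam_t: float, lam_z: float, alpha: float = 0.0,
                       p: float = 0.0) -> "DeformationState":
        """Build a state with lam_r = 1/(lam_t lam_z) so J = 1 exactly."""
        return cls(1.0 / (lam_t * lam_z), lam_t, lam_z, alpha, p)

    @property
    def J(self) -> float:
        return self.lam_r * self.lam_t * self.lam_z

    @property
    def invariants(self) -> tuple[float, float]:
        return invariants_from_stretches(self.lam_r, self.lam_t, self.lam_z, self.alpha)


def strain_energy(state: DeformationState, params: MaterialParams) -> tuple[float, float]:
    """Energy density Psi (kPa) and the reference-measured energy Psi_hat.

    The printed matrix term is not pinned to zero at I1 = 3, so the second
    return subtracts the reference-state value: Psi_hat = Psi - Psi(3, 1),
    giving Psi_hat = 0 at the undeformed state.
    """
    i1, i4f = state.invariants
    psi = _psi(i1, i4f, params)
    psi_ref = params.a / (2.0 * params.b)  # Psi(I1=3, I4f=1)
    return psi, psi - psi_ref


def _psi(i1: float, i4f: float, params: MaterialParams) -> float:
    matrix = params.a / (2.0 * params.b) * math.exp(params.b * (i1 - 3.0))
    fiber = params.a_f / (2.0 * params.b_f) * math.expm1(params.b_f * (i4f - 1.0) ** 2)
    return matrix + fiber


class CauchyStress(NamedTuple):
    """Diagonal Cauchy stress components and the fiber-direction stress (kPa)."""

    rr: float
    tt: float
    zz: float
    ff: float


def cauchy_stress(state: DeformationState, params: MaterialParams) -> CauchyStress:
    """Cauchy stress for a diagonal state with fiber f = (0, lam_t cos a, lam_z sin a).

    sigma = a exp[b(I1-3)] B - p I + 2 a_f (I4f - 1) exp[b_f (I4f - 1)^2] f (x) f

    Returns the (rr, tt, zz) diagonal components and sigma_ff = fhat.sigma.fhat.
    The fiber term also produces a theta-z shear component when
    sin(alpha) cos(alpha) != 0; it does not enter the returned components
    other than through sigma_ff.
    """
    if abs(state.J - 1.0) > 1e-8:
        raise ValueError("cauchy_stress requires an isochoric state (J = 1)")
    i1, i4f = state.invariants
    e_mat = params.a * math.exp(params.b * (i1 - 3.0))
    fib = 2.0 * params.a_f * (i4f - 1.0) * math.exp(params.b_f * (i4f - 1.0) ** 2)
    c2 = math.cos(state.alpha) ** 2
    s2 = math.sin(state.alpha) ** 2
    lt2, lz2, lr2 = state.lam_t ** 2, state.lam_z ** 2, state.lam_r ** 2
    p = state.p
    s_rr = e_mat * lr2 - p
    s_tt = e_mat * lt2 - p + fib * lt2 * c2
    s_zz = e_mat * lz2 - p + fib * lz2 * s2
    # fhat . B fhat = (lam_t^4 c^2 + lam_z^4 s^2)/I4f;  fhat.(f(x)f).fhat = I4f
    s_ff = e_mat * (lt2 ** 2 * c2 + lz2 ** 2 * s2) / i4f - p + fib * i4f
    return CauchyStress(s_rr, s_tt, s_zz, s_ff)


def equibiaxial_trace(lam, params: MaterialParams):
    """Trace of the 1st Piola-Kirchhoff stress, P11 + P22, under equibiaxial stretch.

    In-plane equibiaxial stretch (lam, lam, lam^-2) of a sheet with in-plane
    fibers; plane stress through the thickness fixes the hydrostatic pressure
    p = a exp[b(I1-3)] lam^-4.  The result is independent of the in-plane
    fiber angle because I4f = lam^2 for any in-plane fiber.  Accepts scalars
    or arrays of lam >= 1; returns kPa.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 1.0):
        raise ValueError("equibiaxial stretch requires lam >= 1")
    i1 = 2.0 * lam_arr ** 2 + lam_arr ** -4
    e_mat = params.a * np.exp(params.b * (i1 - 3.0))
    i4m1 = lam_arr ** 2 - 1.0
    fib = 2.0 * params.a_f * i4m1 * np.exp(params.b_f * i4m1 ** 2)
    # sigma11 + sigma22 with p eliminated; P = J sigma F^-T so P11+P22 = (s11+s22)/lam
    trace_sigma = 2.0 * e_mat * (lam_arr ** 2 - lam_arr ** -4) + fib * lam_arr ** 2
    out = trace_sigma / lam_arr
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BiaxialData:
    """Measured equibiaxial response: stretches and P11 + P22 (kPa)."""

    stretches: np.ndarray
    trace_P: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretches, dtype=float)
        tr = np.asarray(self.trace_P, dtype=float)
        if lam.shape != tr.shape or lam.ndim != 1:
            raise ValueError("stretches and trace_P must be 1-D of equal length")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretches must be strictly increasing")
        if np.any(lam < 1.0):
            raise ValueError("stretches must be >= 1")
        object.__setattr__(self, "stretches", lam)
        object.__setattr__(self, "trace_P", tr)

    def __len__(self) -> int:
        return len(self.stretches)


@dataclass(frozen=True)
class BiaxialFit:
    a_f: float
    b_f: float
    rms_residual: float
    converged: bool
    n_iterations: int


# Sampling-range corners used as multi-start seeds for the biaxial fit.
_AF_RANGE = (0.01, 100.0)
_BF_RANGE = (0.01, 20.0)


def fit_biaxial(data: BiaxialData, a: float = DEFAULT_A, b: float = DEFAULT_B) -> BiaxialFit:
    """Recover (a_f, b_f) from an equibiaxial trace by nonlinear least squares.

    The matrix constants (a, b) stay fixed.  The fit runs on log-parameters
    (positivity by construction) from four starts at the corners of the
    sampling range and keeps the best converged solution.
    """
    loaded = data.stretches > 1.0
    if int(loaded.sum()) < 3:
        raise ValueError("need at least 3 data points with stretch > 1")

    lam = data.stretches
    meas = data.trace_P

    def resid(logx):
        with np.errstate(over="ignore"):
            a_f, b_f = np.exp(np.clip(logx, -600.0, 600.0))
            if not (np.isfinite(a_f) and np.isfinite(b_f) and a_f > 0 and b_f > 0):
                return np.full_like(meas, 1e6)
            model = equibiaxial_trace(lam, MaterialParams(a, b, a_f, b_f))
        return np.where(np.isfinite(model), model - meas, 1e6)

    best = None
    for af0 in _AF_RANGE:
        for bf0 in _BF_RANGE:
            res = least_squares(resid, np.log([af0, bf0]), method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
            if best is None or res.cost < best.cost:
                best = res
    a_f, b_f = np.exp(best.x)
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return BiaxialFit(float(a_f), float(b_f), rms, bool(best.status > 0), int(best.nfev))


def read_biaxial(path) -> BiaxialData:
    """Read two-column delimited text with header ``stretch,trace_P_kPa``."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    return BiaxialData(df["stretch"].to_numpy(), df["trace_P_kPa"].to_numpy())


def write_biaxial(data: BiaxialData, path) -> None:
    import pandas as pd

    pd.DataFrame({"stretch": data.stretches, "trace_P_kPa": data.trace_P}).to_csv(
        path, index=False)
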