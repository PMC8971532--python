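"""Idealized biventricular anatomy and its scalar features.

Stands in for an MRI-derived geometry library: each "parent" heart is a pair
of truncated semi-ellipsoids of revolution (LV endocardium inside a fixed
epicardium, both truncated at the base plane z = 0) plus a crescent-shaped
RV cavity parameterized as an angular sector of a band under the epicardium.
Children are produced by resizing the LV and RV endocardial surfaces in the
short-axis (X-Y) plane while keeping the epicardium fixed, exactly the
degrees of freedom that the resize factors (f_LV, f_RV) control.

Twelve scalar features describe a geometry: LV cavity volume and endocardial
area, RV cavity volume and endocardial area, the epicardium-enclosed areas of
six equally spaced short-axis slices from base toward apex, and the interior
volume and surface area of the epicardium.  Units: mm, mm^2, ul (1 mm^3).

For mechanics the LV wall is reduced to an equivalent thick-walled cylinder
that preserves the lumen volume and the wall volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ParentGeometry",
    "HeartGeometry",
    "GeometricFeatures",
    "FiberArchitecture",
    "CylinderModel",
    "DEFAULT_PARENT_RANGES",
    "FEATURE_NAMES",
    "make_parent",
    "make_parent_library",
    "resize",
    "geometric_features",
    "fiber_layers",
    "equivalent_cylinder",
    "read_parent_library",
    "write_parent_library",
]

#: Canonical order of the 12 geometric features.
FEATURE_NAMES = ("LV_V", "LV_A", "RV_V", "RV_A",
                 "S_A1", "S_A2", "S_A3", "S_A4", "S_A5", "S_A6",
                 "Epi_V", "Epi_A")

#: Default sampling ranges for parent hearts (rat scale).  Chosen so that the
#: unloaded LV cavity volume across 25 parents x f_LV in (0.7, 1.6) spans
#: roughly 35 ul up to about five times that.
DEFAULT_PARENT_RANGES: Mapping[str, tuple[float, float]] = {
    "R_epi": (3.6, 4.4),            # mm
    "Z_epi": (11.5, 13.5),          # mm
    "R_lv": (1.78, 1.88),           # mm
    "Z_lv": (9.3, 10.1),            # mm
    "rv_sector": (1.0, 2.0),        # rad
    "rv_thickness_frac": (0.3, 0.5),
}

#: Fraction of the long axis covered by the RV crescent (base toward apex).
RV_AXIAL_EXTENT = 0.8


@dataclass(frozen=True)
class ParentGeometry:
    """A parent heart: fixed epicardium, unscaled LV/RV endocardial shapes."""

    R_epi: float   # epicardial equatorial radius, mm
    Z_epi: float   # epicardial base-to-apex length, mm
    R_lv: float    # LV endocardial equatorial radius, mm
    Z_lv: float    # LV endocardial apex depth, mm
    rv_sector: float          # RV crescent angular extent, rad
    rv_thickness_frac: float  # RV cavity radial fraction of the epi radius
    parent_id: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.R_lv < self.R_epi:
            raise ValueError("need 0 < R_lv < R_epi")
        if not 0 < self.Z_lv < self.Z_epi:
            raise ValueError("need 0 < Z_lv < Z_epi")
        if not 0 < self.rv_sector < math.pi:
            raise ValueError("need 0 < rv_sector < pi")
        if not 0 < self.rv_thickness_frac < 1:
            raise ValueError("need 0 < rv_thickness_frac < 1")


@dataclass(frozen=True)
class HeartGeometry:
    """A parent resized in the X-Y plane by (f_LV, f_RV); epicardium fixed."""

    parent: ParentGeometry
    f_LV: float = 1.0
    f_RV: float = 1.0

    def __post_init__(self) -> None:
        if not 0.7 <= self.f_LV <= 1.6 or not 0.7 <= self.f_RV <= 1.6:
            raise ValueError("resize factors must lie within [0.7, 1.6]")
        if self.f_LV * self.parent.R_lv >= self.parent.R_epi:
            raise ValueError("resized LV endocardium would exit the epicardium")
        if self.f_RV * self.parent.rv_thickness_frac >= 1.0:
            raise ValueError("resized RV cavity would exit the epicardium")

    # -- shape profiles (radius as a function of depth z from the base) -----
    @property
    def lv_radius(self) -> float:
        return self.f_LV * self.parent.R_lv

    def r_epi(self, z):
        p = self.parent
        return p.R_epi * np.sqrt(np.clip(1.0 - (z / p.Z_epi) ** 2, 0.0, None))

    def r_lv(self, z):
        p = self.parent
        return self.lv_radius * np.sqrt(np.clip(1.0 - (z / p.Z_lv) ** 2, 0.0, None))


def make_parent(seed: int, ranges: Mapping[str, tuple[float, float]] | None = None,
                parent_id: int = 0) -> ParentGeometry:
    """Seeded uniform draw of a parent heart from per-field ranges."""
    ranges = dict(DEFAULT_PARENT_RANGES if ranges is None else ranges)
    rng = np.random.default_rng(seed)
    vals = {}
    for name in ("R_epi", "Z_epi", "R_lv", "Z_lv", "rv_sector", "rv_thickness_frac"):
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"inverted range for {name}: ({lo}, {hi})")
        vals[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return ParentGeometry(parent_id=parent_id, **vals)


def make_parent_library(n: int = 25, seed: int = 0,
                        ranges: Mapping[str, tuple[float, float]] | None = None
                        ) -> list[ParentGeometry]:
    """Library of ``n`` parents with per-parent seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [make_parent(child, ranges, parent_id=i)
            for i, child in enumerate(ss.spawn(n))]


def resize(parent: ParentGeometry, f_LV: float, f_RV: float) -> HeartGeometry:
    """Resize the LV and RV endocardial surfaces in the X-Y plane."""
    return HeartGeometry(parent, f_LV, f_RV)


@dataclass(frozen=True)
class GeometricFeatures:
    LV_V: float
    LV_A: float
    RV_V: float
    RV_A: float
    S_A: tuple  # six short-axis epicardium-enclosed areas, base -> apex
    Epi_V: float
    Epi_A: float

    def to_array(self) -> np.ndarray:
        return np.array([self.LV_V, self.LV_A, self.RV_V, self.RV_A,
                         *self.S_A, self.Epi_V, self.Epi_A])

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.to_array()))


def _semi_ellipsoid_volume(R: float, Z: float) -> float:
    return 2.0 / 3.0 * math.pi * R * R * Z


def _semi_ellipsoid_area(R: float, Z: float) -> float:
    """Lateral surface area of the half-ellipsoid r = R sqrt(1 - (z/Z)^2), z in (0, Z).

    Parameterized as r = R cos t, z = Z sin t to keep the integrand smooth at
    the apex; quadrature relative tolerance 1e-10.
    """
    def ds(t):
        return 2.0 * math.pi * R * np.cos(t) * np.sqrt(
            R * R * np.sin(t) ** 2 + Z * Z * np.cos(t) ** 2)

    val, _ = quad(ds, 0.0, math.pi / 2.0, epsabs=0.0, epsrel=1e-10)
    return val


def geometric_features(geom: HeartGeometry) -> GeometricFeatures:
    """The 12 scalar features, by closed form or quadrature (rel. tol 1e-8)."""
    p = geom.parent
    lv_r = geom.lv_radius

    lv_v = _semi_ellipsoid_volume(lv_r, p.Z_lv)
    lv_a = _semi_ellipsoid_area(lv_r, p.Z_lv)
    epi_v = _semi_ellipsoid_volume(p.R_epi, p.Z_epi)
    epi_a = _semi_ellipsoid_area(p.R_epi, p.Z_epi)

    # epicardium-enclosed short-axis areas at z_k = (k-1)/6 * Z_epi
    zk = np.arange(6) / 6.0 * p.Z_epi
    s_a = tuple(float(math.pi * r * r) for r in geom.r_epi(zk))

    rv_v, rv_a = _rv_features(geom)
    return GeometricFeatures(lv_v, lv_a, rv_v, rv_a, s_a, epi_v, epi_a)


def _rv_features(geom: HeartGeometry) -> tuple[float, float]:
    """Volume and endocardial area of the RV crescent.

    The cavity occupies the angular sector ``rv_sector`` of the band between
    r_in(z) = (1 - t) r_epi(z) and the epicardium, with effective radial
    fraction t = rv_thickness_frac * f_RV, over z in (0, 0.8 Z_epi).
    """
    p = geom.parent
    t = p.rv_thickness_frac * geom.f_RV
    z_max = RV_AXIAL_EXTENT * p.Z_epi
    shrink = 1.0 - t

    def dv(z):
        re = geom.r_epi(z)
        return 0.5 * p.rv_sector * (re * re - (shrink * re) ** 2)

    rv_v, _ = quad(dv, 0.0, z_max, epsabs=0.0, epsrel=1e-8)

    def da(z):
        # inner (endocardial) surface r_in(z) = shrink * r_epi(z)
        r_in = shrink * geom.r_epi(z)
        drdz = -shrink * p.R_epi ** 2 * z / (p.Z_epi ** 2 * geom.r_epi(z))
        return p.rv_sector * r_in * np.sqrt(1.0 + drdz ** 2)

    rv_a, _ = quad(da, 0.0, z_max, epsabs=0.0, epsrel=1e-8)
    return float(rv_v), float(rv_a)


@dataclass(frozen=True)
class FiberArchitecture:
    """Rule-based transmural helix angles, endocardium to epicardium."""

    theta_endo: float  # rad, in (0, pi/2)
    theta_epi: float   # rad, in (-pi/2, 0)
    n_layers: int = 4
    layer_angles: tuple = field(default=None)

    def __post_init__(self) -> None:
        if not 0 < self.theta_endo < math.pi / 2:
            raise ValueError("theta_endo must lie in (0, pi/2)")
        if not -math.pi / 2 < self.theta_epi < 0:
            raise ValueError("theta_epi must lie in (-pi/2, 0)")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.layer_angles is None:
            d = (np.arange(self.n_layers) + 0.5) / self.n_layers
            angles = self.theta_endo + (self.theta_epi - self.theta_endo) * d
            object.__setattr__(self, "layer_angles", tuple(float(a) for a in angles))


def fiber_layers(theta_endo: float, theta_epi: float, n_layers: int = 4) -> FiberArchitecture:
    """Helix angle per layer: linear in layer-midpoint transmural depth.

    Depth d runs 0 at the endocardium to 1 at the epicardium; layer m
    (m = 1..n) sits at d_m = (m - 1/2)/n and carries
    theta(d_m) = theta_endo + (theta_epi - theta_endo) d_m.
    """
    return FiberArchitecture(theta_endo, theta_epi, n_layers)


@dataclass(frozen=True)
class CylinderModel:
    """Equivalent thick-walled cylinder (reference configuration)."""

    R_i: float  # inner radius, mm
    R_o: float  # outer radius, mm
    L: float    # length, mm

    def __post_init__(self) -> None:
        if not 0 < self.R_i < self.R_o:
            raise ValueError("need 0 < R_i < R_o")
        if self.L <= 0:
            raise ValueError("need L > 0")

    @property
    def lumen_volume(self) -> float:
        return math.pi * self.R_i ** 2 * self.L

    @property
    def wall_volume(self) -> float:
        return math.pi * (self.R_o ** 2 - self.R_i ** 2) * self.L


def equivalent_cylinder(geom: HeartGeometry,
                        features: GeometricFeatures | None = None) -> CylinderModel:
    """Reduce a geometry to a cylinder preserving lumen and LV-wall volumes.

    L is the base-to-apex length; R_i preserves the LV cavity volume and R_o
    preserves the wall volume Epi_V - LV_V - RV_V.
    """
    f = geometric_features(geom) if features is None else features
    L = geom.parent.Z_epi
    wall = f.Epi_V - f.LV_V - f.RV_V
    if wall <= 0:
        raise ValueError("non-positive wall volume; geometry is not realizable")
    R_i = math.sqrt(f.LV_V / (math.pi * L))
    R_o = math.sqrt(R_i ** 2 + wall / (math.pi * L))
    return CylinderModel(R_i, R_o, L)


# ---------------------------------------------------------------------------
# parent library I/O (delimited text, one record per parent)

_PARENT_COLS = ("parent_id", "R_epi", "Z_epi", "R_lv", "Z_lv",
                "rv_sector", "rv_thickness_frac")


def write_parent_library(parents: Sequence[ParentGeometry], path) -> None:
    import pandas as pd

    rows = [{c: getattr(p, c) for c in _PARENT_COLS} for p in parents]
    pd.DataFrame(rows, columns=_PARENT_COLS).to_csv(path, index=False)


def read_parent_library(path) -> list[ParentGeometry]:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    return [ParentGeometry(parent_id=int(r.parent_id), R_epi=r.R_epi, Z_epi=r.Z_epi,
                           R_lv=r.R_lv, Z_lv=r.Z_lv, rv_sector=r.rv_sector,
                           rv_thickness_frac=r.rv_thickness_frac)
            for r in df.itertuples(index=False)]
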