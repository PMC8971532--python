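"""Universal (Klotz-style) EDPVR and single-point curve reconstruction.

Empirically, EDPVRs from very different hearts collapse onto a near-common
shape once the volume axis is normalized between the unloaded volume V0 and
the volume at 30 mmHg, V30:

    Vn(p) = (V(p) - V0) / (V30 - V0),   Vn(30) = 1.

A power law P = An * Vn^Bn fitted over a corpus of normalized curves defines
the universal curve.  With it, a full EDPVR can be reconstructed from a
single measured end-diastolic point (P_ED, V_ED):

    V0  = V_ED (0.6 - 0.006 P_ED)               (empirical unloaded volume)
    V30 = V0 + (V_ED - V0) / (P_ED / An)^(1/Bn)
    P(V) = alpha V^beta, beta = log(P_ED/30) / log(V_ED/V30),
    alpha = 30 / V30^beta

which passes through (P_ED, V_ED) exactly and reaches 30 mmHg at V30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .inflation import EDPVR, standard_pressure_grid

__all__ = [
    "UniversalCurve",
    "KlotzConstants",
    "normalize_curve",
    "fit_universal",
    "edpvr_from_point",
]


@dataclass(frozen=True)
class KlotzConstants:
    """Empirical constants of the single-point reconstruction, exposed for audit."""

    v0_intercept: float = 0.6     # V0/V_ED at zero pressure
    v0_slope: float = 0.006       # per mmHg
    vn_floor: float = 0.01        # Vn cutoff for the log-log universal fit


@dataclass(frozen=True)
class UniversalCurve:
    An: float       # mmHg
    Bn: float       # dimensionless exponent
    fit_r2: float   # pooled log-log fit quality
    constants: KlotzConstants = KlotzConstants()

    def __post_init__(self) -> None:
        if not self.An > 0:
            raise ValueError("An must be positive")
        if not self.Bn > 1:
            raise ValueError("Bn must exceed 1")

    def vn_at(self, p_mmhg):
        return (np.asarray(p_mmhg, float) / self.An) ** (1.0 / self.Bn)

    def to_json(self) -> dict:
        return {"An_mmHg": self.An, "Bn": self.Bn, "fit_r2": self.fit_r2,
                "v0_intercept": self.constants.v0_intercept,
                "v0_slope": self.constants.v0_slope}

    @classmethod
    def from_json(cls, d: dict) -> "UniversalCurve":
        return cls(d["An_mmHg"], d["Bn"], d.get("fit_r2", float("nan")),
                   KlotzConstants(d.get("v0_intercept", 0.6), d.get("v0_slope", 0.006)))


def normalize_curve(curve: EDPVR) -> np.ndarray:
    """Normalized volumes Vn on the curve's pressure grid.

    Requires the curve to reach 30 mmHg; Vn(30) = 1 by construction.
    """
    v30 = curve.volume_at(30.0)
    if curve.pressures[-1] < 30.0 - 1e-9:
        raise ValueError("curve must extend to 30 mmHg")
    if not v30 > curve.V0:
        raise ValueError("V30 must exceed V0")
    return (curve.volumes - curve.V0) / (v30 - curve.V0)


def fit_universal(curves: Sequence[EDPVR],
                  constants: KlotzConstants = KlotzConstants()) -> UniversalCurve:
    """Pooled power-law fit P = An Vn^Bn over a family of normalized curves.

    Linear regression of log P on log Vn over all points with Vn above the
    configured floor (avoids log 0 near the unloaded state).
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    logs_p, logs_v = [], []
    for c in curves:
        vn = normalize_curve(c)
        keep = vn > constants.vn_floor
        logs_p.append(np.log(c.pressures[keep]))
        logs_v.append(np.log(vn[keep]))
    x = np.concatenate(logs_v)
    y = np.concatenate(logs_p)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate pooled data")
    bn, log_an = np.polyfit(x, y, 1)
    yhat = log_an + bn * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot else 1.0
    return UniversalCurve(float(math.exp(log_an)), float(bn), r2, constants)


def reconstruction_coefficients(p_ed: float, v_ed: float,
                                uc: UniversalCurve) -> tuple[float, float, float]:
    """Coefficients (alpha, beta, V0) of the single-point power law P = alpha V^beta.

    The law passes through (P_ED, V_ED) exactly and reaches 30 mmHg at the
    estimated V30.
    """
    if not 0 < p_ed <= 30.0:
        raise ValueError("P_ED must lie in (0, 30] mmHg")
    c = uc.constants
    v0 = v_ed * (c.v0_intercept - c.v0_slope * p_ed)
    if v_ed <= v0:
        raise ValueError("V_ED does not exceed the estimated unloaded volume")
    if abs(p_ed - 30.0) < 1e-12:
        # exact endpoint case: the measurement pins V30 directly
        v30 = v_ed
        beta = uc.Bn  # shape carried by the universal exponent
    else:
        v30 = v0 + (v_ed - v0) / float(uc.vn_at(p_ed))
        beta = math.log(p_ed / 30.0) / math.log(v_ed / v30)
    alpha = 30.0 / v30 ** beta
    return alpha, beta, v0


def edpvr_from_point(p_ed: float, v_ed: float, uc: UniversalCurve,
                     grid_mmhg: np.ndarray | None = None) -> EDPVR:
    """Reconstruct a full EDPVR from a single (P_ED, V_ED) measurement.

    The power law from :func:`reconstruction_coefficients` is sampled by
    inversion, V(p) = (p / alpha)^(1/beta), at the standard pressure grid.
    """
    grid = standard_pressure_grid() if grid_mmhg is None else np.asarray(grid_mmhg, float)
    alpha, beta, v0 = reconstruction_coefficients(p_ed, v_ed, uc)
    volumes = (grid / alpha) ** (1.0 / beta)
    return EDPVR(grid, volumes, V0=v0)
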