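"""End-to-end studies: training, worst-case stress audit, single-point pathway.

``run_training_study`` reproduces the whole pipeline: parent library ->
Latin hypercube design -> forward-simulated corpus -> surrogate training ->
held-out metrics for the full and reduced feature sets -> forward stress
consistency for the worst-predicted test case.

``predict_from_single_point`` is the clinical-style pathway: reconstruct a
full EDPVR from one (P_ED, V_ED) measurement through the universal curve,
assemble the 114-vector and run the surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import anatomy, dataset as ds_mod, inflation, klotz, surrogate
from .anatomy import ParentGeometry
from .constitutive import MaterialParams
from .dataset import Dataset, Example, INPUT_NAMES, TARGET_NAMES
from .importance import reduce_and_retrain
from .klotz import UniversalCurve
from .surrogate import Metrics, SurrogateConfig, TrainedSurrogate

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_training_study",
    "worst_case_stress_check",
    "predict_from_single_point",
    "REDUCED_KEEP",
]

#: Geometric features retained in the reduced model (plus fibers + EDPVR).
REDUCED_KEEP = ("LV_V", "LV_A", "theta_endo", "theta_epi")


@dataclass(frozen=True)
class StudyConfig:
    n_parents: int = 25
    n_samples: int = 2500
    n_test: int = 100
    parent_seed: int = 11
    lhs_seed: int = 22
    split_seed: int = 33
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    n_worst: int = 1


@dataclass
class StudyReport:
    config: StudyConfig
    dataset: Dataset
    model: TrainedSurrogate
    test_metrics: Metrics
    reduced_model: TrainedSurrogate
    reduced_metrics: Metrics
    worst_cases: list                 # (test row, per-case MAE, actual, predicted)
    stress_r2: list                   # % per worst case
    parents: list

    def summary(self) -> dict:
        return {
            "n_examples": len(self.dataset),
            "n_test": len(self.dataset.test_indices),
            "R2_a_f_%": self.test_metrics.r2["a_f"],
            "R2_b_f_%": self.test_metrics.r2["b_f"],
            "NMAE_a_f_%": self.test_metrics.nmae["a_f"],
            "NMAE_b_f_%": self.test_metrics.nmae["b_f"],
            "reduced_R2_a_f_%": self.reduced_metrics.r2["a_f"],
            "reduced_R2_b_f_%": self.reduced_metrics.r2["b_f"],
            "reduced_NMAE_b_f_%": self.reduced_metrics.nmae["b_f"],
            "worst_case_stress_R2_%": min(self.stress_r2) if self.stress_r2 else None,
        }


def run_training_study(cfg: StudyConfig) -> StudyReport:
    """Run the full pipeline and evaluate on the held-out test split."""
    parents = anatomy.make_parent_library(cfg.n_parents, cfg.parent_seed)
    samples = ds_mod.lhs_sample(cfg.n_samples, seed=cfg.lhs_seed,
                                n_parents=cfg.n_parents)
    ds = ds_mod.build_dataset(parents, samples)
    ds_mod.split(ds, n_test=cfg.n_test, seed=cfg.split_seed)

    model = surrogate.train(ds, cfg.surrogate)
    Xt = ds.subset_X(ds.test_indices)
    Yt = ds.subset_Y(ds.test_indices)
    pred = surrogate.predict(model, Xt)
    test_metrics = surrogate.metrics(Yt, pred, model.output_scaler)

    reduced_model, reduced_metrics = reduce_and_retrain(ds, REDUCED_KEEP, cfg.surrogate)

    worst, stress_r2 = worst_case_stress_check(model, ds, parents, cfg.n_worst)
    return StudyReport(cfg, ds, model, test_metrics, reduced_model, reduced_metrics,
                       worst, stress_r2, parents)


def _per_case_mae(model: TrainedSurrogate, Y, pred) -> np.ndarray:
    yn = model.output_scaler.transform(Y)
    pn = model.output_scaler.transform(pred)
    return np.abs(yn - pn).sum(axis=1)


def worst_case_stress_check(model: TrainedSurrogate, ds: Dataset,
                            parents: Sequence[ParentGeometry], n_worst: int = 1
                            ) -> tuple[list, list]:
    """Forward stress-curve agreement for the worst-predicted test cases.

    Test cases are ranked by per-case normalized MAE; for each of the
    ``n_worst`` worst, the inflation solver runs twice on the same geometry
    and fibers -- once with the actual (a_f, b_f), once with the predicted --
    and the R^2 (in %) between the two transmural-maximum fiber-stress
    curves is reported.
    """
    if ds.test_indices is None:
        raise ValueError("dataset needs a test split")
    Xt = ds.subset_X(ds.test_indices)
    Yt = ds.subset_Y(ds.test_indices)
    pred = surrogate.predict(model, Xt)
    mae_cases = _per_case_mae(model, Yt, pred)
    order = np.argsort(mae_cases)[::-1][:n_worst]

    worst, r2s = [], []
    for row in order:
        ex: Example = ds.examples[int(ds.test_indices[row])]
        s = ex.sample
        geom = anatomy.resize(parents[s.parent_id], s.f_LV, s.f_RV)
        fibers = anatomy.fiber_layers(s.theta_endo, s.theta_epi)
        cyl = anatomy.equivalent_cylinder(geom)
        grid = ds.pressure_grid
        _, sig_actual = inflation.fiber_stress_curve(
            cyl, fibers, MaterialParams(a_f=s.a_f, b_f=s.b_f), grid)
        _, sig_pred = inflation.fiber_stress_curve(
            cyl, fibers, MaterialParams(a_f=float(pred[row, 0]),
                                        b_f=float(pred[row, 1])), grid)
        ss_res = float(np.sum((sig_actual - sig_pred) ** 2))
        ss_tot = float(np.sum((sig_actual - sig_actual.mean()) ** 2))
        r2 = (1.0 - ss_res / ss_tot) * 100.0
        worst.append({"test_row": int(row), "case_mae": float(mae_cases[row]),
                      "actual": tuple(Yt[row]), "predicted": tuple(pred[row])})
        r2s.append(r2)
    return worst, r2s


def predict_from_single_point(model: TrainedSurrogate,
                              geometric: Mapping[str, float] | np.ndarray,
                              theta_endo: float, theta_epi: float,
                              p_ed: float, v_ed: float,
                              universal: UniversalCurve,
                              grid_mmhg: np.ndarray | None = None) -> tuple[float, float]:
    """Estimate (a_f, b_f) from geometry, fiber angles and one (P_ED, V_ED) point.

    The EDPVR is reconstructed through the universal curve, the 114-vector
    assembled in canonical order, and the surrogate evaluated.  Geometric
    features may be a mapping by name or an array in canonical order.
    """
    if universal is None:
        raise ValueError("a fitted universal curve is required")
    if isinstance(geometric, Mapping):
        geo = np.array([geometric[n] for n in anatomy.FEATURE_NAMES])
    else:
        geo = np.asarray(geometric, dtype=float)
        if geo.shape != (len(anatomy.FEATURE_NAMES),):
            raise ValueError(f"expected {len(anatomy.FEATURE_NAMES)} geometric features")
    curve = klotz.edpvr_from_point(p_ed, v_ed, universal, grid_mmhg)
    inputs = np.concatenate([geo, [theta_endo, theta_epi], curve.volumes])
    out = surrogate.predict(model, inputs)
    return float(out[0]), float(out[1])
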