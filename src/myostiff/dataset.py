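"""Latin hypercube sampling of the design space and training-corpus assembly.

The design space has six dimensions: LV and RV resize factors, the two
transmural helix angles, and the two fiber material constants.  Each
dimension is partitioned into n equal-probability intervals and exactly one
sample lands in each interval per dimension (the Latin constraint), with
uniform jitter inside the interval.  Samples are assigned round-robin to the
parent-geometry library.

One example pairs a 114-vector of inputs (12 geometric features, 2 fiber
angles, 100 EDPVR volumes) with the (a_f, b_f) targets that generated it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import anatomy, inflation
from .anatomy import FEATURE_NAMES, ParentGeometry
from .constitutive import MaterialParams

__all__ = [
    "DesignSample",
    "Example",
    "Dataset",
    "DEFAULT_RANGES",
    "INPUT_NAMES",
    "TARGET_NAMES",
    "lhs_sample",
    "build_dataset",
    "split",
    "write_dataset",
    "read_dataset",
]

#: Sampling ranges of the six design dimensions.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = {
    "f_LV": (0.7, 1.6),
    "f_RV": (0.7, 1.6),
    "theta_endo": (0.0, math.pi / 2),
    "theta_epi": (-math.pi / 2, 0.0),
    "a_f": (0.01, 100.0),   # kPa
    "b_f": (0.01, 20.0),
}

_DIMENSIONS = tuple(DEFAULT_RANGES)

#: Canonical 114 input-column names: 12 geometric + 2 fiber + 100 EDPVR volumes.
INPUT_NAMES: tuple = tuple(FEATURE_NAMES) + ("theta_endo", "theta_epi") + tuple(
    f"edpvr_v{k:03d}" for k in range(1, 101))
TARGET_NAMES = ("a_f", "b_f")
_PROVENANCE = ("parent_id", "f_LV", "f_RV")


@dataclass(frozen=True)
class DesignSample:
    f_LV: float
    f_RV: float
    theta_endo: float
    theta_epi: float
    a_f: float
    b_f: float
    parent_id: int = 0


@dataclass(frozen=True)
class Example:
    inputs: np.ndarray        # length 114
    targets: tuple            # (a_f, b_f)
    sample: DesignSample

    def __post_init__(self) -> None:
        x = np.asarray(self.inputs, dtype=float)
        if x.shape != (len(INPUT_NAMES),):
            raise ValueError(f"inputs must have length {len(INPUT_NAMES)}")
        if not np.all(np.isfinite(x)):
            raise ValueError("inputs must be finite")
        object.__setattr__(self, "inputs", x)


@dataclass
class Dataset:
    """A corpus of examples with train/test split indices."""

    examples: list
    seed: int | None = None
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    pressure_grid: np.ndarray = field(default_factory=inflation.standard_pressure_grid)

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def X(self) -> np.ndarray:
        return np.stack([e.inputs for e in self.examples])

    @property
    def Y(self) -> np.ndarray:
        return np.array([e.targets for e in self.examples])

    def subset_X(self, indices) -> np.ndarray:
        return self.X[np.asarray(indices)]

    def edpvr_curves(self, indices=None) -> list:
        """Reconstruct EDPVR objects from the stored volume block.

        V0 equals the LV_V feature because the equivalent cylinder preserves
        the lumen volume.
        """
        idx = range(len(self)) if indices is None else np.asarray(indices)
        grid = np.asarray(self.pressure_grid, float)
        return [inflation.EDPVR(grid, self.examples[int(i)].inputs[14:],
                                V0=self.examples[int(i)].inputs[0]) for i in idx]

    def subset_Y(self, indices) -> np.ndarray:
        return self.Y[np.asarray(indices)]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        X = self.X
        for i, name in enumerate(INPUT_NAMES):
            cols[name] = X[:, i]
        Y = self.Y
        for i, name in enumerate(TARGET_NAMES):
            cols[name] = Y[:, i]
        cols["parent_id"] = [e.sample.parent_id for e in self.examples]
        cols["f_LV"] = [e.sample.f_LV for e in self.examples]
        cols["f_RV"] = [e.sample.f_RV for e in self.examples]
        return pd.DataFrame(cols)


def lhs_sample(n: int, ranges: Mapping[str, tuple[float, float]] | None = None,
               seed: int = 0, n_parents: int = 25) -> list[DesignSample]:
    """Latin hypercube draw of ``n`` design samples.

    Each of the six dimensions is split into ``n`` equally probable
    intervals and every interval is hit exactly once per dimension; the
    sample sits uniformly inside its interval.  Parents are assigned
    round-robin (sample i gets parent i mod n_parents).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    sampler = qmc.LatinHypercube(d=len(_DIMENSIONS), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges[d][0] for d in _DIMENSIONS])
    hi = np.array([ranges[d][1] for d in _DIMENSIONS])
    vals = qmc.scale(unit, lo, hi)
    return [DesignSample(**dict(zip(_DIMENSIONS, row)), parent_id=i % n_parents)
            for i, row in enumerate(vals)]


def build_example(parents: Sequence[ParentGeometry], sample: DesignSample,
                  grid: np.ndarray, n_gauss: int = 8) -> Example:
    parent = parents[sample.parent_id]
    geom = anatomy.resize(parent, sample.f_LV, sample.f_RV)
    feats = anatomy.geometric_features(geom)
    fibers = anatomy.fiber_layers(sample.theta_endo, sample.theta_epi)
    cyl = anatomy.equivalent_cylinder(geom, feats)
    params = MaterialParams(a_f=sample.a_f, b_f=sample.b_f)
    curve = inflation.inflate(cyl, fibers, params, grid, n_gauss)
    inputs = np.concatenate([feats.to_array(),
                             [sample.theta_endo, sample.theta_epi],
                             curve.volumes])
    return Example(inputs=inputs, targets=(sample.a_f, sample.b_f), sample=sample)


def build_dataset(parents: Sequence[ParentGeometry], samples: Sequence[DesignSample],
                  grid: np.ndarray | None = None, n_gauss: int = 8,
                  max_failure_fraction: float = 0.01) -> Dataset:
    """Assemble the corpus by running the forward solver for every sample.

    Solver failures are excluded and reported; more than
    ``max_failure_fraction`` of failures aborts the build.
    """
    grid = inflation.standard_pressure_grid() if grid is None else np.asarray(grid, float)
    examples, failures = [], []
    for i, s in enumerate(samples):
        try:
            examples.append(build_example(parents, s, grid, n_gauss))
        except (RuntimeError, ValueError) as err:
            failures.append((i, str(err)))
    if failures and len(failures) > max_failure_fraction * len(samples):
        detail = "; ".join(f"sample {i}: {msg}" for i, msg in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{len(samples)} solver failures exceed the "
            f"{max_failure_fraction:.0%} budget ({detail} ...)")
    for i, msg in failures:
        warnings.warn(f"sample {i} excluded: {msg}")
    return Dataset(examples=examples, pressure_grid=grid)


def split(ds: Dataset, n_test: int = 100, seed: int = 0) -> Dataset:
    """Seeded uniform train/test split, stored on the dataset in place."""
    n = len(ds)
    if n_test >= n:
        raise ValueError("n_test must be smaller than the corpus")
    if n_test == 0:
        warnings.warn("empty test set requested")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ds.test_indices = np.sort(perm[:n_test])
    ds.train_indices = np.sort(perm[n_test:])
    ds.seed = seed
    return ds


# ---------------------------------------------------------------------------
# I/O: delimited table + structured-text metadata sidecar

def write_dataset(ds: Dataset, path, metadata_path=None) -> None:
    df = ds.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    if metadata_path is not None:
        meta = {
            "n_examples": len(ds),
            "split_seed": ds.seed,
            "train_indices": None if ds.train_indices is None else ds.train_indices.tolist(),
            "test_indices": None if ds.test_indices is None else ds.test_indices.tolist(),
            "pressure_grid_mmHg": np.asarray(ds.pressure_grid).tolist(),
            "input_columns": list(INPUT_NAMES),
            "target_columns": list(TARGET_NAMES),
        }
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_dataset(path, metadata_path=None) -> Dataset:
    df = pd.read_csv(path, float_precision="round_trip")
    examples = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sample = DesignSample(
            f_LV=d["f_LV"], f_RV=d["f_RV"], theta_endo=d["theta_endo"],
            theta_epi=d["theta_epi"], a_f=d["a_f"], b_f=d["b_f"],
            parent_id=int(d["parent_id"]))
        inputs = np.array([d[name] for name in INPUT_NAMES])
        examples.append(Example(inputs=inputs, targets=(d["a_f"], d["b_f"]), sample=sample))
    ds = Dataset(examples=examples)
    if metadata_path is not None:
        with open(metadata_path) as fh:
            meta = json.load(fh)
        if meta.get("train_indices") is not None:
            ds.train_indices = np.asarray(meta["train_indices"])
        if meta.get("test_indices") is not None:
            ds.test_indices = np.asarray(meta["test_indices"])
        ds.seed = meta.get("split_seed")
        ds.pressure_grid = np.asarray(meta["pressure_grid_mmHg"])
    return ds
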