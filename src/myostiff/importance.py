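"""Permutation feature importance and the feature-reduction retraining workflow.

Importance of feature j is the degradation of the model's MAE score when
column j is randomly permuted, averaged over K repetitions:

    i_j = (1/K) sum_k s_kj - s

with s the reference MAE.  Important features therefore score positive.
(The sign is flipped relative to the formula written with an accuracy-style
score so that breaking an informative feature yields a positive bar.)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, INPUT_NAMES, TARGET_NAMES
from .surrogate import (Metrics, SurrogateConfig, TrainedSurrogate, metrics,
                        predict, train)

__all__ = [
    "ImportanceResult",
    "permutation_importance",
    "reduce_and_retrain",
    "EDPVR_FEATURES",
]

#: Names of the 100 EDPVR input columns (always kept in feature reduction).
EDPVR_FEATURES: tuple = tuple(n for n in INPUT_NAMES if n.startswith("edpvr_"))


@dataclass(frozen=True)
class ImportanceResult:
    feature_names: tuple
    importance: np.ndarray          # i_j, MAE units (normalized targets)
    reference_score: float          # s
    scores: np.ndarray              # s_kj, shape (n_features, K)
    K: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names, "importance": self.importance})
        for k in range(self.K):
            df[f"score_rep{k + 1}"] = self.scores[:, k]
        return df


def permutation_importance(model: TrainedSurrogate, X: np.ndarray, Y: np.ndarray,
                           K: int = 10, seed: int = 0) -> ImportanceResult:
    """Permutation importance of every input feature on data (X, Y).

    The score is the MAE on normalized targets (the training loss metric).
    Each repetition draws an independent permutation of the corrupted column.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if K < 1:
        raise ValueError("need K >= 1")
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")

    def score(Xs) -> float:
        pred = predict(model, Xs)
        yn = model.output_scaler.transform(Y)
        pn = model.output_scaler.transform(pred)
        return float(np.abs(yn - pn).sum(axis=1).mean())

    rng = np.random.default_rng(seed)
    s = score(X)
    nf = X.shape[1]
    scores = np.empty((nf, K))
    for j in range(nf):
        for k in range(K):
            Xc = X.copy()
            Xc[:, j] = Xc[rng.permutation(len(X)), j]
            scores[j, k] = score(Xc)
    importance = scores.mean(axis=1) - s
    return ImportanceResult(tuple(model.feature_names), importance, s, scores, K)


def reduce_and_retrain(ds: Dataset, keep: Sequence[str],
                       cfg: SurrogateConfig | None = None
                       ) -> tuple[TrainedSurrogate, Metrics]:
    """Drop all input features except ``keep`` + the EDPVR block and retrain.

    Hyperparameters are unchanged; the returned metrics are computed on the
    dataset's test split (which must be present).
    """
    keep = tuple(keep)
    if not keep:
        raise ValueError("keep set must not be empty")
    unknown = [k for k in keep if k not in INPUT_NAMES]
    if unknown:
        raise ValueError(f"unknown feature(s): {unknown}")
    kept = tuple(n for n in INPUT_NAMES if n in set(keep) | set(EDPVR_FEATURES))
    if not any(n in EDPVR_FEATURES for n in kept):
        raise ValueError("the EDPVR block must be kept")
    cols = [INPUT_NAMES.index(n) for n in kept]

    reduced = _column_subset_view(ds, cols)
    model = train(reduced, cfg)
    model.feature_names = kept
    if ds.test_indices is None:
        raise ValueError("dataset needs a test split for reduced-model evaluation")
    Xt = ds.subset_X(ds.test_indices)[:, cols]
    Yt = ds.subset_Y(ds.test_indices)
    m = metrics(Yt, predict(model, Xt), model.output_scaler)
    return model, m


class _column_subset_view:
    """Lightweight dataset view restricted to selected input columns."""

    def __init__(self, ds: Dataset, cols):
        self._ds = ds
        self._cols = np.asarray(cols)
        self.train_indices = ds.train_indices
        self.test_indices = ds.test_indices

    def __len__(self):
        return len(self._ds)

    def subset_X(self, indices):
        return self._ds.subset_X(indices)[:, self._cols]

    def subset_Y(self, indices):
        return self._ds.subset_Y(indices)
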