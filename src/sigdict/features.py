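"""Dictionary-derived features for classifier training and testing.

Three features are computed for each segment x against the trained
dictionary D (atoms as unit-norm columns, P of them):

* F1 — the projection coefficient of largest magnitude, max_m |<x, psi_m>|
  (the signed-maximum variant is available via ``signed_f1``, mirroring the
  ambiguity between "maximum value" and "largest absolute value").
* F2 — the coefficient vector a = D^+ x (length P), where D^+ is the
  Moore–Penrose pseudo-inverse computed once per dictionary by SVD with a
  relative singular-value cutoff ``rtol``; minimum-norm least-squares
  solution when atoms are linearly dependent.
* F3 — the reconstruction error eps = ||x - D D^+ x||_2, the l2 distance of
  x from its (rank-truncated) orthogonal projection onto the atom span.

Feature sets are the seven non-empty combinations F1, F2, F3, F1F2, F1F3,
F2F3, F1F2F3; F2-containing sets concatenate the length-P vector with the
scalar features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import TrainedDictionary
from .types_and_io import Segment

FEATURE_SETS = ("F1", "F2", "F3", "F1F2", "F1F3", "F2F3", "F1F2F3")

__all__ = [
    "FEATURE_SETS",
    "FeatureMatrix",
    "feature_f1",
    "feature_f2",
    "feature_f3",
    "assemble_features",
]


@dataclass
class FeatureMatrix:
    """Per-segment feature rows restricted to one feature set."""

    X: np.ndarray
    labels: list[str | None]
    feature_set: str
    columns: list[str]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.columns)
        df["label"] = self.labels
        df.to_csv(path, index=False)


def _values(segment) -> np.ndarray:
    if isinstance(segment, Segment):
        return segment.values
    return np.asarray(segment, dtype=float)


def _check(trained: TrainedDictionary) -> None:
    if trained.P == 0:
        raise ValueError("trained dictionary is empty")


def feature_f1(segment, trained: TrainedDictionary, signed: bool = False) -> float:
    """Largest projection coefficient of the segment on the trained atoms.

    By default the coefficient of largest absolute value (consistent with the
    learning stage); with ``signed=True`` the plain maximum of the signed
    coefficients is returned instead.
    """
    _check(trained)
    alphas = trained.matrix.T @ _values(segment)
    if signed:
        return float(np.max(alphas))
    return float(np.max(np.abs(alphas)))


def feature_f2(
    segment, trained: TrainedDictionary, rtol: float = 1e-10
) -> np.ndarray:
    """Coefficient vector a = D^+ x (length P)."""
    _check(trained)
    return trained.pseudo_inverse(rtol) @ _values(segment)


def feature_f3(segment, trained: TrainedDictionary, rtol: float = 1e-10) -> float:
    """Reconstruction error eps = ||x - D D^+ x||_2 (non-negative)."""
    _check(trained)
    x = _values(segment)
    a = trained.pseudo_inverse(rtol) @ x
    return float(np.linalg.norm(x - trained.matrix @ a))


def assemble_features(
    segments: Sequence,
    trained: TrainedDictionary,
    feature_set: str = "F3",
    rtol: float = 1e-10,
    signed_f1: bool = False,
) -> FeatureMatrix:
    """Build the feature matrix for a list of segments, rows in input order.

    All segments are projected with one cached pseudo-inverse, so the cost is
    one SVD per dictionary plus a matrix product per call.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"feature_set must be one of {FEATURE_SETS}, got {feature_set!r}"
        )
    P = trained.P
    cols: list[str] = []
    if "F1" in feature_set:
        cols.append("f1")
    if "F2" in feature_set:
        cols.extend(f"f2_{i + 1:04d}" for i in range(P))
    if "F3" in feature_set:
        cols.append("f3")

    if not segments:
        return FeatureMatrix(
            X=np.empty((0, len(cols))), labels=[], feature_set=feature_set,
            columns=cols,
        )

    _check(trained)
    n = trained.matrix.shape[0]
    vals = []
    labels = []
    for s in segments:
        v = _values(s)
        if v.size != n:
            raise ValueError(
                f"segment length {v.size} does not match atom length {n}"
            )
        vals.append(v)
        labels.append(s.label if isinstance(s, Segment) else None)
    Xsig = np.column_stack(vals)  # (n, n_seg)

    D = trained.matrix
    blocks = []
    need_a = "F2" in feature_set or "F3" in feature_set
    if need_a:
        A = trained.pseudo_inverse(rtol) @ Xsig  # (P, n_seg)
    if "F1" in feature_set:
        proj = D.T @ Xsig
        f1 = proj.max(axis=0) if signed_f1 else np.abs(proj).max(axis=0)
        blocks.append(f1[None, :])
    if "F2" in feature_set:
        blocks.append(A)
    if "F3" in feature_set:
        eps = np.linalg.norm(Xsig - D @ A, axis=0)
        blocks.append(eps[None, :])
    X = np.vstack(blocks).T
    return FeatureMatrix(X=X, labels=labels, feature_set=feature_set, columns=cols)
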