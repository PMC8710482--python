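"""Signal-derived empirical dictionaries: raw construction and greedy learning.

The raw dictionary pools every decomposition component (IMF or wavelet
detail/smooth) of every dictionary-pool segment of both classes, normalized
to unit l2 norm: with k segments per class and Q components each, the
class dictionary has L = k*Q atoms and the combined dictionary M = 2L.

The trained dictionary is a small subset selected by a greedy,
matching-pursuit-style algorithm. Each learning signal keeps a *private*
working copy of the raw dictionary and a private residue, both persisting
across outer iterations: per iteration the signal projects its residue on
its remaining atoms, claims the atom with the largest absolute projection
coefficient (added to the shared trained dictionary if not already there,
identity by atom id), removes it from its private copy, and subtracts the
atom's contribution from its residue. After every iteration a validation
distance d = ||Gamma_c1 - Gamma_c2||_2^2 is computed, where Gamma_c collects
each validation signal's largest absolute projection on the current trained
atoms (signals paired positionally in temporal order). The snapshot with the
largest d — earliest iteration on ties — is returned.

Everything here is deterministic; ties among equal |projection| values break
toward the lowest atom id.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decomposition import DecompositionConfig, decompose
from .types_and_io import NON_SEIZURE, SEIZURE, Segment

logger = logging.getLogger("sigdict")

__all__ = [
    "Atom",
    "RawDictionary",
    "TrainedDictionary",
    "LearningTrace",
    "build_raw_dictionary",
    "learn_dictionary",
    "validation_distance",
    "save_dictionary_bundle",
    "load_dictionary_bundle",
]


@dataclass
class Atom:
    """A unit-l2-norm dictionary atom with provenance."""

    values: np.ndarray
    source_class: str
    source_segment: str
    component_index: int
    atom_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nrm = np.linalg.norm(self.values)
        if abs(nrm - 1.0) > 1e-12:
            raise ValueError(f"atom {self.atom_id} has norm {nrm}, expected 1")


@dataclass
class RawDictionary:
    """Combined raw dictionary: class-c1 (seizure) atoms first, then c2."""

    atoms: list[Atom]

    @property
    def M(self) -> int:
        return len(self.atoms)

    @property
    def per_class_counts(self) -> dict[str, int]:
        counts = {SEIZURE: 0, NON_SEIZURE: 0}
        for a in self.atoms:
            counts[a.source_class] += 1
        return counts

    @property
    def matrix(self) -> np.ndarray:
        """Atoms as columns, (n, M)."""
        return np.column_stack([a.values for a in self.atoms])


@dataclass
class LearningTrace:
    """Per-iteration record of the learning run."""

    distances: list[float] = field(default_factory=list)
    sizes: list[int] = field(default_factory=list)
    gammas_c1: list[list[float]] = field(default_factory=list)
    gammas_c2: list[list[float]] = field(default_factory=list)
    #: atom_ids in order of first addition, across all iterations
    selected_ids: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "distances": self.distances,
            "sizes": self.sizes,
            "gammas_c1": self.gammas_c1,
            "gammas_c2": self.gammas_c2,
            "selected_ids": self.selected_ids,
        }


@dataclass
class TrainedDictionary:
    """Greedy-selected atom subset with its learning trace.

    ``atoms`` are in order of first selection, truncated at the cumulative
    size reached by ``best_iteration``.
    """

    atoms: list[Atom]
    best_iteration: int
    trace: LearningTrace
    raw_M: int = 0

    _pinv_cache: dict = field(default_factory=dict, repr=False)

    @property
    def P(self) -> int:
        return len(self.atoms)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([a.values for a in self.atoms])

    def pseudo_inverse(self, rtol: float = 1e-10) -> np.ndarray:
        """SVD pseudo-inverse of the atom matrix, cached per tolerance.

        Singular values below ``rtol * s_max`` are truncated, giving the
        minimum-norm least-squares solution when atoms are dependent.
        """
        key = float(rtol)
        if key not in self._pinv_cache:
            D = self.matrix
            self._pinv_cache[key] = np.linalg.pinv(D, rcond=rtol)
            n = D.shape[0]
            s = np.linalg.svd(D, compute_uv=False)
            rank = int(np.sum(s > rtol * s[0]))
            if self.P >= n and rank >= n:
                logger.warning(
                    "trained dictionary spans the full signal space "
                    "(P=%d >= n=%d, rank %d): reconstruction error is ~0 "
                    "for every input and uninformative", self.P, n, rank,
                )
        return self._pinv_cache[key]


# ---------------------------------------------------------------------------
# Raw dictionary
# ---------------------------------------------------------------------------

def build_raw_dictionary(
    dict_segments: dict[str, Sequence[Segment]],
    config: DecompositionConfig,
) -> RawDictionary:
    """Decompose every dictionary-pool segment and pool unit-norm atoms.

    Segments of both classes (all channels already pooled by the caller) are
    decomposed with ``config``; every component is normalized to unit l2 norm
    and appended as an Atom. Identically-zero components are dropped with a
    log entry. Seizure-class atoms precede non-seizure atoms.
    """
    for cls in (SEIZURE, NON_SEIZURE):
        if not dict_segments.get(cls):
            raise ValueError(f"dictionary pool for class {cls!r} is empty")
    atoms: list[Atom] = []
    atom_id = 0
    n_dropped = 0
    for cls in (SEIZURE, NON_SEIZURE):
        n_before = len(atoms)
        for si, seg in enumerate(dict_segments[cls]):
            cset = decompose(seg, config)
            seg_id = f"{seg.patient_id}/{seg.channel}/t{seg.t_index}"
            for qi, comp in enumerate(cset.components):
                nrm = np.linalg.norm(comp)
                if nrm == 0.0:
                    n_dropped += 1
                    continue
                atoms.append(Atom(
                    values=comp / nrm,
                    source_class=cls,
                    source_segment=seg_id,
                    component_index=qi,
                    atom_id=atom_id,
                ))
                atom_id += 1
        if len(atoms) == n_before:
            raise ValueError(f"class {cls!r} produced zero usable atoms")
    if n_dropped:
        logger.info("dropped %d identically-zero components", n_dropped)
    return RawDictionary(atoms=atoms)


# ---------------------------------------------------------------------------
# Validation distance
# ---------------------------------------------------------------------------

def _max_abs_projection(D: np.ndarray, x: np.ndarray) -> float:
    return float(np.max(np.abs(D.T @ x)))


def validation_distance(
    trained_matrix: np.ndarray,
    validation_c1: Sequence[np.ndarray],
    validation_c2: Sequence[np.ndarray],
) -> tuple[float, list[float], list[float]]:
    """Squared distance between per-class best-projection vectors.

    For each validation signal, the largest absolute projection coefficient
    over the current trained atoms goes into its class vector Gamma_c;
    returns (||Gamma_c1 - Gamma_c2||_2^2, Gamma_c1, Gamma_c2). Signals are
    paired positionally (temporal order; the pairing is arbitrary by design).
    """
    if trained_matrix.size == 0:
        raise ValueError("trained dictionary is empty")
    if len(validation_c1) != len(validation_c2):
        raise ValueError(
            f"validation pools must have equal counts "
            f"({len(validation_c1)} vs {len(validation_c2)})"
        )
    X1 = np.column_stack([np.asarray(x, float) for x in validation_c1])
    X2 = np.column_stack([np.asarray(x, float) for x in validation_c2])
    g1 = np.abs(trained_matrix.T @ X1).max(axis=0).tolist()
    g2 = np.abs(trained_matrix.T @ X2).max(axis=0).tolist()
    d = float(np.sum((np.asarray(g1) - np.asarray(g2)) ** 2))
    return d, g1, g2


# ---------------------------------------------------------------------------
# Greedy dictionary learning
# ---------------------------------------------------------------------------

def _segment_arrays(segments) -> list[np.ndarray]:
    return [s.values if isinstance(s, Segment) else np.asarray(s, float)
            for s in segments]


def learn_dictionary(
    raw: RawDictionary,
    training_segments: dict[str, Sequence],
    validation_segments: dict[str, Sequence],
    max_iter: int = 7,
) -> TrainedDictionary:
    """Learn a trained dictionary from the raw dictionary.

    ``training_segments`` are the same signals whose components built the raw
    dictionary (per class); ``validation_segments`` hold equal per-class
    counts of held-out signals for the stopping rule. See the module
    docstring for the algorithm. With k training signals per class, at most
    2k atoms join the trained dictionary per iteration, so P <= 2*k*max_iter.
    """
    if raw.M == 0:
        raise ValueError("raw dictionary is empty")
    val_c1 = _segment_arrays(validation_segments[SEIZURE])
    val_c2 = _segment_arrays(validation_segments[NON_SEIZURE])
    if len(val_c1) != len(val_c2):
        raise ValueError("validation pools must have equal per-class counts")
    if not val_c1:
        raise ValueError("validation pools are empty")

    train = _segment_arrays(training_segments[SEIZURE]) + _segment_arrays(
        training_segments[NON_SEIZURE]
    )
    D = raw.matrix  # (n, M), column m is atom_id raw.atoms[m].atom_id
    atom_ids = np.array([a.atom_id for a in raw.atoms])

    R = np.column_stack(train)                     # (n, S) private residues
    available = np.ones((raw.M, len(train)), bool)  # private working copies
    warned_exhausted = set()

    selected_order: list[int] = []   # column indices in order of first selection
    selected_set: set[int] = set()   # atom_ids in the trained dictionary
    trace = LearningTrace()
    best_d = -np.inf
    best_iteration = 0
    best_size = 0

    for it in range(1, max_iter + 1):
        # selections are independent across signals within an iteration (the
        # shared trained dictionary only accumulates), so the per-signal
        # projections batch into one GEMM
        scores = np.abs(D.T @ R)                   # (M, S)
        scores[~available] = -1.0
        picks = np.argmax(scores, axis=0)          # first (lowest id) on ties
        for si, m in enumerate(picks):
            if scores[m, si] < 0.0:                # private dictionary empty
                if si not in warned_exhausted:
                    warned_exhausted.add(si)
                    logger.info("training signal %d exhausted its private "
                                "dictionary at iteration %d", si, it)
                continue
            aid = int(atom_ids[m])
            if aid not in selected_set:
                selected_set.add(aid)
                selected_order.append(int(m))
            available[m, si] = False
            R[:, si] -= D[:, m] * float(D[:, m] @ R[:, si])

        Dtrain = D[:, selected_order]
        d, g1, g2 = validation_distance(Dtrain, val_c1, val_c2)
        trace.distances.append(d)
        trace.sizes.append(len(selected_order))
        trace.gammas_c1.append(g1)
        trace.gammas_c2.append(g2)
        if d > best_d:
            best_d = d
            best_iteration = it
            best_size = len(selected_order)

    trace.selected_ids = [int(atom_ids[m]) for m in selected_order]
    atoms = [raw.atoms[m] for m in selected_order[:best_size]]
    return TrainedDictionary(
        atoms=atoms, best_iteration=best_iteration, trace=trace, raw_M=raw.M
    )


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def save_dictionary_bundle(trained: TrainedDictionary, directory: str | Path) -> None:
    """Serialize a trained dictionary: atoms.npy + provenance CSV + trace JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "atoms.npy", trained.matrix)
    pd.DataFrame({
        "atom_id": [a.atom_id for a in trained.atoms],
        "source_class": [a.source_class for a in trained.atoms],
        "source_segment": [a.source_segment for a in trained.atoms],
        "component_index": [a.component_index for a in trained.atoms],
    }).to_csv(directory / "provenance.csv", index=False)
    with open(directory / "trace.json", "w") as fh:
        json.dump({
            "best_iteration": trained.best_iteration,
            "raw_M": trained.raw_M,
            "P": trained.P,
            "trace": trained.trace.as_dict(),
        }, fh, indent=2)


def load_dictionary_bundle(directory: str | Path) -> TrainedDictionary:
    directory = Path(directory)
    matrix = np.load(directory / "atoms.npy")
    prov = pd.read_csv(directory / "provenance.csv")
    with open(directory / "trace.json") as fh:
        meta = json.load(fh)
    atoms = [
        Atom(
            values=matrix[:, i],
            source_class=row.source_class,
            source_segment=row.source_segment,
            component_index=int(row.component_index),
            atom_id=int(row.atom_id),
        )
        for i, row in enumerate(prov.itertuples())
    ]
    trace = LearningTrace(**meta["trace"])
    return TrainedDictionary(
        atoms=atoms, best_iteration=int(meta["best_iteration"]),
        trace=trace, raw_M=int(meta["raw_M"]),
    )
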