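"""Raw-dictionary construction and greedy learning vs a brute-force oracle."""

import numpy as np
import pytest

from sigdict import (
    NON_SEIZURE,
    SEIZURE,
    DecompositionConfig,
    RawDictionary,
    Segment,
    build_raw_dictionary,
    learn_dictionary,
    load_dictionary_bundle,
    save_dictionary_bundle,
    validation_distance,
)
from sigdict.dictionary import Atom


def brute_force_learn(atom_values, train_signals, max_iter):
    """Straight-line transcription of the greedy learning loop.

    atom_values: list of unit-norm 1-D arrays (atom_id = position).
    train_signals: list of 1-D arrays.
    Returns the ordered list of atom_ids ever added to the trained dictionary
    and the per-iteration cumulative sizes. Private residues and private
    dictionary copies persist across iterations.
    """
    trained: list[int] = []
    residues = [np.array(x, float) for x in train_signals]
    private = [list(range(len(atom_values))) for _ in train_signals]
    sizes = []
    for _ in range(max_iter):
        for si in range(len(train_signals)):
            if not private[si]:
                continue
            best_m, best_val = None, -1.0
            for m in private[si]:
                val = abs(float(np.dot(residues[si], atom_values[m])))
                if val > best_val:  # strict: lowest atom id wins ties
                    best_m, best_val = m, val
            if best_m not in trained:
                trained.append(best_m)
            private[si].remove(best_m)
            psi = atom_values[best_m]
            residues[si] = residues[si] - psi * float(np.dot(residues[si], psi))
        sizes.append(len(trained))
    return trained, sizes


def make_raw(atom_values):
    atoms = [
        Atom(values=v, source_class=SEIZURE if i % 2 == 0 else NON_SEIZURE,
             source_segment=f"s{i}", component_index=0, atom_id=i)
        for i, v in enumerate(atom_values)
    ]
    return RawDictionary(atoms=atoms)


def random_instance(rng, n, n_atoms, n_train):
    atoms = [v / np.linalg.norm(v)
             for v in rng.standard_normal((n_atoms, n))]
    train = list(rng.standard_normal((n_train, n)))
    val = list(rng.standard_normal((2, n)))
    return atoms, train, val


def seg(values, label, t=0):
    return Segment(np.asarray(values, float), "A", t, label=label)


class TestRawDictionary:
    def test_dwt_atom_count_is_2_x_k_x_Q(self, rng):
        cfg = DecompositionConfig(method="dwt", levels=7)
        pools = {
            cls: [seg(rng.standard_normal(1024), cls, t) for t in range(5)]
            for cls in (SEIZURE, NON_SEIZURE)
        }
        raw = build_raw_dictionary(pools, cfg)
        assert raw.M == 2 * 5 * 8
        assert raw.per_class_counts == {SEIZURE: 40, NON_SEIZURE: 40}

    def test_atoms_have_unit_norm_and_class_ordering(self, rng):
        cfg = DecompositionConfig(method="dwt", levels=3)
        pools = {
            cls: [seg(rng.standard_normal(256), cls)]
            for cls in (SEIZURE, NON_SEIZURE)
        }
        raw = build_raw_dictionary(pools, cfg)
        norms = np.linalg.norm(raw.matrix, axis=0)
        assert np.abs(norms - 1).max() <= 1e-12
        classes = [a.source_class for a in raw.atoms]
        assert classes == [SEIZURE] * 4 + [NON_SEIZURE] * 4

    def test_zero_components_dropped(self, rng):
        # an all-zero segment decomposes into identically-zero components,
        # none of which can be unit-normalized; they are excluded
        cfg = DecompositionConfig(method="dwt", levels=2)
        pools = {
            SEIZURE: [seg(rng.standard_normal(64), SEIZURE, 0),
                      seg(np.zeros(64), SEIZURE, 1)],
            NON_SEIZURE: [seg(rng.standard_normal(64), NON_SEIZURE)],
        }
        raw = build_raw_dictionary(pools, cfg)
        assert raw.per_class_counts[SEIZURE] == 3  # zero segment adds nothing
        assert raw.M == 3 + 3

    def test_empty_class_rejected(self, rng):
        cfg = DecompositionConfig(method="dwt", levels=2)
        with pytest.raises(ValueError):
            build_raw_dictionary({SEIZURE: [], NON_SEIZURE: []}, cfg)


class TestValidationDistance:
    def test_scalar_example(self):
        D = np.eye(4)[:, :2]
        # validation signals engineered to give gammas 0.9 and 0.4
        d, g1, g2 = validation_distance(D, [np.array([0.9, 0.1, 0, 0])],
                                        [np.array([0.4, 0.2, 0, 0])])
        assert d == pytest.approx((0.9 - 0.4) ** 2)

    def test_identical_pools_give_zero(self, rng):
        D = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        xs = list(rng.standard_normal((2, 8)))
        d, *_ = validation_distance(D, xs, [x.copy() for x in xs])
        assert d == 0.0

    def test_matches_exhaustive_inner_product_oracle(self, rng):
        atoms, _, _ = random_instance(rng, 16, 10, 0)
        D = np.column_stack(atoms)
        v1 = list(rng.standard_normal((3, 16)))
        v2 = list(rng.standard_normal((3, 16)))
        d, g1, g2 = validation_distance(D, v1, v2)
        og1 = [max(abs(float(np.dot(x, a))) for a in atoms) for x in v1]
        og2 = [max(abs(float(np.dot(x, a))) for a in atoms) for x in v2]
        assert np.allclose(g1, og1, atol=1e-12)
        assert np.allclose(g2, og2, atol=1e-12)
        assert d == pytest.approx(
            float(np.sum((np.array(og1) - np.array(og2)) ** 2)), abs=1e-12
        )

    def test_empty_dictionary_rejected(self, rng):
        with pytest.raises(ValueError):
            validation_distance(np.empty((8, 0)), [np.zeros(8)], [np.zeros(8)])


class TestLearning:
    def test_hand_traced_standard_basis_instance(self):
        # raw dictionary = e1..e4; single training signal x = (3,1,0,0):
        # iteration 1 selects e1 (|alpha|=3), residue (0,1,0,0);
        # iteration 2 selects e2, residue zero
        basis = [np.eye(4)[i] for i in range(4)]
        raw = make_raw(basis)
        x = np.array([3.0, 1.0, 0.0, 0.0])
        trained = learn_dictionary(
            raw,
            {SEIZURE: [x], NON_SEIZURE: [np.array([0.0, 0.0, 2.0, 0.0])]},
            {SEIZURE: [np.array([1.0, 0, 0, 0])],
             NON_SEIZURE: [np.array([0.0, 0, 1.0, 0])]},
            max_iter=2,
        )
        # signal order: seizure x then non-seizure; iteration 1 picks e1 and
        # e3; iteration 2 picks e2 for x (residue (0,1,0,0)); the other
        # signal's residue is zero, so it re-picks the lowest remaining id
        # (e1), already present. Both iterations give d = 0, so the earliest
        # snapshot (iteration 1, atoms {e1, e3}) is retained.
        assert trained.trace.selected_ids == [0, 2, 1]
        assert trained.trace.sizes == [2, 3]
        assert trained.best_iteration == 1
        assert [a.atom_id for a in trained.atoms] == [0, 2]

    def test_identical_validation_pools_force_first_iteration(self, rng):
        atoms, train, _ = random_instance(rng, 12, 8, 2)
        raw = make_raw(atoms)
        v = list(rng.standard_normal((2, 12)))
        trained = learn_dictionary(
            raw,
            {SEIZURE: train[:1], NON_SEIZURE: train[1:]},
            {SEIZURE: v, NON_SEIZURE: [x.copy() for x in v]},
            max_iter=5,
        )
        assert trained.trace.distances == [0.0] * 5
        assert trained.best_iteration == 1

    def test_growth_bounded_by_2k_per_iteration_and_monotone(self, rng):
        atoms, _, _ = random_instance(rng, 32, 30, 0)
        k = 3
        train = {
            SEIZURE: list(rng.standard_normal((k, 32))),
            NON_SEIZURE: list(rng.standard_normal((k, 32))),
        }
        val = {
            SEIZURE: list(rng.standard_normal((2, 32))),
            NON_SEIZURE: list(rng.standard_normal((2, 32))),
        }
        trained = learn_dictionary(make_raw(atoms), train, val, max_iter=4)
        sizes = trained.trace.sizes
        assert sizes[0] <= 2 * k
        assert all(b - a <= 2 * k for a, b in zip(sizes, sizes[1:]))
        assert sizes == sorted(sizes)

    @pytest.mark.parametrize("trial", range(10))
    def test_selection_sequence_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(8, 24))
        n_atoms = int(rng.integers(4, 21))
        n_train = int(rng.integers(2, 5))
        atoms, train, _ = random_instance(rng, n, n_atoms, n_train)
        max_iter = int(rng.integers(1, 6))
        oracle_ids, oracle_sizes = brute_force_learn(atoms, train, max_iter)

        half = n_train // 2
        trained = learn_dictionary(
            make_raw(atoms),
            {SEIZURE: train[:half], NON_SEIZURE: train[half:]},
            {SEIZURE: [rng.standard_normal(n)],
             NON_SEIZURE: [rng.standard_normal(n)]},
            max_iter=max_iter,
        )
        assert trained.trace.selected_ids == oracle_ids
        assert trained.trace.sizes == oracle_sizes
        # the returned atoms are the prefix at the best iteration
        got_ids = [a.atom_id for a in trained.atoms]
        assert got_ids == oracle_ids[: len(got_ids)]

    def test_deterministic_replay(self, rng):
        atoms, train, _ = random_instance(rng, 16, 12, 4)
        pools = {SEIZURE: train[:2], NON_SEIZURE: train[2:]}
        val = {SEIZURE: [np.sin(np.arange(16.0))],
               NON_SEIZURE: [np.cos(np.arange(16.0))]}
        t1 = learn_dictionary(make_raw(atoms), pools, val, max_iter=7)
        t2 = learn_dictionary(make_raw(atoms), pools, val, max_iter=7)
        assert [a.atom_id for a in t1.atoms] == [a.atom_id for a in t2.atoms]
        assert t1.trace.distances == t2.trace.distances
        assert t1.best_iteration == t2.best_iteration


class TestShrinkage:
    def test_dwt_trained_size_strictly_below_raw(self, rng):
        # with Q = 8 components and max_iter = 7, P <= 14k < M = 16k
        cfg = DecompositionConfig(method="dwt", levels=7)
        k = 4
        pools = {
            cls: [seg(np.cumsum(rng.standard_normal(1024)), cls, t)
                  for t in range(k)]
            for cls in (SEIZURE, NON_SEIZURE)
        }
        raw = build_raw_dictionary(pools, cfg)
        assert raw.M == 16 * k
        val = {
            cls: [np.cumsum(rng.standard_normal(1024)) for _ in range(2)]
            for cls in (SEIZURE, NON_SEIZURE)
        }
        trained = learn_dictionary(raw, pools, val, max_iter=7)
        assert trained.P <= 14 * k < raw.M


class TestBundle:
    def test_round_trip(self, rng, tmp_path):
        atoms, train, _ = random_instance(rng, 16, 10, 2)
        trained = learn_dictionary(
            make_raw(atoms),
            {SEIZURE: train[:1], NON_SEIZURE: train[1:]},
            {SEIZURE: [rng.standard_normal(16)],
             NON_SEIZURE: [rng.standard_normal(16)]},
            max_iter=3,
        )
        save_dictionary_bundle(trained, tmp_path / "bundle")
        back = load_dictionary_bundle(tmp_path / "bundle")
        assert back.P == trained.P
        assert back.best_iteration == trained.best_iteration
        assert np.array_equal(back.matrix, trained.matrix)
        assert [a.atom_id for a in back.atoms] == [a.atom_id for a in trained.atoms]
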