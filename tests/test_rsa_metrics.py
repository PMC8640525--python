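"""RDM construction, Kendall tau_A, noise floor, superclass RDMs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from degensim import injury_engine as inj
from degensim.errors import InvalidArgumentError
from degensim.hierarchy import make_hierarchy
from degensim.rsa_metrics import (
    RDM,
    average_rdms,
    build_rdm,
    compare_rdms,
    from_utv,
    kendall_tau_a,
    kendall_tau_a_brute,
    kendall_tau_a_fast,
    penultimate_activations,
    scrambled_noise_floor,
    superclass_rdm,
    utv,
)
from degensim.synthetic_data import StimulusSet


class TestKendallTauA:
    @pytest.mark.parametrize(
        "v1,v2,expect",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 4 / 6),  # brute enumeration: 5 conc, 1 disc
            ((1, 2, 3, 4), (1, 1, 2, 3), 5 / 6),  # tied pair stays in the denominator
        ],
    )
    def test_worked_examples_both_paths(self, v1, v2, expect):
        assert kendall_tau_a_brute(np.array(v1), np.array(v2)) == pytest.approx(expect, abs=1e-12)
        assert kendall_tau_a_fast(np.array(v1), np.array(v2)) == pytest.approx(expect, abs=1e-12)

    def test_fast_equals_brute_on_tie_containing_vectors(self):
        # oracle equivalence over many random pairs, ties guaranteed by
        # drawing from a small integer alphabet
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            m = rng.integers(2, 51)
            v1 = rng.integers(0, 8, m).astype(float)
            v2 = rng.integers(0, 8, m).astype(float)
            assert kendall_tau_a_fast(v1, v2) == pytest.approx(
                kendall_tau_a_brute(v1, v2), abs=1e-12
            )

    def test_matches_scipy_derived_tau_a(self):
        # independent cross-check: scale scipy's tau_b numerator back to
        # the all-pairs denominator
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = int(rng.integers(5, 60))
            v1 = rng.integers(0, 6, m).astype(float)
            v2 = rng.integers(0, 6, m).astype(float)
            n0 = m * (m - 1) / 2
            tx = sum(t * (t - 1) / 2 for t in np.unique(v1, return_counts=True)[1])
            ty = sum(t * (t - 1) / 2 for t in np.unique(v2, return_counts=True)[1])
            if tx == n0 or ty == n0:
                continue  # constant vector: tau_b undefined
            tau_b = stats.kendalltau(v1, v2).statistic
            s = tau_b * np.sqrt((n0 - tx) * (n0 - ty))
            assert kendall_tau_a(v1, v2) == pytest.approx(s / n0, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=30),
        st.data(),
    )
    def test_property_fast_equals_brute(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 5), min_size=len(xs), max_size=len(xs)))
        v1, v2 = np.array(xs, dtype=float), np.array(ys, dtype=float)
        assert kendall_tau_a_fast(v1, v2) == pytest.approx(kendall_tau_a_brute(v1, v2), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        v1, v2 = rng.normal(size=40), rng.normal(size=40)
        base = kendall_tau_a(v1, v2)
        assert kendall_tau_a(np.exp(v1), v2) == pytest.approx(base, abs=1e-12)
        assert kendall_tau_a(v1, 3 * v2 + 10) == pytest.approx(base, abs=1e-12)

    def test_length_and_size_guards(self):
        with pytest.raises(InvalidArgumentError):
            kendall_tau_a(np.array([1.0]), np.array([1.0]))
        with pytest.raises(InvalidArgumentError):
            kendall_tau_a(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestBuildRDM:
    def test_perfect_correlation_examples(self):
        d = build_rdm(np.array([[1.0, 2, 3], [2, 4, 6]])).matrix
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        d = build_rdm(np.array([[1.0, 2, 3], [3, 2, 1]])).matrix
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_zero_correlation_example(self):
        d = build_rdm(np.array([[1.0, 0, 1, 0], [1, 1, 0, 0]])).matrix
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_agreement_with_per_pair_pearson(self, rng):
        # independent oracle: scipy.stats.pearsonr entry by entry
        for _ in range(100):
            acts = rng.normal(size=(rng.integers(3, 8), rng.integers(3, 10)))
            d = build_rdm(acts).matrix
            n = acts.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    expect = 1 - stats.pearsonr(acts[i], acts[j]).statistic
                    assert d[i, j] == pytest.approx(expect, abs=1e-9)

    def test_symmetry_zero_diagonal_range(self, rng):
        acts = rng.normal(size=(20, 15))
        rdm = build_rdm(acts)
        d = rdm.matrix
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_degenerate_row_convention_and_logging(self, rng, caplog):
        acts = rng.normal(size=(4, 6))
        acts[2] = 3.14  # zero-variance row
        with caplog.at_level("WARNING", logger="degensim.rsa_metrics"):
            d = build_rdm(acts).matrix
        assert "zero-variance" in caplog.text
        assert np.all(d[2, [0, 1, 3]] == 1.0) and np.all(d[[0, 1, 3], 2] == 1.0)
        assert d[2, 2] == 0.0

    def test_duplicated_stimulus_has_zero_dissimilarity(self, rng):
        acts = rng.normal(size=(5, 8))
        acts[3] = acts[1]
        d = build_rdm(acts).matrix
        assert d[1, 3] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_rdm(np.ones((3, 1)))


class TestUTV:
    def test_row_major_order_and_length(self):
        m = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
        rdm = RDM((0, 1, 2), m)
        assert np.array_equal(utv(rdm), [1, 2, 3])
        assert len(utv(RDM((0, 1), np.array([[0.0, 5], [5, 0]])))) == 1

    def test_inverse_consistency(self, rng):
        acts = rng.normal(size=(6, 9))
        rdm = build_rdm(acts)
        rebuilt = from_utv(utv(rdm), rdm.condition_ids)
        assert np.allclose(rebuilt.matrix, rdm.matrix, atol=1e-12)


class TestCompareRDMs:
    def test_self_comparison_is_one(self, rng):
        rdm = build_rdm(rng.normal(size=(8, 10)))
        assert compare_rdms(rdm, rdm).tau_a == pytest.approx(1.0)

    def test_monotone_transform_of_entries_gives_one(self, rng):
        rdm = build_rdm(rng.normal(size=(8, 10)))
        squashed = RDM(rdm.condition_ids, np.sqrt(rdm.matrix))
        assert compare_rdms(rdm, squashed).tau_a == pytest.approx(1.0)

    def test_four_condition_toy_matches_brute_force(self, rng):
        a = build_rdm(rng.normal(size=(4, 6)))
        b = build_rdm(rng.normal(size=(4, 6)))
        cmp_ = compare_rdms(a, b)
        assert cmp_.n_pairs == 6
        assert cmp_.tau_a == pytest.approx(kendall_tau_a_brute(utv(a), utv(b)), abs=1e-12)

    def test_include_diagonal_reads_superclass_diagonal(self):
        # two superclass-level RDMs that differ only in their within-
        # superclass (diagonal) organisation: utv-only comparison is blind
        # to it, the diagonal-included comparison is not
        off = np.array([[0.0, 0.6, 0.7], [0.6, 0.0, 0.8], [0.7, 0.8, 0.0]])
        a = RDM((0, 1, 2), off + np.diag([0.1, 0.2, 0.3]))
        b = RDM((0, 1, 2), off + np.diag([0.3, 0.2, 0.1]))
        assert compare_rdms(a, b).tau_a == pytest.approx(1.0)
        assert compare_rdms(a, b, include_diagonal=True).tau_a < 1.0
        assert compare_rdms(a, a, include_diagonal=True).tau_a == pytest.approx(1.0)

    def test_condition_mismatch_rejected(self, rng):
        a = build_rdm(rng.normal(size=(4, 6)))
        b = build_rdm(rng.normal(size=(4, 6)), condition_ids=(9, 8, 7, 6))
        with pytest.raises(InvalidArgumentError):
            compare_rdms(a, b)


class TestNoiseFloor:
    def test_constant_rdm_gives_exactly_zero(self):
        n = 6
        m = np.full((n, n), 0.7)
        np.fill_diagonal(m, 0.0)
        res = scrambled_noise_floor(RDM(tuple(range(n)), m), n_reps=5, seed=0)
        assert res.taus == (0.0,) * 5

    def test_large_random_rdm_floor_is_tiny(self, rng):
        # null bound: sd(tau) ~ sqrt(4/(9 n_pairs)) ~ 9.4e-4 at 1000
        # conditions, so 25 scrambles average within 0.005 of zero
        n = 1000
        vec = rng.random(n * (n - 1) // 2)
        rdm = from_utv(vec)
        res = scrambled_noise_floor(rdm, n_reps=25, seed=1)
        assert abs(res.mean_tau) <= 0.005
        assert res.mean_abs_tau <= 0.005

    def test_row_scramble_mode_and_guards(self, rng):
        rdm = build_rdm(rng.normal(size=(6, 8)))
        res = scrambled_noise_floor(rdm, n_reps=3, seed=2, method="rows")
        assert all(-1 <= t <= 1 for t in res.taus)
        with pytest.raises(InvalidArgumentError):
            scrambled_noise_floor(rdm, n_reps=0, seed=0)
        two = build_rdm(rng.normal(size=(2, 5)))
        with pytest.raises(InvalidArgumentError):
            scrambled_noise_floor(two, n_reps=1, seed=0)


class TestSuperclassRDM:
    def test_constant_rdm_collapses_to_constant(self):
        h = make_hierarchy(2, 2)
        n = 8
        m = np.full((n, n), 0.3)
        np.fill_diagonal(m, 0.0)
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        s = superclass_rdm(RDM(tuple(range(n)), m), labels, h)
        assert np.allclose(s.matrix, 0.3)

    def test_hand_built_block_means(self):
        h = make_hierarchy(2, 1)
        m = np.array(
            [
                [0.0, 0.2, 0.5, 0.7],
                [0.2, 0.0, 0.9, 1.1],
                [0.5, 0.9, 0.0, 0.4],
                [0.7, 1.1, 0.4, 0.0],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        s = superclass_rdm(RDM(tuple(range(4)), m), labels, h)
        assert s.matrix[0, 0] == pytest.approx(0.2)
        assert s.matrix[1, 1] == pytest.approx(0.4)
        assert s.matrix[0, 1] == pytest.approx((0.5 + 0.7 + 0.9 + 1.1) / 4)

    def test_invariant_to_within_superclass_permutation(self, rng):
        h = make_hierarchy(2, 2)
        acts = rng.normal(size=(12, 10))
        labels = np.repeat([0, 1, 2, 3], 3)
        rdm = build_rdm(acts)
        base = superclass_rdm(rdm, labels, h).matrix
        perm = np.array([1, 2, 0, 4, 5, 3, 7, 8, 6, 10, 11, 9])  # rotate within classes
        rdm_p = build_rdm(acts[perm])
        swapped = superclass_rdm(rdm_p, labels[perm], h).matrix
        assert np.allclose(base, swapped, atol=1e-12)

    def test_singleton_superclass_rejected(self, rng):
        h = make_hierarchy(2, 1)
        rdm = build_rdm(rng.normal(size=(3, 6)))
        with pytest.raises(InvalidArgumentError):
            superclass_rdm(rdm, np.array([0, 0, 1]), h)


class TestAverageRDMs:
    def test_average_of_one_is_itself(self, rng):
        rdm = build_rdm(rng.normal(size=(5, 6)))
        assert np.array_equal(average_rdms([rdm]).matrix, rdm.matrix)

    def test_average_of_x_and_2x(self, rng):
        rdm = build_rdm(rng.normal(size=(5, 6)))
        doubled = RDM(rdm.condition_ids, 2 * rdm.matrix)
        avg = average_rdms([rdm, doubled])
        assert np.allclose(avg.matrix, 1.5 * rdm.matrix, atol=1e-12)
        assert np.all(np.diag(avg.matrix) == 0.0)

    def test_empty_and_mismatched_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            average_rdms([])
        a = build_rdm(rng.normal(size=(4, 6)))
        b = build_rdm(rng.normal(size=(5, 6)))
        with pytest.raises(InvalidArgumentError):
            average_rdms([a, b])


class TestPenultimateActivations:
    def test_shape_and_determinism(self, tiny_trained):
        model, test = tiny_trained
        a1 = penultimate_activations(model, test)
        a2 = penultimate_activations(model, test)
        assert a1.shape == (len(test), 32)  # dense_2 width
        assert np.array_equal(a1, a2)

    def test_fully_injured_model_constant_rows(self, tiny_trained):
        model, test = tiny_trained
        cat = inj.build_catalog(model)
        injured = inj.apply(model, inj.advance(inj.initial_state(cat, seed=0), 1.0))
        acts = penultimate_activations(injured, test)
        assert np.allclose(acts, acts[0])
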