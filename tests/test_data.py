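import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancekit.data import (
    Dataset,
    build_connectome,
    chance_level,
    devectorize_upper,
    feature_similarity,
    make_fold_plan,
    read_dataset,
    vectorize_upper,
    write_dataset,
)


class TestDataset:
    def test_valid_roundtrip_fields(self):
        ds = Dataset(X=np.arange(6.0).reshape(3, 2), y=np.array([0, 1, 0]))
        assert ds.n_samples == 3 and ds.n_features == 2 and ds.n_classes == 2

    @pytest.mark.parametrize(
        "X, y, msg",
        [
            (np.ones((3, 2)), np.array([0, 0, 0]), "2 classes"),
            (np.ones((3, 2)), np.array([0, 1]), "does not match"),
            (np.array([[1.0, np.nan], [0, 1]]), np.array([0, 1]), "non-finite"),
            (np.ones((1, 2)), np.array([0]), "2 samples"),
            (np.ones((3, 2)), np.array([0, 2, 2]), "contiguous"),
        ],
    )
    def test_invariant_violations_raise(self, X, y, msg):
        with pytest.raises(ValueError, match=msg):
            Dataset(X=X, y=y)

    def test_from_arrays_maps_labels(self):
        ds = Dataset.from_arrays(np.ones((4, 2)), ["hc", "scz", "hc", "bp"])
        assert sorted(ds.label_names) == ["bp", "hc", "scz"]
        assert np.array_equal(np.sort(np.unique(ds.y)), [0, 1, 2])

    def test_with_X_keeps_shape_contract(self):
        ds = Dataset(X=np.ones((3, 2)), y=np.array([0, 1, 0]))
        with pytest.raises(ValueError, match="shape"):
            ds.with_X(np.ones((3, 3)))


class TestConnectome:
    def test_perfectly_correlated_pair_is_clipped_fisher_z(self):
        ts = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        Z = build_connectome(ts, clip=0.999999)
        expected = np.arctanh(0.999999)  # ~7.2543
        assert Z[0, 1] == pytest.approx(expected, rel=1e-12)
        assert Z[0, 1] == pytest.approx(7.2543, abs=5e-5)

    def test_uncorrelated_pair_gives_zero_edge(self):
        ts = np.column_stack([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        Z = build_connectome(ts)
        assert Z[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_forced_zero_and_symmetric(self):
        rng = np.random.default_rng(0)
        Z = build_connectome(rng.normal(size=(50, 6)))
        assert np.array_equal(np.diag(Z), np.zeros(6))
        assert np.array_equal(Z, Z.T)

    def test_zero_variance_node_named_in_error(self):
        ts = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="node index 1"):
            build_connectome(ts)

    def test_nonfinite_input_rejected(self):
        ts = np.ones((5, 2)) + np.arange(10.0).reshape(5, 2)
        ts[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            build_connectome(ts)


class TestVectorizeUpper:
    def test_shen_atlas_dimension(self):
        v = vectorize_upper(np.zeros((268, 268)))
        assert v.shape == (35778,)

    def test_two_and_three_node_ordering(self):
        a = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert np.array_equal(vectorize_upper(a), [5.0])
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert np.array_equal(vectorize_upper(m), [1.0, 2.0, 3.0])

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError, match="square"):
            vectorize_upper(np.zeros((3, 4)))

    @pytest.mark.parametrize("N", range(2, 7))
    def test_roundtrip_exhaustive_small_sizes(self, N):
        rng = np.random.default_rng(N)
        M = rng.normal(size=(N, N))
        M = M + M.T
        np.fill_diagonal(M, 0.0)
        assert np.array_equal(devectorize_upper(vectorize_upper(M)), M)

    def test_devectorize_rejects_nontriangular_length(self):
        with pytest.raises(ValueError, match="triangular"):
            devectorize_upper(np.arange(4.0))


class TestChanceLevel:
    def test_cohort_class_sizes(self):
        y = np.repeat([0, 1, 2, 3], [117, 46, 44, 38])
        assert chance_level(y) == pytest.approx(117 / 245)
        assert round(100 * chance_level(y), 2) == 47.76

    def test_balanced_and_degenerate(self):
        assert chance_level([0, 1, 0, 1]) == 0.5
        assert chance_level([2, 2, 2]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chance_level([])

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_and_permutation_invariance(self, labels):
        y = np.asarray(labels)
        c = chance_level(y)
        K = np.unique(y).size
        assert 1 / K <= c <= 1
        rng = np.random.default_rng(0)
        assert chance_level(rng.permutation(y)) == c


class TestFeatureSimilarity:
    def test_identity_is_exactly_one(self):
        X = np.random.default_rng(1).normal(size=(5, 4))
        assert feature_similarity(X, X.copy()).r == 1.0

    def test_sign_flip_is_minus_one(self):
        X = np.random.default_rng(1).normal(size=(5, 4))
        assert feature_similarity(X, -X).r == pytest.approx(-1.0)

    def test_hand_computed_four_pair_value(self):
        # Pearson on (1,2,3,4) vs (1,2,3,8): cov=11, sx^2=5, sy^2=29
        Xo = np.array([[1.0, 2.0], [3.0, 4.0]])
        Xe = np.array([[1.0, 2.0], [3.0, 8.0]])
        expected = 11.0 / np.sqrt(5.0 * 29.0)
        assert feature_similarity(Xo, Xe).r == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_and_zero_variance(self):
        with pytest.raises(ValueError, match="shape"):
            feature_similarity(np.ones((2, 2)), np.ones((2, 3)))
        with pytest.raises(ValueError, match="variance"):
            feature_similarity(np.ones((2, 2)), np.zeros((2, 2)) + np.arange(4).reshape(2, 2))

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        r_ab = feature_similarity(A, B).r
        assert feature_similarity(B, A).r == pytest.approx(r_ab, rel=1e-12)
        assert feature_similarity(2.5 * A + 1, 2.5 * B + 1).r == pytest.approx(r_ab, rel=1e-9)

    def test_per_sample_rows(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 5))
        rep = feature_similarity(A, A + rng.normal(scale=1e-3, size=A.shape), per_sample=True)
        assert rep.per_sample_r.shape == (3,)
        assert np.all(rep.per_sample_r > 0.99)


class TestFoldPlan:
    def test_exact_partition(self):
        y = np.repeat([0, 1], 5)
        plan = make_fold_plan(y, 5, stratified=True, seed=0)
        held = np.sort(np.concatenate([plan.held_out(k) for k in range(5)]))
        assert np.array_equal(held, np.arange(10))
        assert all(plan.held_out(k).size == 2 for k in range(5))

    def test_stratified_proportions_within_one(self):
        y = np.repeat([0, 1, 2, 3], [117, 46, 44, 38])
        plan = make_fold_plan(y, 5, stratified=True, seed=1)
        for k in range(5):
            ho = plan.held_out(k)
            for cls, total in zip(range(4), (117, 46, 44, 38)):
                got = np.sum(y[ho] == cls)
                assert abs(got - total / 5) <= 1

    def test_deterministic_given_seed(self):
        y = np.repeat([0, 1], 20)
        a = make_fold_plan(y, 4, seed=3).assignments
        b = make_fold_plan(y, 4, seed=3).assignments
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_fold_plan(y, 4, seed=4).assignments)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_fold_plan(np.array([0, 1, 0]), 4)

    def test_small_class_falls_back_unstratified(self):
        y = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="unstratified"):
            plan = make_fold_plan(y, 5, stratified=True, seed=0)
        assert not plan.stratified
        assert np.array_equal(
            np.sort(np.concatenate([plan.held_out(k) for k in range(5)])), np.arange(10)
        )


class TestIO:
    def _ds(self):
        rng = np.random.default_rng(9)
        return Dataset(
            X=rng.normal(size=(3, 2)) * 1e-3 + np.pi,
            y=np.array([0, 1, 0]),
            feature_names=["edge_a", "edge_b"],
        )

    def test_csv_roundtrip_full_precision(self, tmp_path):
        ds = self._ds()
        write_dataset(ds, tmp_path / "f.csv", tmp_path / "y.csv")
        back = read_dataset(tmp_path / "f.csv", tmp_path / "y.csv")
        assert np.array_equal(back.X, ds.X)
        assert np.array_equal(back.y, ds.y)
        assert back.feature_names == ["edge_a", "edge_b"]

    def test_npy_roundtrip_bit_exact(self, tmp_path):
        ds = self._ds()
        write_dataset(ds, tmp_path / "f.npy", tmp_path / "y.npy")
        back = read_dataset(tmp_path / "f.npy", tmp_path / "y.npy")
        assert np.array_equal(back.X, ds.X) and back.X.dtype == ds.X.dtype

    def test_row_count_mismatch_names_both_counts(self, tmp_path):
        np.save(tmp_path / "f.npy", np.ones((5, 2)))
        (tmp_path / "y.csv").write_text("label\n0\n1\n0\n1\n")
        with pytest.raises(ValueError, match=r"\(5\).*\(4\)"):
            read_dataset(tmp_path / "f.npy", tmp_path / "y.csv")

    def test_unknown_extension_rejected(self, tmp_path):
        (tmp_path / "f.parquet").write_text("")
        with pytest.raises(ValueError, match="extension"):
            read_dataset(tmp_path / "f.parquet", tmp_path / "y.csv")

    def test_unparseable_values_rejected(self, tmp_path):
        (tmp_path / "f.csv").write_text("a,b\n1.0,oops\n2.0,3.0\n")
        (tmp_path / "y.csv").write_text("0\n1\n")
        with pytest.raises(ValueError, match="non-numeric|parse"):
            read_dataset(tmp_path / "f.csv", tmp_path / "y.csv")

    def test_headerless_csv(self, tmp_path):
        (tmp_path / "f.csv").write_text("1.0,2.0\n3.0,4.0\n")
        (tmp_path / "y.csv").write_text("1\n0\n")
        ds = read_dataset(tmp_path / "f.csv", tmp_path / "y.csv")
        assert ds.feature_names is None
        assert np.array_equal(ds.X, [[1.0, 2.0], [3.0, 4.0]])
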