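"""SVD variance decomposition, bootstrap CIs, permutation controls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfc import (
    BOLDRun,
    DataMatrix,
    average_projection,
    bold_to_datamatrix,
    bootstrap_svd,
    generate_atlas,
    pair_index,
    permute_dataset,
    planted_lowrank_dataset,
    pool_datasets,
    reproducible_dimension,
    residual_fc,
    svd_variance,
    unflatten_bold,
    unvectorize,
)


def _dm(X, tags=None):
    m = X.shape[1]
    return DataMatrix(
        X=X,
        subject_ids=[f"s{j:02d}" for j in range(m)],
        source_tags=tags or ["x"] * m,
    )


class TestSVDVariance:
    def test_rank_one_concentrates_all_variance(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=6))
        _, fracs, _, _ = svd_variance(X)
        assert fracs[0] == pytest.approx(1.0, abs=1e-12)
        assert fracs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_columns_closed_form(self):
        X = np.zeros((4, 2))
        X[0, 0] = 3.0
        X[1, 1] = 4.0
        _, fracs, _, _ = svd_variance(X)
        assert sorted(fracs, reverse=True) == pytest.approx([16 / 25, 9 / 25])

    def test_eckart_young_truncation_error(self, rng):
        X = rng.normal(size=(50, 10))
        s, _, u, v = svd_variance(X)
        for d in (1, 3, 7):
            approx = (u[:, :d] * s[:d]) @ v[:, :d].T
            err = np.linalg.norm(X - approx, "fro")
            assert err == pytest.approx(np.sqrt(np.sum(s[d:] ** 2)), rel=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            svd_variance(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_singular_values_invariant_under_common_permutations(self, rng):
        X = rng.normal(size=(30, 8))
        s0 = svd_variance(X)[0]
        assert np.allclose(svd_variance(X[rng.permutation(30)])[0], s0, atol=1e-10)
        assert np.allclose(svd_variance(X[:, rng.permutation(8)])[0], s0, atol=1e-10)
        flips = rng.choice([-1.0, 1.0], 8)
        assert np.allclose(svd_variance(X * flips)[0], s0, atol=1e-10)


class TestReproducibleDimension:
    @pytest.mark.parametrize(
        "cis,expected",
        [
            ([(10, 11), (5, 6), (4.5, 5.5)], 1),
            ([(10, 11), (5, 6), (2, 3), (1.9, 2.5)], 2),
            ([(10, 12), (11, 13), (2, 3)], 0),
        ],
    )
    def test_contiguous_rule(self, cis, expected):
        lo = [c[0] for c in cis]
        hi = [c[1] for c in cis]
        assert reproducible_dimension(lo, hi) == expected

    def test_last_rule_ignores_earlier_overlaps(self):
        lo, hi = [10, 9.5, 5], [11, 10.5, 6]
        assert reproducible_dimension(lo, hi, rule="contiguous") == 0
        assert reproducible_dimension(lo, hi, rule="last") == 2

    @given(st.integers(min_value=0, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_contiguous_rule_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mid = np.sort(rng.uniform(0, 10, 6))[::-1]
        half = rng.uniform(0, 1.5, 6)
        lo, hi = mid - half, mid + half

        def disjoint(i):
            return lo[i] > hi[i + 1] or lo[i + 1] > hi[i]

        brute = 0
        for i in range(5):
            if not disjoint(i):
                break
            brute += 1
        assert reproducible_dimension(lo, hi) == brute


class TestBootstrapSVD:
    def test_planted_rank_one_recovered(self):
        dm = planted_lowrank_dataset(300, 21, 1, (0.9,), 0.1, seed=2)
        res = bootstrap_svd(dm, B=200, seed=2)
        assert res.reproducible_dim == 1
        assert res.variance_fractions[0] == pytest.approx(0.9, abs=0.05)

    def test_planted_rank_two_recovered(self):
        dm = planted_lowrank_dataset(300, 21, 2, (0.6, 0.3), 0.1, seed=2)
        res = bootstrap_svd(dm, B=200, seed=2)
        assert res.reproducible_dim == 2

    def test_pure_noise_has_no_reproducible_subspace(self, rng):
        dm = _dm(rng.standard_normal((300, 21)))
        res = bootstrap_svd(dm, B=200, seed=0)
        assert res.reproducible_dim == 0

    def test_deterministic_given_seed(self, rng):
        dm = _dm(rng.standard_normal((50, 8)))
        a = bootstrap_svd(dm, B=150, seed=7)
        b = bootstrap_svd(dm, B=150, seed=7)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.ci_high, b.ci_high)

    def test_small_b_warns_and_few_subjects_rejected(self, rng):
        dm = _dm(rng.standard_normal((20, 5)))
        with pytest.warns(UserWarning):
            bootstrap_svd(dm, B=50, seed=0)
        tiny = DataMatrix(
            X=rng.standard_normal((20, 2)), subject_ids=["a", "b"], source_tags=["x"] * 2
        )
        with pytest.raises(ValueError):
            bootstrap_svd(tiny, B=200, seed=0)

    def test_subject_blocks_resampled_together(self, rng):
        # two columns per subject; fractions must sum to 1 and CIs be finite
        X = rng.standard_normal((40, 8))
        dm = DataMatrix(
            X=X,
            subject_ids=[f"s{j // 2}" for j in range(8)],
            source_tags=["a", "b"] * 4,
        )
        res = bootstrap_svd(dm, B=150, seed=1)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.ci_low <= res.ci_high)


class TestAverageProjection:
    def test_single_column_is_orthogonal_projection(self, rng):
        x = rng.normal(size=20)
        u = rng.normal(size=20)
        u /= np.linalg.norm(u)
        dm = DataMatrix(X=x[:, None], subject_ids=["s0"], source_tags=["e"])
        assert np.allclose(average_projection(dm, u), (u @ x) * u)

    def test_projection_and_averaging_commute(self, rng):
        X = rng.normal(size=(30, 6))
        u = rng.normal(size=30)
        u /= np.linalg.norm(u)
        dm = _dm(X)
        via_mean = (u @ X.mean(axis=1)) * u
        assert np.allclose(average_projection(dm, u), via_mean, atol=1e-12)

    def test_source_filter_equals_submatrix_computation(self, rng):
        X = rng.normal(size=(30, 6))
        tags = ["empirical"] * 2 + ["model"] * 4
        dm = DataMatrix(X=X, subject_ids=[f"s{j}" for j in range(6)], source_tags=tags)
        u = rng.normal(size=30)
        u /= np.linalg.norm(u)
        sub = DataMatrix(X=X[:, :2], subject_ids=["s0", "s1"], source_tags=["e"] * 2)
        assert np.allclose(
            average_projection(dm, u, source_filter="empirical"),
            average_projection(sub, u),
        )


@pytest.fixture(scope="module")
def planted_matrices():
    dm = planted_lowrank_dataset(780, 21, 1, (0.9,), 0.1, seed=0)
    idx = pair_index(40)
    return dm, [unvectorize(dm.X[:, j], idx, 40) for j in range(21)]


class TestPermutations:
    def test_forced_identity_permutation_is_a_no_op(self, planted_matrices):
        dm, mats = planted_matrices
        atlas = generate_atlas(40)
        out = permute_dataset(mats, atlas, "links", permutations=np.arange(780))
        assert np.allclose(out.X, dm.X)

    def test_common_permutation_preserves_singular_values(self, planted_matrices):
        dm, mats = planted_matrices
        atlas = generate_atlas(40)
        perm = np.random.default_rng(3).permutation(780)
        out = permute_dataset(mats, atlas, "links", permutations=perm)
        assert np.allclose(svd_variance(out)[0], svd_variance(dm)[0], atol=1e-10)

    @pytest.mark.parametrize("mode", ["links", "regions", "within_hemisphere"])
    def test_independent_permutations_destroy_reproducibility(self, planted_matrices, mode):
        _, mats = planted_matrices
        atlas = generate_atlas(40)
        out = permute_dataset(mats, atlas, mode, seed=8)
        res = bootstrap_svd(out, B=200, seed=8)
        assert res.reproducible_dim == 0

    def test_within_hemisphere_mode_preserves_homotopic_pairing(self):
        # a matrix carrying weight only on homotopic pairs is invariant
        atlas = generate_atlas(10)
        w = np.zeros((10, 10))
        for i, j in atlas.homotopic_pairs():
            w[i, j] = w[j, i] = 1.0
        out = permute_dataset([w] * 3, atlas, "within_hemisphere", seed=0)
        from scfc import vectorize_upper

        base = vectorize_upper(w, atlas).values
        assert np.allclose(out.X, base[:, None])


class TestPoolingAndResiduals:
    def test_pooled_column_counts(self, rng):
        subjects = [f"s{j:02d}" for j in range(21)]
        models = [f"m{i}" for i in range(7)]
        sim = [(m, {s: rng.normal(size=10) for s in subjects}) for m in models]
        assert pool_datasets(sim).n_observations == 147
        emp = [("empirical", {s: rng.normal(size=10) for s in subjects})]
        pooled = pool_datasets(emp + sim)
        assert pooled.n_observations == 168
        # subject-major ordering keeps a subject's columns adjacent
        assert pooled.subject_ids[:8] == ["s00"] * 8

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            pool_datasets(
                [("a", {"s0": np.zeros(5), "s1": np.zeros(5), "s2": np.zeros(5)}),
                 ("b", {"s0": np.zeros(6), "s1": np.zeros(6), "s2": np.zeros(6)})]
            )

    def test_residuals_zero_when_simulation_matches(self, rng):
        emp = {f"s{j}": rng.normal(size=12) for j in range(21)}
        sim = {f"m{i}": {s: emp[s].copy() for s in emp} for i in range(7)}
        dm = residual_fc(emp, sim)
        assert dm.n_observations == 147
        assert np.allclose(dm.X, 0.0)

    def test_residual_subtraction_order(self):
        emp = {"s0": np.array([3.0, 1.0])}
        sim = {"m": {"s0": np.array([1.0, 1.0])}}
        dm = residual_fc(emp, sim)
        assert np.array_equal(dm.X[:, 0], [2.0, 0.0])


class TestBOLDFlattening:
    def test_feature_count_and_round_trip(self, rng):
        runs = {
            f"s{j}": BOLDRun(values=rng.normal(size=(6, 20))) for j in range(4)
        }
        dm = bold_to_datamatrix(runs)
        assert dm.n_features == 120
        back = unflatten_bold(dm.X[:, 0], (6, 20))
        assert np.array_equal(back, runs["s0"].values)

    def test_flattening_is_region_major(self):
        run = BOLDRun(values=np.array([[1.0, 2.0], [3.0, 4.0]]))
        dm = bold_to_datamatrix({"s0": run})
        assert np.array_equal(dm.X[:, 0], [1.0, 2.0, 3.0, 4.0])
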