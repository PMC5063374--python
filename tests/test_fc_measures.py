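"""Connectivity measures: correlation, information estimators, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from scfc import (
    BOLDRun,
    DomainError,
    ct3,
    dynamic_fc,
    gaussian_ct3,
    gaussian_mi,
    generate_atlas,
    global_signal_regression,
    knn_mutual_information,
    knn_total_correlation,
    mi_fc,
    pair_index,
    pearson_fc,
    triplet_index,
    unvectorize,
    vectorize_upper,
)


def _gaussian_run(n_regions, n_samples, rho=0.0, seed=0, tr=3.29):
    rng = np.random.default_rng(seed)
    cov = np.full((n_regions, n_regions), rho)
    np.fill_diagonal(cov, 1.0)
    x = rng.multivariate_normal(np.zeros(n_regions), cov, size=n_samples).T
    return BOLDRun(values=x, tr=tr)


class TestGSR:
    def test_idempotent(self, rng):
        run = BOLDRun(values=rng.normal(size=(10, 50)))
        once = global_signal_regression(run)
        twice = global_signal_regression(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)
        assert once.gsr_applied

    def test_identical_regions_leave_zero_residuals(self):
        base = np.sin(np.linspace(0, 10, 40))
        run = BOLDRun(values=np.tile(base, (6, 1)))
        out = global_signal_regression(run)
        assert np.allclose(out.values, 0, atol=1e-12)

    def test_residuals_orthogonal_to_global_mean(self, rng):
        run = BOLDRun(values=rng.normal(size=(12, 80)))
        g = run.values.mean(axis=0)
        out = global_signal_regression(run)
        for row in out.values:
            r = np.corrcoef(row, g)[0, 1]
            assert abs(r) < 1e-10

    def test_constant_global_signal_warns(self, rng):
        a, b = rng.normal(size=(2, 30))
        x = np.vstack([a, -a, b, -b])  # region mean is exactly zero
        with pytest.warns(UserWarning):
            global_signal_regression(BOLDRun(values=x))


class TestPearsonFC:
    def test_perfect_linear_relations(self, rng):
        x = rng.normal(size=60)
        run = BOLDRun(values=np.vstack([x, 2 * x + 3, -x]))
        r = pearson_fc(run)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_constant_region_raises_unless_opted_out(self, rng):
        x = rng.normal(size=(3, 30))
        x[1] = 5.0
        with pytest.raises(ValueError):
            pearson_fc(BOLDRun(values=x))
        r = pearson_fc(BOLDRun(values=x), on_constant="zero")
        assert r[0, 1] == 0.0


class TestVectorization:
    @pytest.mark.parametrize(
        "n,subset,length",
        [
            (160, "all", 12720),
            (160, "intrahemispheric", 6320),
            (461, "all", 106030),
            (40, "all", 780),
        ],
    )
    def test_lengths(self, n, subset, length):
        atlas = generate_atlas(n) if n % 2 == 0 else None
        vec = vectorize_upper(np.zeros((n, n)), atlas, subset=subset)
        assert len(vec.values) == length

    def test_odd_parcellation_pair_count(self):
        # 461 regions cannot form a two-hemisphere atlas; the pair count
        # contract still holds for the plain vectorization above
        assert len(pair_index(461)) == 106030
        assert len(pair_index(825)) == 339900

    @given(st.integers(min_value=2, max_value=12))
    @settings(max_examples=15, deadline=None)
    def test_round_trip_bijection(self, n):
        rng = np.random.default_rng(n)
        m = rng.normal(size=(n, n))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        vec = vectorize_upper(m)
        back = unvectorize(vec.values, vec.index, n)
        assert np.array_equal(back, m)

    def test_lexicographic_order(self):
        idx = pair_index(4)
        assert idx.tolist() == [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]
        tri = triplet_index(4)
        assert tri.tolist() == [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]


class TestGaussianClosedForms:
    def test_mi_zero_at_independence(self):
        assert gaussian_mi(0.0) == 0.0

    def test_mi_sign_symmetric_and_monotone(self):
        assert gaussian_mi(-0.6) == pytest.approx(gaussian_mi(0.6))
        vals = [gaussian_mi(r) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(vals) > 0)

    def test_mi_domain_error(self):
        with pytest.raises(DomainError):
            gaussian_mi(1.0)

    def test_mi_against_numerical_double_integration(self):
        # independent oracle: quadrature of the bivariate Gaussian MI integral
        rho = 0.9
        det = 1 - rho**2

        def integrand(y, x):
            p = np.exp(-(x**2 - 2 * rho * x * y + y**2) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )
            px = stats.norm.pdf(x)
            py = stats.norm.pdf(y)
            return p * np.log(p / (px * py)) if p > 1e-300 else 0.0

        val, _ = integrate.dblquad(integrand, -8, 8, -8, 8, epsabs=1e-6)
        assert gaussian_mi(rho) == pytest.approx(val, abs=1e-4)

    def test_ct3_zero_when_uncorrelated(self):
        assert gaussian_ct3(0.0, 0.0, 0.0) == 0.0

    def test_ct3_reduces_to_pairwise_mi(self):
        assert gaussian_ct3(0.7, 0.0, 0.0) == pytest.approx(gaussian_mi(0.7))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_ct3_expanded_form_matches_log_determinant(self, seed):
        rng = np.random.default_rng(seed)
        # sample a guaranteed-PD correlation matrix from random data
        x = rng.normal(size=(3, 30))
        R = np.corrcoef(x)
        val = gaussian_ct3(R[0, 1], R[1, 2], R[0, 2])
        assert val == pytest.approx(-0.5 * np.log(np.linalg.det(R)), abs=1e-12)

    def test_ct3_domain_error_on_invalid_triple(self):
        with pytest.raises(DomainError):
            gaussian_ct3(0.9, 0.9, -0.9)


class TestKnnEstimators:
    def test_mi_near_zero_for_independent_gaussians(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        assert abs(knn_mutual_information(x, y, k=4)) < 0.05

    def test_mi_matches_gaussian_closed_form(self, rng):
        rho = 0.9
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        est = knn_mutual_information(xy[:, 0], xy[:, 1], k=4)
        assert est == pytest.approx(gaussian_mi(rho), abs=0.1)

    def test_mi_grows_without_bound_for_identical_variables(self, rng):
        ests = []
        for n in (200, 800):
            x = rng.normal(size=n)
            ests.append(knn_mutual_information(x, x, k=4))
        assert ests[0] > 1.0
        assert ests[1] > ests[0]

    def test_k_too_large_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            knn_mutual_information(x, x, k=10)

    def test_estimate_converges_with_sample_size(self):
        rho = 0.6
        errs = []
        for n in (500, 4000):
            rng = np.random.default_rng(7)
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            est = knn_mutual_information(xy[:, 0], xy[:, 1], k=4)
            errs.append(abs(est - gaussian_mi(rho)))
        assert errs[1] < errs[0]

    def test_total_correlation_matches_trivariate_closed_form(self, rng):
        R = np.array([[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1]])
        xyz = rng.multivariate_normal(np.zeros(3), R, size=2000)
        est = knn_total_correlation(xyz.T, k=4)
        assert est == pytest.approx(gaussian_ct3(0.5, 0.2, 0.3), abs=0.15)


class TestPairwiseSweeps:
    def test_mi_fc_length_and_permutation_invariance(self, rng):
        run = _gaussian_run(8, 120, rho=0.3, seed=1)
        vec = mi_fc(run, k=4)
        assert len(vec.values) == 28
        perm = rng.permutation(120)
        shuffled = BOLDRun(values=run.values[:, perm], tr=run.tr)
        vec2 = mi_fc(shuffled, k=4)
        assert np.allclose(vec.values, vec2.values, atol=1e-12)

    def test_mi_fc_tracks_gaussian_curve(self):
        run = _gaussian_run(10, 400, rho=0.5, seed=3)
        cfc = vectorize_upper(pearson_fc(run)).values
        mfc = mi_fc(run, k=4).values
        dev = np.abs(mfc - gaussian_mi(cfc))
        assert np.median(dev) < 0.1

    def test_ct3_length_and_gate(self):
        run = _gaussian_run(10, 80, seed=2)
        vec = ct3(run, k=4)
        assert len(vec.values) == 120
        big = _gaussian_run(160, 30, seed=2)
        with pytest.raises(ValueError, match="allow_large"):
            ct3(big, k=4)

    def test_ct3_of_independent_series_converges_to_zero(self):
        meds = []
        for n in (200, 1000):
            run = _gaussian_run(6, n, rho=0.0, seed=4)
            meds.append(np.median(np.abs(ct3(run, k=4).values)))
        assert meds[1] < meds[0]
        assert meds[1] < 0.05

    def test_ct3_tracks_trivariate_gaussian_predictions(self):
        run = _gaussian_run(6, 2000, rho=0.4, seed=5)
        r = pearson_fc(run)
        est = ct3(run, k=4).values
        pred = np.array(
            [gaussian_ct3(r[i, j], r[j, k], r[i, k]) for i, j, k in triplet_index(6)]
        )
        assert np.median(np.abs(est - pred)) < 0.15


class TestDynamicFC:
    def test_window_counts(self):
        run = _gaussian_run(6, 200, rho=0.2, seed=6)
        for w, n_windows in [(8, 25), (10, 20), (100, 2)]:
            vec = dynamic_fc(run, w)
            assert vec.n_windows == n_windows
            assert len(vec.values) == n_windows * 15

    def test_full_length_window_equals_static_fc(self):
        run = _gaussian_run(6, 200, rho=0.2, seed=7)
        vec = dynamic_fc(run, 200)
        static = vectorize_upper(pearson_fc(run)).values
        assert np.allclose(vec.values, static)

    def test_non_dividing_window_rejected_unless_truncated(self):
        run = _gaussian_run(4, 200, seed=8)
        with pytest.raises(ValueError):
            dynamic_fc(run, 33)
        vec = dynamic_fc(run, 33, truncate=True)
        assert vec.n_windows == 6

    def test_window_average_correlates_with_full_run_fc(self):
        run = _gaussian_run(8, 200, rho=0.4, seed=9)
        vec = dynamic_fc(run, 8)
        per_window = vec.values.reshape(25, -1)
        static = vectorize_upper(pearson_fc(run)).values
        r = np.corrcoef(per_window.mean(axis=0), static)[0, 1]
        assert r > 0.8
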