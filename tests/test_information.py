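"""Histogram and k-nearest-neighbor information estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdsynapse import (
    BinnedDistribution,
    KnnEstimatorConfig,
    entropy_bits,
    freedman_diaconis_nbins,
    joint_entropy_bits,
    kl_knn_entropy,
    ksg_mi,
    mi_ntuple_history,
    mi_psr_vs_preceding_isi,
    mi_vs_sum_history,
    mutual_information_hist,
    preset,
)
from fdsynapse.experiments import pr_samples_at
from fdsynapse.information import LN2
from fdsynapse.response import ResponseModel, generate_psr_series


class TestFreedmanDiaconis:
    def test_twenty_bins_for_reference_statistics(self):
        # range 1, Iqr 0.25, n = 1000: 1 / (2 * 0.25 * 1000^(-1/3)) = 20
        # a sample engineered to have exactly those statistics
        n = 1000
        x = np.concatenate(
            [
                np.full(250, 0.375),
                np.full(250, 0.5),
                np.full(250, 0.625),
                np.full(248, 0.5),
                [0.0, 1.0],
            ]
        )
        assert len(x) == n
        assert np.percentile(x, 75) - np.percentile(x, 25) == pytest.approx(0.25)
        assert freedman_diaconis_nbins(x) == 20

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 1e3),
        seed=st.integers(0, 100),
    )
    def test_translation_and_scale_invariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).normal(size=500)
        base = freedman_diaconis_nbins(x)
        assert freedman_diaconis_nbins(x + shift) == base
        assert freedman_diaconis_nbins(scale * x) == base

    def test_zero_iqr_falls_back_with_warning(self):
        x = np.concatenate([np.zeros(100), [1.0]])
        with pytest.warns(UserWarning):
            nbins = freedman_diaconis_nbins(x)
        assert nbins == int(np.ceil(np.sqrt(101)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            freedman_diaconis_nbins([1.0, 2.0])


class TestEntropy:
    def test_uniform_sixteen_bins(self):
        dist = BinnedDistribution(np.arange(17.0), np.full(16, 1 / 16), n=16)
        assert entropy_bits(dist) == pytest.approx(4.0)

    def test_point_mass(self):
        dist = BinnedDistribution(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0]), n=10)
        assert entropy_bits(dist) == 0.0

    def test_fair_coin(self):
        dist = BinnedDistribution(np.array([0.0, 1.0, 2.0]), np.array([0.5, 0.5]), n=10)
        assert entropy_bits(dist) == pytest.approx(1.0)

    def test_bounded_by_log_occupied_bins(self, rng):
        x = rng.normal(size=5000)
        dist = BinnedDistribution.from_samples(x, bins=64)
        occupied = np.count_nonzero(dist.probs)
        assert 0.0 <= entropy_bits(dist) <= np.log2(occupied)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            BinnedDistribution(np.array([0.0, 1.0]), np.array([0.7]), n=1)
        with pytest.raises(ValueError):
            BinnedDistribution(np.array([1.0, 0.0, 2.0]), np.array([0.5, 0.5]), n=2)


class TestJointEntropyAndMI:
    def test_joint_entropy_bounds(self, rng):
        x = rng.uniform(size=4096)
        y = rng.uniform(size=4096)
        edges = np.linspace(0, 1, 17)
        hx = entropy_bits(BinnedDistribution.from_samples(x, edges))
        hy = entropy_bits(BinnedDistribution.from_samples(y, edges))
        hxy = joint_entropy_bits(x, y, binning=(edges, edges))
        assert max(hx, hy) <= hxy + 1e-9
        assert hxy <= hx + hy + 1e-9

    def test_identical_variables_share_entropy(self, rng):
        x = rng.uniform(size=4096)
        edges = np.linspace(0, 1, 17)
        hx = entropy_bits(BinnedDistribution.from_samples(x, edges))
        assert joint_entropy_bits(x, x, binning=(edges, edges)) == pytest.approx(hx)
        assert mutual_information_hist(x, x, binning=(edges, edges)) == pytest.approx(hx)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy_bits(np.arange(10.0), np.arange(9.0))

    def test_four_by_four_enumeration_oracle(self):
        # explicit joint counts on a 4 x 4 table
        counts = np.array(
            [
                [10, 2, 1, 0],
                [2, 8, 3, 1],
                [0, 3, 9, 2],
                [1, 0, 2, 12],
            ],
            dtype=float,
        )
        xs, ys = [], []
        for i in range(4):
            for j in range(4):
                xs += [i + 0.5] * int(counts[i, j])
                ys += [j + 0.5] * int(counts[i, j])
        edges = np.arange(5.0)

        # brute-force oracle: direct double sum over the printed table
        p = counts / counts.sum()
        px, py = p.sum(axis=1), p.sum(axis=0)
        oracle_mi = sum(
            p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
            for i in range(4)
            for j in range(4)
            if p[i, j] > 0
        )
        oracle_joint = -sum(
            p[i, j] * np.log2(p[i, j]) for i in range(4) for j in range(4) if p[i, j] > 0
        )
        assert mutual_information_hist(xs, ys, binning=(edges, edges)) == pytest.approx(
            oracle_mi, abs=1e-12
        )
        assert joint_entropy_bits(xs, ys, binning=(edges, edges)) == pytest.approx(
            oracle_joint, abs=1e-12
        )

    def test_symmetry_exact(self, rng):
        x = rng.normal(size=2000)
        y = 0.5 * x + rng.normal(size=2000)
        assert abs(
            mutual_information_hist(x, y, binning=16) - mutual_information_hist(y, x, binning=16)
        ) < 1e-12

    def test_nonnegative_and_near_zero_for_independent(self, rng):
        x = rng.normal(size=2**13)
        y = rng.normal(size=2**13)
        mi = mutual_information_hist(x, y)
        assert mi >= 0.0
        assert mi < 0.2  # finite-sample bias only


class TestKnnEstimators:
    def test_uniform_entropy_near_zero(self, rng):
        assert abs(kl_knn_entropy(rng.uniform(size=10**4))) < 0.02

    def test_gaussian_entropy_closed_form(self, rng):
        h = kl_knn_entropy(rng.normal(size=10**4))
        assert h == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.02)

    def test_two_dimensional_uniform_additivity(self, rng):
        pts = rng.uniform(size=(10**4, 2))
        assert abs(kl_knn_entropy(pts)) < 0.05

    def test_duplicates_without_jitter_raise(self):
        pts = np.zeros(50)
        with pytest.raises(FloatingPointError):
            kl_knn_entropy(pts, KnnEstimatorConfig(k=3, jitter=0.0))

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    @pytest.mark.parametrize("k", [3, 4, 6])
    def test_ksg_gaussian_oracle(self, rho, k):
        rng = np.random.default_rng(17)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 10**4)
        mi = ksg_mi(xy[:, 0], xy[:, 1], k=k)
        assert mi == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.02)

    def test_ksg_independent_near_zero(self):
        rng = np.random.default_rng(23)
        mi = ksg_mi(rng.normal(size=10**4), rng.normal(size=10**4), k=4)
        assert abs(mi) < 0.01

    def test_ksg_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(29)
        xy = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 2**13)
        base = ksg_mi(xy[:, 0], xy[:, 1], k=4)
        warped = ksg_mi(np.exp(xy[:, 0]), xy[:, 1] ** 3, k=4)
        assert warped == pytest.approx(base, abs=0.05)

    def test_ksg_agrees_with_sklearn_reference(self):
        # independent route to the same estimator family
        from sklearn.feature_selection import mutual_info_regression

        rng = np.random.default_rng(37)
        xy = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 2**13)
        ours = ksg_mi(xy[:, 0], xy[:, 1], k=4)
        ref = mutual_info_regression(
            xy[:, [0]], xy[:, 1], n_neighbors=4, random_state=0
        )[0]
        assert ours == pytest.approx(ref, abs=0.03)

    def test_ksg_nonnegative_at_scale(self):
        rng = np.random.default_rng(31)
        mi = ksg_mi(rng.uniform(size=2**14), rng.uniform(size=2**14), k=4)
        assert mi > -0.01


class TestSeriesMeasures:
    @pytest.fixture(scope="class")
    def psr_5hz(self):
        series = pr_samples_at(preset("control"), 5.0, 2**13, seed=41)
        return series, generate_psr_series(series, ResponseModel(), seed=42)

    def test_sum_history_depth_one_reduces_to_pairwise(self, psr_5hz):
        _, psr = psr_5hz
        by_depth = mi_vs_sum_history(psr, max_depth=1)
        assert by_depth[0] == pytest.approx(mi_psr_vs_preceding_isi(psr), abs=1e-12)

    def test_sum_history_requires_long_series(self, psr_5hz):
        _, psr = psr_5hz
        with pytest.raises(ValueError):
            mi_vs_sum_history(psr, max_depth=len(psr) - 10)

    def test_misalignment_rejected(self, psr_5hz):
        _, psr = psr_5hz
        with pytest.raises(ValueError):
            mi_psr_vs_preceding_isi(psr, isis=psr.isi_ms[:-1])

    def test_constant_response_carries_no_information(self, control):
        series = pr_samples_at(control, 5.0, 2**12, seed=43)
        flat = generate_psr_series(series, ResponseModel(), seed=44)
        flat.amplitude = np.full(len(flat), 1.0)
        flat.amplitude[0] = 1.0 + 1e-9  # keep the Iqr fallback path out
        assert mi_psr_vs_preceding_isi(flat, binning=8) < 0.05

    def test_ntuple_depth_one_agrees_with_histogram(self, control):
        series = pr_samples_at(control, 5.0, 2**13, seed=45)
        knn_nats = mi_ntuple_history(series, depth=1, k=4)
        hist_nats = mutual_information_hist(series.isi_ms, series.pr) * LN2
        assert knn_nats == pytest.approx(hist_nats, rel=0.20)

    def test_ntuple_depth_guard(self, control):
        series = pr_samples_at(control, 5.0, 2**12, seed=46)
        with pytest.raises(ValueError):
            mi_ntuple_history(series, depth=9)

    def test_excluding_failures_changes_the_estimate(self, psr_5hz):
        _, psr = psr_5hz
        with_failures = mi_psr_vs_preceding_isi(psr, include_failures=True)
        without = mi_psr_vs_preceding_isi(psr, include_failures=False)
        assert with_failures != without


def test_pr_entropy_has_interior_theta_maximum(control):
    """Fixed-partition Pr entropy peaks at an interior rate in (1, 10) Hz."""
    from fdsynapse.information import fixed_partition_entropy

    rates = np.array([1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 10.0])
    seeds = np.random.SeedSequence(47).spawn(len(rates))
    H = [
        fixed_partition_entropy(pr_samples_at(control, f, 2**13, s).pr)
        for f, s in zip(rates, seeds)
    ]
    i = int(np.argmax(H))
    assert 0 < i < len(rates) - 1
    assert 1.0 < rates[i] < 10.0
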