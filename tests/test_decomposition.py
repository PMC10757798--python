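import numpy as np
import pytest
import scipy.stats
from scipy.optimize import linear_sum_assignment

from dualica.data import LFCMatrix, preprocess
from dualica.decomposition import (
    ComponentScree,
    choose_components,
    dagostino_k2,
    dual_decompose,
    k2_scree,
    kneedle,
    run_ica,
)
from dualica.exceptions import (
    DegenerateSampleError,
    SampleTooSmallError,
    TooFewPointsError,
)


def reference_kneedle(x, y, sensitivity=1.0):
    """Independent plain-Python kneedle: normalize, build the difference
    curve, walk local maxima against the sensitivity threshold."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    xn = [(v - x[0]) / (x[-1] - x[0]) for v in x]
    lo, hi = min(y), max(y)
    if hi == lo:
        return None
    yn = [(v - lo) / (hi - lo) for v in y]
    d = [yn[i] - xn[i] for i in range(n)]
    maxima = [
        i for i in range(1, n - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    step = sum(xn[i + 1] - xn[i] for i in range(n - 1)) / (n - 1)
    for pos, i in enumerate(maxima):
        threshold = d[i] - sensitivity * step
        end = maxima[pos + 1] if pos + 1 < len(maxima) else n
        if any(d[j] < threshold for j in range(i + 1, end)):
            return x[i]
    return None


class TestRunICA:
    def test_recovers_mixed_laplace_sources(self):
        rng = np.random.default_rng(3)
        S_true = rng.laplace(size=(2000, 3))
        A = rng.normal(size=(3, 3))
        d = run_ica(S_true @ A, 3, seed=0)
        corr = np.abs(np.corrcoef(S_true.T, d.signal.T)[:3, 3:])
        ri, cj = linear_sum_assignment(-corr)
        assert (corr[ri, cj] > 0.95).all()

    def test_signal_columns_zero_mean_unit_variance(self, rng):
        X = rng.laplace(size=(300, 12))
        d = run_ica(X, 5, seed=1)
        np.testing.assert_allclose(d.signal.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(d.signal.var(axis=0), 1, atol=1e-6)

    def test_full_rank_reconstruction(self, rng):
        X = rng.laplace(size=(80, 10))
        d = run_ica(X, 10, seed=2)
        rel = np.linalg.norm(d.reconstruct() - X) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_deterministic_per_seed(self, rng):
        X = rng.laplace(size=(100, 8))
        a = run_ica(X, 4, seed=9)
        b = run_ica(X, 4, seed=9)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.mixing, b.mixing)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            run_ica(rng.normal(size=(10, 5)), 6, seed=0)

    def test_skewed_one_sided_sources_separated(self):
        # one-tailed indicator sources are invisible to even contrasts;
        # the auto contrast must still unmix them
        rng = np.random.default_rng(11)
        n = 80
        S_true = np.zeros((n, 3))
        for j in range(3):
            S_true[rng.choice(n, 12, replace=False), j] = 3.0
        X = S_true @ rng.normal(size=(3, 400)) + rng.normal(size=(n, 400)) * 0.5
        d = run_ica(X, 3, seed=0)
        corr = np.abs(np.corrcoef(S_true.T, d.signal.T)[:3, 3:])
        ri, cj = linear_sum_assignment(-corr)
        assert (corr[ri, cj] > 0.9).all()


class TestDagostinoK2:
    def test_matches_z_skew_z_kurt_composition(self, rng):
        x = rng.laplace(size=(400,))
        k2, p = dagostino_k2(x)
        zs = scipy.stats.skewtest(x).statistic
        zk = scipy.stats.kurtosistest(x).statistic
        np.testing.assert_allclose(k2, zs**2 + zk**2, rtol=1e-12)
        np.testing.assert_allclose(p, scipy.stats.chi2.sf(k2, 2), rtol=1e-12)

    def test_normal_samples_rarely_rejected(self):
        # type-I error calibration at alpha=0.001
        low_p = 0
        for seed in range(200):
            x = np.random.default_rng(seed).normal(size=5000)
            _, p = dagostino_k2(x)
            low_p += p <= 0.001
        assert low_p <= 2  # >= 99% of seeds have p > 0.001

    def test_laplace_heavy_tails_detected(self):
        x = np.random.default_rng(0).laplace(size=5000)
        _, p = dagostino_k2(x)
        assert p < 1e-6

    def test_short_sample_rejected(self):
        with pytest.raises(SampleTooSmallError):
            dagostino_k2(np.arange(5.0))

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            dagostino_k2(np.full(50, 2.0))


class TestScree:
    def test_planted_signals_rise_then_flatten(self):
        rng = np.random.default_rng(5)
        n = 600
        S_true = np.zeros((n, 3))
        for j in range(3):
            S_true[rng.choice(n, 40, replace=False), j] = 4.0
        X = S_true @ rng.normal(size=(3, 50)) + rng.normal(size=(n, 50))
        scree = k2_scree(X, [1, 2, 3, 4, 5, 6], seed=0)
        m = scree.excess_metric
        assert m[2] - m[0] > 5 * abs(m[5] - m[2])

    def test_pure_noise_metric_small_versus_planted(self, rng):
        # on pure noise the raw metric stays far below a planted-signal
        # scree of the same shape, and the null-corrected excess is small
        noise = rng.normal(size=(800, 40))
        s_noise = k2_scree(noise, [2, 4, 6], seed=0)
        signal = noise.copy()
        S = np.zeros((800, 3))
        for j in range(3):
            S[rng.choice(800, 40, replace=False), j] = 4.0
        signal += S @ rng.normal(size=(3, 40))
        s_signal = k2_scree(signal, [2, 4, 6], seed=0, null_correction=False)
        assert (s_noise.metric >= 0).all()
        assert (s_signal.metric > 5 * s_noise.metric).all()
        assert np.abs(s_noise.excess_metric).max() < 0.2 * s_signal.metric.max()

    def test_metric_invariant_to_permutation(self, rng):
        # with well-separated sources the optimum is unique, so the
        # per-component K^2 values are permutation invariant
        n = 300
        S = np.zeros((n, 3))
        for j in range(3):
            S[rng.choice(n, 30, replace=False), j] = 5.0
        X = S @ rng.normal(size=(3, 40)) + rng.normal(size=(n, 40))
        perm_r = rng.permutation(n)
        perm_c = rng.permutation(40)
        a = k2_scree(X, [2, 3, 4], seed=0, null_correction=False)
        b = k2_scree(
            X[np.ix_(perm_r, perm_c)], [2, 3, 4], seed=0, null_correction=False
        )
        np.testing.assert_allclose(
            np.sort(np.concatenate(a.per_component_k2)),
            np.sort(np.concatenate(b.per_component_k2)),
            rtol=0.05,
        )

    def test_descending_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="ascending"):
            k2_scree(rng.normal(size=(50, 10)), [4, 2], seed=0)

    def test_grid_beyond_min_dim_rejected(self, rng):
        with pytest.raises(ValueError, match="min matrix dimension"):
            k2_scree(rng.normal(size=(50, 10)), [2, 12], seed=0)


class TestKneedle:
    def test_piecewise_linear_breakpoint_found_exactly(self):
        x = np.arange(1.0, 11.0)
        y = np.minimum(x, 5.0)
        assert kneedle(x, y) == 5.0

    def test_straight_line_has_no_knee(self):
        x = np.arange(1.0, 11.0)
        assert kneedle(x, 2 * x) is None

    def test_constant_curve_has_no_knee(self):
        x = np.arange(1.0, 8.0)
        assert kneedle(x, np.full_like(x, 3.0)) is None

    @pytest.mark.parametrize(
        "curve",
        [
            lambda x: 1 - np.exp(-x),
            lambda x: np.sqrt(x),
            lambda x: np.log1p(x),
            lambda x: x / (1 + x),
            lambda x: np.minimum(x, 3.0),
            lambda x: np.minimum(2 * x, x + 4),
        ],
    )
    @pytest.mark.parametrize("sensitivity", [1.0, 2.0])
    def test_agrees_with_reference_implementation(self, curve, sensitivity):
        x = np.arange(0.0, 10.5, 0.5)
        y = curve(x)
        assert kneedle(x, y, sensitivity) == reference_kneedle(
            x, y, sensitivity
        )

    def test_agrees_with_reference_on_noisy_concave_curves(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.arange(2.0, 42.0, 2.0)
            y = 10 * (1 - np.exp(-x / 8)) + rng.normal(0, 0.05, x.size)
            assert kneedle(x, y) == reference_kneedle(x, y)

    def test_too_few_points_rejected(self):
        with pytest.raises(TooFewPointsError):
            kneedle([1, 2], [1, 2])


class TestChooseComponents:
    def test_planted_scree_selects_true_count(self):
        rng = np.random.default_rng(8)
        n = 600
        S_true = np.zeros((n, 3))
        for j in range(3):
            S_true[rng.choice(n, 40, replace=False), j] = 4.0
        X = S_true @ rng.normal(size=(3, 50)) + rng.normal(size=(n, 50))
        scree = k2_scree(X, [1, 2, 3, 4, 5, 6, 7], seed=0)
        r, fallback = choose_components(scree)
        assert not fallback
        assert abs(r - 3) <= 1

    def test_linear_scree_triggers_fallback_with_warning(self):
        scree = ComponentScree(
            r_grid=[2, 4, 6, 8],
            metric=np.array([1.0, 2.0, 3.0, 3.5]),
            per_component_k2=[np.zeros(r) for r in (2, 4, 6, 8)],
            seed=0,
        )
        with pytest.warns(UserWarning, match="no knee"):
            r, fallback = choose_components(scree)
        assert fallback
        assert r == 6  # largest drop in incremental gain is after 6

    def test_two_point_scree_rejected(self):
        scree = ComponentScree(
            r_grid=[2, 4],
            metric=np.array([1.0, 2.0]),
            per_component_k2=[np.zeros(2), np.zeros(4)],
            seed=0,
        )
        with pytest.raises(TooFewPointsError):
            choose_components(scree)


class TestDualDecompose:
    @pytest.fixture(scope="class")
    def decomps(self):
        rng = np.random.default_rng(21)
        M = LFCMatrix(
            rng.laplace(size=(120, 30)),
            [f"g{i}" for i in range(120)],
            [f"c{j}" for j in range(30)],
        )
        Mp = preprocess(M)
        return Mp, dual_decompose(Mp, k=5, l=4, seed=0)

    def test_shapes(self, decomps):
        Mp, (cond, gene) = decomps
        assert cond.signal.shape == (120, 5)
        assert cond.mixing.shape == (5, 30)
        assert gene.signal.shape == (30, 4)
        assert gene.mixing.shape == (4, 120)

    def test_labels_attached(self, decomps):
        Mp, (cond, gene) = decomps
        assert cond.row_ids == Mp.gene_ids
        assert gene.row_ids == Mp.condition_ids

    def test_deterministic(self, decomps):
        Mp, (cond, gene) = decomps
        cond2, gene2 = dual_decompose(Mp, k=5, l=4, seed=0)
        assert np.array_equal(cond.signal, cond2.signal)
        assert np.array_equal(gene.signal, gene2.signal)

    def test_requires_preprocessed_matrix(self, rng):
        M = LFCMatrix(
            rng.normal(size=(40, 10)),
            [f"g{i}" for i in range(40)],
            [f"c{j}" for j in range(10)],
        )
        with pytest.raises(ValueError, match="preprocess"):
            dual_decompose(M, 2, 2, seed=0)
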