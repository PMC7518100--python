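import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrdenoise.shrinkage import (
    ShrinkageParams,
    denoise_group,
    estimate_truncation,
    log_prox,
    shrink_spectrum,
    soft_threshold_spectrum,
)
from mrdenoise.tensor_core import reconstruct


def grid_prox_oracle(y, lam, a, step=1e-5):
    """Brute-force minimization of 0.5*(y-x)^2 + lam*(1/a)*log(1+a*x)
    over a dense grid x in [0, y]."""
    x = np.arange(0.0, y + step, step)
    obj = 0.5 * (y - x) ** 2 + lam / a * np.log1p(a * x)
    return x[np.argmin(obj)]


class TestLogProx:
    def test_below_threshold(self):
        assert log_prox(0.5, 1.0, 0.5) == 0.0

    @pytest.mark.parametrize("lam,a", [(1.0, 0.5), (2.0, 0.3), (0.5, 1.5)])
    def test_continuous_at_threshold(self, lam, a):
        assert log_prox(lam, lam, a) == pytest.approx(0.0, abs=1e-12)
        eps = 1e-9
        assert abs(log_prox(lam + eps, lam, a)) < 1e-3

    def test_against_grid_oracle(self):
        assert log_prox(2.0, 1.0, 0.4) == pytest.approx(
            grid_prox_oracle(2.0, 1.0, 0.4), abs=1e-4
        )
        # frozen from the grid oracle (and the closed form)
        assert log_prox(2.0, 1.0, 0.4) == pytest.approx(1.3507810594, abs=1e-6)

    def test_soft_threshold_limit(self):
        assert log_prox(3.0, 1.0, 1e-8) == pytest.approx(2.0, abs=1e-6)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            log_prox(1.0, 1.0, 1.0)  # a == 1/lam
        with pytest.raises(ValueError):
            log_prox(1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            log_prox(1.0, 0.0, 0.1)

    @settings(max_examples=100, deadline=None)
    @given(
        y=st.floats(-8, 8),
        lam=st.floats(0.1, 3),
        frac=st.floats(0.01, 0.99),
    )
    def test_sandwich_monotone_odd(self, y, lam, frac):
        a = frac / lam
        v = log_prox(y, lam, a)
        assert max(abs(y) - lam, 0.0) - 1e-12 <= abs(v) <= abs(y) + 1e-12
        assert log_prox(-y, lam, a) == pytest.approx(-v, abs=1e-12)
        if y >= 0:
            assert log_prox(y + 0.1, lam, a) >= v - 1e-12

    def test_vectorized(self):
        y = np.array([-3.0, -0.5, 0.0, 0.5, 3.0])
        out = log_prox(y, 1.0, 0.4)
        assert out.shape == y.shape
        assert out[2] == 0.0 and out[0] == -out[4]


class TestSoftThreshold:
    def test_basic(self):
        np.testing.assert_allclose(
            soft_threshold_spectrum([3.0, 1.0, 0.2], 1.0), [2.0, 0.0, 0.0]
        )

    def test_lam_zero_identity(self, rng):
        d = np.abs(rng.normal(size=10))
        np.testing.assert_array_equal(soft_threshold_spectrum(d, 0.0), d)

    def test_matches_log_prox_limit(self, rng):
        d = np.sort(np.abs(rng.normal(size=20)) * 3)[::-1]
        soft = soft_threshold_spectrum(d, 1.0)
        logp = log_prox(d, 1.0, 1e-10)
        np.testing.assert_allclose(logp, soft, atol=1e-6)


class TestShrinkSpectrum:
    def params(self, lam=1.0):
        return ShrinkageParams(lam=lam, a=0.5 / lam, tau=1.0)

    def test_all_zero_floors_to_one(self):
        shrunk, rank = shrink_spectrum(np.zeros(3), self.params())
        assert rank == 1
        np.testing.assert_array_equal(shrunk, np.zeros(3))

    def test_threshold_branch(self):
        _, rank = shrink_spectrum(
            np.array([10.0, 0.5, 0.1]), ShrinkageParams(1.0, 0.4, 1.0)
        )
        assert rank == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            shrink_spectrum(np.array([1.0, 2.0]), self.params())

    def test_rank_matches_elementwise_oracle(self, rng):
        params = ShrinkageParams(1.0, 0.3, 1.0)
        for _ in range(200):
            d = np.sort(np.abs(rng.normal(size=8)) * 3)[::-1]
            _, rank = shrink_spectrum(d, params)
            oracle = sum(1 for v in d if log_prox(float(v), 1.0, 0.3) > 0)
            assert rank == max(oracle, 1)

    def test_output_nonincreasing(self, rng):
        d = np.sort(np.abs(rng.normal(size=12)) * 5)[::-1]
        shrunk, _ = shrink_spectrum(d, self.params())
        assert np.all(np.diff(shrunk) <= 1e-12)


class TestEstimateTruncation:
    def test_noiseless_rank_identification(self, low_rank_tensor_factory):
        t = low_rank_tensor_factory(shape=(4, 4, 4, 8), ranks=(2, 2, 2, 1), scale=10.0)
        params = ShrinkageParams(lam=1e-4, a=0.5 / 1e-4, tau=1.0)
        f = estimate_truncation(t, params)
        assert f.ranks == (2, 2, 2, 1)

    def test_all_floored_to_one(self, rng):
        t = rng.normal(size=(3, 3, 3, 4)) * 0.01
        lam = 1e6
        f = estimate_truncation(t, ShrinkageParams(lam, 0.5 / lam, 1.0))
        assert f.ranks == (1, 1, 1, 1)

    def test_orthonormal_truncated_factors(self, rng):
        t = rng.normal(size=(4, 4, 4, 8))
        f = estimate_truncation(t, ShrinkageParams(2.0, 0.25, 1.0))
        for u, r in zip(f.factors, f.ranks):
            assert u.shape[1] == r
            np.testing.assert_allclose(u.T @ u, np.eye(r), atol=1e-10)

    def test_spectra_untruncated(self, rng):
        t = rng.normal(size=(4, 4, 4, 8))
        f = estimate_truncation(t, ShrinkageParams(5.0, 0.1, 1.0))
        assert [len(s) for s in f.spectra] == [4, 4, 4, 8]

    def test_rank_recovery_under_noise(self, low_rank_tensor_factory):
        # reduced-size Monte-Carlo check with a threshold above the noise
        # singular-value edge of the similarity mode: genuine truncation
        p, m, sigma = 4, 16, 0.1
        lam = sigma * 2 * np.log(p**3 * m)
        params = ShrinkageParams(lam, 0.5 / lam, 2 * np.log(p**3 * m))
        mode4 = []
        for seed in range(30):
            t = low_rank_tensor_factory(
                shape=(p, p, p, m), ranks=(2, 2, 2, 2), scale=1.0, seed=seed
            )
            noisy = t + np.random.default_rng(1000 + seed).normal(
                0, sigma, size=t.shape
            )
            mode4.append(estimate_truncation(noisy, params).ranks[3])
        mode4 = np.asarray(mode4)
        assert np.median(mode4) == 2  # noise-only directions discarded
        assert np.mean(mode4 >= 2) >= 0.85


class TestDenoiseGroup:
    def test_full_rank_projection_is_identity(self, rng):
        t = rng.normal(size=(3, 3, 3, 4))
        lam = 1e-8  # below every singular value: no truncation anywhere
        out = denoise_group(t, ShrinkageParams(lam, 0.5 / lam, 1.0))
        np.testing.assert_allclose(out, t, rtol=0, atol=1e-10 * np.linalg.norm(t))

    def test_pythagoras(self, rng):
        t = rng.normal(size=(4, 4, 4, 8))
        params = ShrinkageParams(3.0, 0.1, 1.0)
        xhat = denoise_group(t, params)
        lhs = np.linalg.norm(t) ** 2
        rhs = np.linalg.norm(xhat) ** 2 + np.linalg.norm(t - xhat) ** 2
        assert abs(lhs - rhs) <= 1e-8 * lhs

    def test_noiseless_low_rank_exact(self, low_rank_tensor_factory):
        t = low_rank_tensor_factory(shape=(4, 4, 4, 8), ranks=(2, 2, 2, 2), scale=5.0)
        lam = 1e-3
        out = denoise_group(t, ShrinkageParams(lam, 0.5 / lam, 1.0))
        np.testing.assert_allclose(out, t, atol=1e-8)

    def test_core_contractive(self, rng):
        t = rng.normal(size=(4, 4, 4, 8))
        f = estimate_truncation(t, ShrinkageParams(2.0, 0.2, 1.0))
        assert np.linalg.norm(f.core) <= np.linalg.norm(t) + 1e-12
        assert np.linalg.norm(reconstruct(f)) <= np.linalg.norm(t) + 1e-12
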