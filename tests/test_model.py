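"""Shustring-length distribution and the two diversity estimators."""

import math

import numpy as np
import pytest
from scipy.special import comb

from shudiv import (
    ShustringModel,
    background_cdf,
    estimate_pi_d,
    estimate_pi_m,
    histogram,
    homologous_tail,
    load_pool,
    log_likelihood,
    shustring_cdf,
    shustring_lengths,
    shustring_pmf,
)
from shudiv.model import _log_background_general, log_background_cdf

from conftest import profile_strings


def naive_background_sum(p, ell_s, x):
    """Direct high-precision evaluation of the background match-length CDF."""
    if x <= 0:
        return 0.0
    q = 0.5 - p
    total = 0.0
    for k in range(x + 1):
        word = p**k * q ** (x - k)
        total += comb(x, k, exact=True) * 2**x * word * (1.0 - word) ** (2 * ell_s)
    return total


class TestHomologousTail:
    def test_half_at_reciprocal_length(self):
        # pi*x = 1 makes the survival probability exactly 1/2
        assert homologous_tail(0.01, 100) == pytest.approx(0.5)

    def test_certain_at_zero(self):
        assert homologous_tail(0.37, 0) == 1.0

    def test_heavy_tail_decay(self):
        xs = np.array([1e3, 1e5, 1e7])
        vals = homologous_tail(0.01, xs)
        assert (np.diff(vals) < 0).all()
        # survival ~ 1/(pi x): polynomial, not exponential, decay
        assert vals[-1] == pytest.approx(1.0 / (1 + 0.01 * 1e7))


class TestBackgroundCdf:
    @pytest.mark.parametrize("ell_s", [1e3, 1e5, 1e7])
    def test_general_form_reduces_to_equiprobable_closed_form(self, ell_s):
        xs = np.arange(1, 65)
        general = np.exp(_log_background_general(0.25, ell_s, xs))
        # closed form evaluated via log1p: 1 - 4**-x itself rounds to 1.0
        # in double precision beyond x ~ 27
        closed = np.exp(2 * ell_s * np.log1p(-(4.0 ** -xs.astype(float))))
        np.testing.assert_allclose(general, closed, atol=1e-12, rtol=0)

    def test_single_comparison_position(self):
        # one background position (2*ell_S = 1): (1 - 1/4)^1
        assert background_cdf(0.25, 0.5, 1) == pytest.approx(0.75)

    def test_skewed_composition_matches_naive_sum(self):
        got = background_cdf(0.2, 500, 10)
        assert got == pytest.approx(naive_background_sum(0.2, 500, 10), rel=1e-10)

    def test_zero_and_saturation(self):
        assert background_cdf(0.2, 1e5, 0) == 0.0
        assert background_cdf(0.2, 1e5, 500) == pytest.approx(1.0)

    def test_nondecreasing(self):
        for p in (0.25, 0.18):
            vals = background_cdf(p, 1e4, np.arange(0, 80))
            # tolerate 1-ulp wiggle where the CDF saturates at 1
            assert (np.diff(vals) >= -1e-12).all()

    def test_log_form_finite_deep_in_underflow(self):
        lw = log_background_cdf(0.25, 1e5, np.array([1.0]))
        assert lw[0] == pytest.approx(2e5 * math.log(0.75))
        assert background_cdf(0.25, 1e5, 1) == 0.0  # linear space underflows


class TestShustringDistribution:
    model = ShustringModel(pi=0.01, p=0.25, ell_S=5e4, ell_Q=5e4)

    def test_cdf_limits(self):
        assert shustring_cdf(self.model, 0) == 0.0
        assert shustring_cdf(self.model, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_cdf_nondecreasing(self):
        vals = shustring_cdf(self.model, np.arange(0, 5000, dtype=float))
        assert (np.diff(vals) >= 0).all()

    def test_mode_near_background_concentration(self):
        # background matches concentrate near log4(2*ell_S) ~ 8.3: the pmf
        # rises steeply there; the heavy homologous tail then drags the
        # median far above the mode
        xs = np.arange(1, 2000, dtype=float)
        pmf = np.asarray(shustring_pmf(self.model, xs))
        mode = xs[int(np.argmax(pmf))]
        assert 7 <= mode <= 12
        cdf = shustring_cdf(self.model, xs)
        median = xs[int(np.searchsorted(cdf, 0.5))]
        assert median > mode

    def test_pmf_telescopes_to_cdf(self):
        X = 2000
        total = np.sum(shustring_pmf(self.model, np.arange(1, X + 1, dtype=float)))
        assert total == pytest.approx(shustring_cdf(self.model, X), abs=1e-12)

    def test_pmf_nonnegative(self):
        pmf = shustring_pmf(self.model, np.arange(1, 3000, dtype=float))
        assert (pmf >= 0).all()

    def test_normalization_out_to_heavy_tail_cutoff(self):
        # survival ~ 1/(pi*x), so 99.9% of mass needs x ~ 1000/pi
        m = self.model
        X = int(1000 / m.pi)
        total = np.sum(shustring_pmf(m, np.arange(1, X + 1, dtype=float)))
        assert total >= 0.999

    def test_pmf_base_case(self):
        # at x=1 the telescoping leaves only w(1) * pi/(1+pi)
        m = ShustringModel(pi=0.3, p=0.25, ell_S=2, ell_Q=10)
        expected = background_cdf(0.25, 2, 1) * 0.3 / 1.3
        assert shustring_pmf(m, 1) == pytest.approx(expected, rel=1e-12)


class _FakeHist:
    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=np.int64)
        self.total = int(self.counts.sum())
        self.xi = int(np.nonzero(self.counts)[0].max())


class TestLogLikelihood:
    def test_single_length_class(self):
        m = ShustringModel(pi=0.02, p=0.25, ell_S=1e3, ell_Q=1e3)
        counts = np.zeros(20, dtype=int)
        counts[12] = 7
        ll = log_likelihood(m, _FakeHist(counts))
        assert ll == pytest.approx(7 * math.log(shustring_pmf(m, 12)))

    def test_linear_in_counts(self):
        m = ShustringModel(pi=0.02, p=0.25, ell_S=1e3, ell_Q=1e3)
        rng = np.random.default_rng(0)
        counts = np.zeros(40, dtype=int)
        counts[5:30] = rng.integers(0, 50, 25)
        h1, h2 = _FakeHist(counts), _FakeHist(2 * counts)
        assert log_likelihood(m, h2) == pytest.approx(2 * log_likelihood(m, h1))

    def test_grid_maximum_near_truth_for_model_draws(self):
        truth = ShustringModel(pi=0.01, p=0.25, ell_S=1e5, ell_Q=1e5)
        rng = np.random.default_rng(123)
        xs = np.arange(0, 20_000, dtype=float)
        mean_counts = 2.0 * truth.ell_Q * np.asarray(shustring_pmf(truth, xs))
        hist = _FakeHist(rng.poisson(mean_counts))
        grid = np.array([0.004, 0.007, 0.009, 0.01, 0.011, 0.014, 0.02])
        lls = [
            log_likelihood(
                ShustringModel(pi=g, p=0.25, ell_S=1e5, ell_Q=1e5), hist
            )
            for g in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert 0.009 <= best <= 0.011


class TestEstimators:
    def test_pi_d_recovers_truth_from_poisson_counts(self):
        truth = ShustringModel(pi=0.01, p=0.25, ell_S=1e5, ell_Q=1e5)
        rng = np.random.default_rng(2024)
        xs = np.arange(0, 20_000, dtype=float)
        mean_counts = 2.0 * truth.ell_Q * np.asarray(shustring_pmf(truth, xs))
        hist = _FakeHist(rng.poisson(mean_counts))
        est = estimate_pi_d(hist, p=0.25, ell_S=1e5, ell_Q=1e5)
        assert est.converged
        assert est.pi_hat == pytest.approx(0.01, abs=0.001)

    def test_min_total_enforced(self):
        counts = np.zeros(10, dtype=int)
        counts[5] = 50
        with pytest.raises(ValueError):
            estimate_pi_d(_FakeHist(counts), p=0.25, ell_S=1e3, ell_Q=1e3)

    def test_identical_sequences_not_converged(self):
        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), 2000))
        pool_q = load_pool([seq])
        pool_s = load_pool([seq])
        prof = shustring_lengths(pool_q, pool_s)
        hist = histogram(prof)
        est = estimate_pi_d(hist, p=0.25, ell_S=2000, ell_Q=2000)
        assert not est.converged
        assert est.message

    def test_pi_m_inverse_mean(self):
        assert estimate_pi_m(np.full(50, 100)) == pytest.approx(0.01)

    def test_pi_m_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_pi_m(np.array([]))


class TestModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pi": 0.0, "p": 0.25, "ell_S": 10, "ell_Q": 10},
            {"pi": 0.01, "p": 0.5, "ell_S": 10, "ell_Q": 10},
            {"pi": 0.01, "p": 0.25, "ell_S": 0, "ell_Q": 10},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ShustringModel(**kwargs)
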