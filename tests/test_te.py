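"""KSG transfer-entropy core: embedding, estimator, parameter search,
surrogate significance."""

import itertools
import math

import numpy as np
import pytest

from drowsyte import (EmbeddingSpec, cao_dimension, delay_embed,
                      gen_coupled_pair, granger, ksg_te, ksg_te_epochs,
                      ms_to_samples, select_delay, select_u, surrogate_test)
from drowsyte.te import cao_statistics


class TestDelayEmbed:
    def test_basic_definition(self):
        out = delay_embed([1, 2, 3, 4, 5], dim=2, tau=1)
        np.testing.assert_array_equal(out, [[2, 1], [3, 2], [4, 3], [5, 4]])

    def test_dim_one_is_identity(self):
        np.testing.assert_array_equal(delay_embed([1, 2, 3], 1, 1),
                                      [[1], [2], [3]])

    def test_vector_count(self):
        assert delay_embed(np.arange(5), dim=3, tau=2).shape == (1, 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            delay_embed(np.arange(4), dim=3, tau=2)


class TestSelectDelay:
    def test_white_noise_gives_one(self, rng):
        assert select_delay(rng.standard_normal(5000)) == 1

    def test_ar1_gives_first_crossing_of_1_over_e(self):
        # a^tau < e^-1  <=>  tau > 1/0.10536 for a = 0.9, so tau = 10
        rng = np.random.default_rng(5)
        x = np.empty(200_000)
        x[0] = 0.0
        eps = rng.standard_normal(x.size)
        for t in range(1, x.size):
            x[t] = 0.9 * x[t - 1] + eps[t]
        assert select_delay(x) == 10

    def test_delay_grows_with_sine_period(self, rng):
        taus = []
        for period in (20, 80):
            t = np.arange(6000)
            x = np.sin(2 * np.pi * t / period) + \
                0.1 * rng.standard_normal(t.size)
            taus.append(select_delay(x))
        assert taus[1] > taus[0]

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_delay(np.ones(1000))


class TestCao:
    def test_white_noise_e2_near_one_for_all_d(self, rng):
        _, e2 = cao_statistics(rng.standard_normal(3000), tau=1, d_max=5)
        assert np.all(np.abs(e2 - 1.0) < 0.1)

    def test_noiseless_sine_embeds_in_low_dimension(self):
        # incommensurate period so the sampled phases fill the circle
        x = np.sin(np.arange(3000) / 4.0)
        assert cao_dimension(x, tau=6, d_max=8) <= 3

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cao_dimension(np.full(2000, 3.3), tau=1)


SPEC1 = EmbeddingSpec(d=1, m=1, tau=1, u=1)


class TestKsgTe:
    def test_independent_pair_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(ksg_te(y, x, SPEC1).value) < 0.01

    def test_gaussian_te_gc_equivalence_error_shrinks_with_n(self):
        """|TE_bits - GC/(2 ln 2)| decreases over n in {1e3, 1e4, 1e5}
        on the linear-Gaussian fixture."""
        errs = []
        for n in (1000, 10_000, 100_000):
            x, y = gen_coupled_pair(n=n, a=0.5, b=0.5, c=0.5, lag=1, seed=2)
            te = ksg_te(y, x, SPEC1).value
            gc = granger(x, y, p=1)
            errs.append(abs(te - gc / (2 * math.log(2))))
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_markov_chain_matches_plugin_oracle(self, rng):
        """KSG on a (jittered) 2-state Markov-chain pair reproduces the
        exact plug-in transfer entropy summed over the finite outcome
        space."""
        py = np.array([[0.7, 0.3], [0.2, 0.8]])       # p(y'|y)
        px1 = {(0, 0): 0.1, (0, 1): 0.7, (1, 0): 0.4, (1, 1): 0.9}

        # exact TE via the stationary law of the joint chain (x_t, y_t)
        states = list(itertools.product([0, 1], [0, 1]))
        T = np.zeros((4, 4))
        for i, (xs, ys) in enumerate(states):
            for j, (xn, yn) in enumerate(states):
                px = px1[(xs, ys)] if xn == 1 else 1 - px1[(xs, ys)]
                T[i, j] = px * py[ys, yn]
        w, v = np.linalg.eig(T.T)
        st = np.real(v[:, np.argmax(np.real(w))])
        st /= st.sum()
        pxy = dict(zip(states, st))
        px_marg = {xs: pxy[(xs, 0)] + pxy[(xs, 1)] for xs in (0, 1)}
        pnext = {xs: sum(pxy[(xs, ys)] * px1[(xs, ys)] for ys in (0, 1))
                 / px_marg[xs] for xs in (0, 1)}
        te_exact = 0.0
        for (xs, ys), pr in pxy.items():
            for xn in (0, 1):
                pc = px1[(xs, ys)] if xn == 1 else 1 - px1[(xs, ys)]
                pm = pnext[xs] if xn == 1 else 1 - pnext[xs]
                te_exact += pr * pc * math.log2(pc / pm)

        n = 30_000
        xc = np.empty(n, int)
        yc = np.empty(n, int)
        xc[0] = yc[0] = 0
        u1, u2 = rng.random(n), rng.random(n)
        for t in range(1, n):
            yc[t] = int(u1[t] < py[yc[t - 1], 1])
            xc[t] = int(u2[t] < px1[(xc[t - 1], yc[t - 1])])
        jit = 1e-4
        est = ksg_te(yc + jit * rng.standard_normal(n),
                     xc + jit * rng.standard_normal(n), SPEC1).value
        assert est == pytest.approx(te_exact, abs=0.03)

    def test_affine_invariance(self, rng):
        x, y = gen_coupled_pair(n=5000, c=0.5, lag=1, seed=9)
        base = ksg_te(y, x, SPEC1).value
        scaled = ksg_te(100.0 * y - 7.0, 0.01 * x + 3.0, SPEC1).value
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_asymmetry_under_unidirectional_coupling(self):
        fwd, rev = [], []
        for seed in range(20):
            x, y = gen_coupled_pair(n=2000, c=0.3, lag=1, seed=seed)
            fwd.append(ksg_te(y, x, SPEC1).value)
            rev.append(ksg_te(x, y, SPEC1).value)
        assert np.median(fwd) > np.median(rev)

    def test_theiler_window_smooth_and_finite(self):
        x, y = gen_coupled_pair(n=3000, c=0.5, lag=1, seed=3)
        vals = {}
        n_eff = {}
        for T in (0, 1, 2):
            res = ksg_te(y, x, SPEC1.replace(theiler=T))
            assert np.isfinite(res.value)
            vals[T] = res.value
            n_eff[T] = res.n_effective
        assert n_eff[1] <= n_eff[0]
        assert abs(vals[1] - vals[0]) < 0.05

    def test_n_effective_accounting(self):
        x, y = gen_coupled_pair(n=1000, seed=0)
        spec = EmbeddingSpec(d=3, m=2, tau=2, u=4)
        res = ksg_te(y, x, spec)
        assert res.n_effective == 1000 - (3 - 1) * 2 - 4

    @pytest.mark.parametrize("bad_x", [np.full(2000, 2.0),
                                       np.r_[np.nan, np.zeros(1999)]])
    def test_degenerate_series_rejected(self, bad_x, rng):
        with pytest.raises(ValueError):
            ksg_te(rng.standard_normal(2000), bad_x, SPEC1)

    def test_pooled_epochs_close_to_continuous(self):
        x, y = gen_coupled_pair(n=6000, c=0.5, lag=1, seed=7)
        cont = ksg_te(y, x, SPEC1).value
        pooled = ksg_te_epochs(y.reshape(20, 300), x.reshape(20, 300),
                               SPEC1).value
        assert pooled == pytest.approx(cont, abs=0.03)


class TestSelectU:
    def test_ms_conversion_round_half_up(self):
        samples = [ms_to_samples(ms, 250.0)
                   for ms in (5, 10, 20, 40, 60, 80, 100)]
        assert samples == [1, 3, 5, 10, 15, 20, 25]
        assert ms_to_samples(1, 250.0) == 1  # floor at one sample

    def test_true_lag_maximizes_te(self):
        x, y = gen_coupled_pair(n=20_000, c=0.8, lag=10, seed=6)
        # candidates 4/20/40/80 ms at 250 Hz -> 1, 5, 10, 20 samples
        u, scores = select_u(y.reshape(40, 500), x.reshape(40, 500), SPEC1,
                             candidates_ms=[4, 20, 40, 80], fs=250.0)
        assert u == 10
        assert scores[10] == max(scores.values())

    def test_single_candidate_returned(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        u, _ = select_u(y, x, SPEC1, candidates_ms=[40], fs=250.0)
        assert u == 10

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_u(rng.standard_normal(100), rng.standard_normal(100),
                     SPEC1, candidates_ms=[], fs=250.0)


class TestSurrogate:
    def test_coupled_pair_detected(self):
        x, y = gen_coupled_pair(n=8000, c=0.8, lag=1, seed=12)
        p, obs, null = surrogate_test(y, x, SPEC1, n_perm=200, seed=0,
                                      n_chunks=16)
        assert p <= 0.01
        assert obs > np.quantile(null, 0.99)

    def test_independent_pair_not_detected(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        p, _, _ = surrogate_test(y, x, SPEC1, n_perm=200, seed=0,
                                 n_chunks=16)
        assert p > 0.05

    def test_circular_shift_null_for_single_trial(self):
        x, y = gen_coupled_pair(n=2000, c=0.8, lag=1, seed=12)
        p, _, _ = surrogate_test(y, x, SPEC1, n_perm=39, seed=0)
        assert p == pytest.approx(1 / 40, abs=1e-12)

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            surrogate_test(rng.standard_normal(2000),
                           rng.standard_normal(2000), SPEC1, n_perm=0)
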