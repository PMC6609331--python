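import numpy as np
import pytest

from ornfidelity import decoding as dec
from ornfidelity import encoder as enc
from ornfidelity import stimuli as st


def random_matrix(m, n, seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(m, n))
    return dec.MeasurementMatrix(d, np.zeros(n), np.zeros(m),
                                 np.ones(m, dtype=bool))


class TestCsDecode:
    def test_zero_measurement_gives_zero(self):
        mm = random_matrix(10, 20, 0)
        res = dec.cs_decode(np.zeros(10), mm)
        assert res.feasible
        np.testing.assert_allclose(res.estimate, 0.0, atol=1e-9)

    def test_single_support_exact_recovery(self):
        mm = random_matrix(10, 20, 1)
        x = np.zeros(20)
        x[7] = 1.3
        res = dec.cs_decode(mm.d @ x, mm)
        np.testing.assert_allclose(res.estimate, x, atol=1e-6)

    def test_matches_exhaustive_support_search(self):
        # K<=3 on (M=10, N=20) Gaussian instances vs brute-force
        # least-squares over all support triples
        from itertools import combinations

        n_ok = 0
        n_trials = 40
        for seed in range(n_trials):
            rng = np.random.default_rng(100 + seed)
            d = rng.normal(size=(10, 20))
            mm = dec.MeasurementMatrix(d, np.zeros(20), np.zeros(10),
                                       np.ones(10, dtype=bool))
            k = int(rng.integers(1, 4))
            supp = rng.choice(20, size=k, replace=False)
            x = np.zeros(20)
            x[supp] = rng.normal(1.0, 0.3, size=k)
            y = d @ x
            res = dec.cs_decode(y, mm)
            best, best_res = None, np.inf
            for cand in combinations(range(20), k):
                sub = d[:, cand]
                coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
                r = np.linalg.norm(sub @ coef - y)
                if r < best_res - 1e-12:
                    best_res, best = r, (cand, coef)
            x_oracle = np.zeros(20)
            x_oracle[list(best[0])] = best[1]
            if np.allclose(res.estimate, x_oracle, atol=1e-5):
                n_ok += 1
        # K=3 on a 10x20 Gaussian matrix sits near the L1 phase
        # transition, so exact agreement with the combinatorial oracle is
        # high but not certain
        assert n_ok / n_trials >= 0.85

    def test_l1_optimality_certificate(self):
        # objective never exceeds the truth's L1 norm when truth is feasible
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mm = random_matrix(12, 30, seed + 50)
            x = np.zeros(30)
            x[rng.choice(30, 4, replace=False)] = rng.normal(size=4)
            res = dec.cs_decode(mm.d @ x, mm)
            assert np.abs(res.estimate).sum() <= np.abs(x).sum() + 1e-7

    def test_feasibility_residual_small(self):
        mm = random_matrix(10, 20, 3)
        rng = np.random.default_rng(3)
        x = np.zeros(20)
        x[[2, 9]] = [1.0, 0.5]
        res = dec.cs_decode(mm.d @ x, mm)
        resid = np.abs(mm.d @ res.estimate - mm.d @ x).max()
        assert resid < 1e-6


class TestDecodeSuccess:
    def test_exact_estimate_succeeds(self, rng):
        truth = st.sample_sparse_odor(50, 4, 1.0, rng)
        assert dec.decode_success(truth.concentrations.copy(), truth)

    def test_thirty_percent_error_fails(self, rng):
        truth = st.sample_sparse_odor(50, 4, 1.0, rng)
        est = truth.concentrations.copy()
        i = truth.support[0]
        est[i] *= 1.30
        assert not dec.decode_success(est, truth)

    def test_small_zero_component_tolerated(self, rng):
        truth = st.sample_sparse_odor(50, 4, 1.0, rng)
        est = truth.concentrations.copy()
        free = next(i for i in range(50) if i not in truth.support)
        est[free] = 0.09
        assert dec.decode_success(est, truth)
        est[free] = 0.11
        assert not dec.decode_success(est, truth)


class TestHardThreshold:
    def test_magnitude_selection_hand_case(self):
        np.testing.assert_array_equal(
            dec.hard_threshold(np.array([3.0, -5.0, 1.0]), 1),
            np.array([0.0, -5.0, 0.0]))

    def test_k_equals_n_is_identity(self, rng):
        v = rng.normal(size=8)
        np.testing.assert_array_equal(dec.hard_threshold(v, 8), v)

    def test_idempotent(self, rng):
        v = rng.normal(size=12)
        once = dec.hard_threshold(v, 4)
        np.testing.assert_array_equal(dec.hard_threshold(once, 4), once)

    def test_tie_break_lowest_index(self):
        v = np.array([2.0, -2.0, 1.0])
        np.testing.assert_array_equal(dec.hard_threshold(v, 1),
                                      np.array([2.0, 0.0, 0.0]))


def linear_iht_reference(y, d, k, mu, n_steps):
    """Textbook linear IHT with unit-normalized columns, for cross-checking."""
    norms = np.linalg.norm(d, axis=0)
    norms[norms == 0] = 1.0
    dn = d / norms
    x = np.zeros(d.shape[1])
    for _ in range(n_steps):
        x = dec.hard_threshold(x + mu * dn.T @ (y - d @ x), k)
    return x


class TestIhtDecode:
    def test_response_at_init_returns_zero(self):
        mm = random_matrix(10, 20, 4)

        def sensing(x):
            return mm.d @ x, mm.d

        res = dec.iht_decode(np.zeros(10), sensing, 20, 3)
        np.testing.assert_allclose(res.estimate, 0.0)

    def test_matches_reference_linear_iht(self):
        rng = np.random.default_rng(21)
        d = rng.normal(size=(10, 20))
        x_true = np.zeros(20)
        x_true[[3, 11]] = [1.0, -0.7]
        y = d @ x_true

        def sensing(x):
            return d @ x, d

        mu = 0.3
        res = dec.iht_decode(y, sensing, 20, 2, mu=mu, max_iter=5,
                             tol=0.0)
        ref = linear_iht_reference(y, d, 2, mu, 5)
        np.testing.assert_allclose(res.estimate, ref, atol=1e-10)

    def test_linear_recovery(self):
        rng = np.random.default_rng(22)
        d = rng.normal(size=(12, 24))
        x_true = np.zeros(24)
        x_true[[1, 7, 18]] = [1.2, 0.8, 1.5]
        y = d @ x_true

        def sensing(x):
            return d @ x, d

        res = dec.iht_decode(y, sensing, 24, 3, max_iter=500)
        np.testing.assert_allclose(res.estimate, x_true, atol=1e-4)

    def test_agrees_with_cs_decode_on_orn_map(self, repertoire, adaptation):
        # nonlinear ORN sensing at moderate intensity: IHT success agrees
        # with the L1 decoder on >= 90% of noiseless trials
        n_trials = 30
        agree = 0
        for seed in range(n_trials):
            rng = np.random.default_rng(300 + seed)
            fg = st.sample_sparse_odor(repertoire.n, 2, 1.0, rng).scaled(20)
            eps = enc.steady_state_epsilon(fg, adaptation, repertoire,
                                           beta=0.0)
            r = enc.steady_rates(fg.concentrations, eps, repertoire)
            sensing = dec.make_orn_sensing_fn(repertoire, adaptation, eps)
            res_iht = dec.iht_decode(r, sensing, repertoire.n, 2,
                                     max_iter=300, nonnegative=True)
            ok_iht = res_iht.feasible and dec.decode_success(
                np.clip(res_iht.estimate, 0, None), fg)
            res_l1 = dec.nonlinear_sparse_decode(r, eps, repertoire,
                                                 adaptation)
            ok_l1 = res_l1.feasible and dec.decode_success(
                np.clip(res_l1.estimate, 0, None), fg)
            agree += ok_iht == ok_l1
        assert agree / n_trials >= 0.9


class TestLinearizedMatrix:
    def test_unbound_odorant_column_is_zero(self, adaptation):
        kstar = np.full((5, 8), 2.0)
        kstar[:, 3] = 1e-12  # effectively nothing binds odorant 3
        rep = enc.ReceptorRepertoire(kstar, kstar * 1e-6)
        par = enc.AdaptationParams(eps_low=np.full(5, 4.0),
                                   eps_high=np.full(5, 13.0))
        mm = dec.linearized_measurement_matrix(np.ones(8), rep, par)
        assert np.abs(mm.d[:, 3]).max() < 1e-10 * np.abs(mm.d).max()

    def test_entries_match_finite_difference(self, repertoire, adaptation,
                                             rng):
        sbar = st.sample_sparse_odor(repertoire.n, 5, 1.0,
                                     np.random.default_rng(31)).scaled(10)
        mm = dec.linearized_measurement_matrix(sbar, repertoire, adaptation)
        filt = enc.FiringFilter()
        for i in list(sbar.support)[:2] + [0]:
            ds = 1e-6 * max(sbar.concentrations[i], 1.0)
            plus = sbar.concentrations.copy()
            plus[i] += ds
            fd = filt.dc_gain * (
                enc.channel_activity(plus, mm.eps_state, repertoire)
                - enc.channel_activity(sbar.concentrations, mm.eps_state,
                                       repertoire)) / ds
            np.testing.assert_allclose(mm.d[:, i], fd, rtol=1e-4, atol=1e-9)

    def test_adaptive_entries_weber_scale(self, repertoire, adaptation):
        # doubling the background halves the adaptive gain entries (beta=0,
        # single-odorant deep regime)
        sbar1 = np.zeros(repertoire.n)
        sbar1[5] = 500.0
        sbar2 = sbar1 * 2
        m1 = dec.linearized_measurement_matrix(sbar1, repertoire, adaptation)
        m2 = dec.linearized_measurement_matrix(sbar2, repertoire, adaptation)
        # restrict to rows where adaptation is engaged (unclipped) and the
        # regime holds
        unclipped = (m1.eps_state > adaptation.eps_low + 1e-9) & \
                    (m2.eps_state < adaptation.eps_high - 1e-9)
        deep = repertoire.kstar[:, 5] * 500.0 > 50.0
        rows = unclipped & deep
        assert rows.sum() >= 3
        ratio = m2.d[rows, 5] / m1.d[rows, 5]
        np.testing.assert_allclose(ratio, 0.5, rtol=0.01)


class TestRipSpectrum:
    def test_orthonormal_columns_have_unit_spectrum(self):
        cols = np.linalg.qr(np.random.default_rng(0).normal(size=(10, 4)))[0]
        lam = dec.gram_spectrum(cols)
        np.testing.assert_allclose(lam, 1.0, atol=1e-10)

    def test_duplicate_columns_split_spectrum(self):
        c = np.random.default_rng(1).normal(size=10)
        cols = np.column_stack([c, c])
        lam = dec.gram_spectrum(cols)
        np.testing.assert_allclose(np.sort(lam), [0.0, 2.0], atol=1e-10)

    def test_adaptive_spread_smaller_at_high_intensity(self, repertoire,
                                                       adaptation):
        rng_a = np.random.default_rng(77)
        rng_n = np.random.default_rng(77)
        spec_a = dec.rip_spectrum(repertoire, adaptation, k=5, n_draws=60,
                                  rng=rng_a, intensity=100.0, adaptive=True)
        spec_n = dec.rip_spectrum(repertoire, adaptation, k=5, n_draws=60,
                                  rng=rng_n, intensity=100.0, adaptive=False)
        assert spec_a.median_delta < spec_n.median_delta
        assert np.all(spec_a.lambda_min >= -1e-10)


class TestStaticDecoding:
    def test_adaptive_dominates_at_mid_high_intensity(self, repertoire,
                                                      adaptation):
        accs = {}
        for adaptive in (True, False):
            rng = np.random.default_rng(55)
            accs[adaptive] = dec.static_decoding_accuracy(
                repertoire, adaptation, rng, k_background=5,
                background_intensity=10.0, n_pairs=15, adaptive=adaptive)
        assert accs[True] > accs[False]

    def test_grid_shapes_and_bounds(self, repertoire, adaptation):
        rng = np.random.default_rng(56)
        acc_a, acc_n = dec.decoding_accuracy_grid(
            repertoire, adaptation, rng,
            intensities=np.array([10.0, 100.0]),
            complexities=np.array([2, 5]), n_pairs=4)
        for acc in (acc_a, acc_n):
            assert acc.shape == (2, 2)
            assert np.all((acc >= 0) & (acc <= 1))


class TestTemporalDecoding:
    @pytest.fixture(scope="class")
    def toy_plume(self):
        dt = 0.002
        n = int(8.0 / dt)
        inten = np.full(n, 1.0)
        whiffs = [(1.5, 2.5), (4.0, 5.0), (6.0, 7.0)]
        for s, e in whiffs:
            inten[int(s / dt):int(e / dt)] = 8.0
        return st.PlumeSignal(np.arange(n) * dt, dt, inten, 4.0, whiffs)

    def test_zero_background_all_whiffs_decoded(self, toy_plume, repertoire,
                                                adaptation):
        fg = st.sample_sparse_odor(repertoire.n, 5, 1.0,
                                   np.random.default_rng(1))
        report = dec.decode_time_series(
            toy_plume, fg, st.SparseOdor.zero(repertoire.n), repertoire,
            adaptation, tau_m=0.5, adaptive=True, decode_dt=0.04)
        assert report.percent_whiffs_decoded == 100.0

    def test_memory_shorter_than_tau_degrades(self, toy_plume, repertoire,
                                              adaptation):
        fg = st.sample_sparse_odor(repertoire.n, 5, 1.0,
                                   np.random.default_rng(1))
        bg = st.sample_disjoint_odor(fg, 5, 1.0,
                                     np.random.default_rng(2)).scaled(100.0)
        long_m = dec.decode_time_series(toy_plume, fg, bg, repertoire,
                                        adaptation, tau_m=0.5,
                                        adaptive=True, decode_dt=0.04)
        short_m = dec.decode_time_series(toy_plume, fg, bg, repertoire,
                                         adaptation, tau_m=0.01,
                                         adaptive=True, decode_dt=0.04)
        assert short_m.percent_whiffs_decoded <= long_m.percent_whiffs_decoded

    def test_nonadaptive_fails_under_strong_background(self, toy_plume,
                                                       repertoire,
                                                       adaptation):
        fg = st.sample_sparse_odor(repertoire.n, 5, 1.0,
                                   np.random.default_rng(1))
        bg = st.sample_disjoint_odor(fg, 5, 1.0,
                                     np.random.default_rng(2)).scaled(3000.0)
        rep_a = dec.decode_time_series(toy_plume, fg, bg, repertoire,
                                       adaptation, tau_m=0.5, adaptive=True,
                                       decode_dt=0.04)
        rep_n = dec.decode_time_series(toy_plume, fg, bg, repertoire,
                                       adaptation, tau_m=0.5, adaptive=False,
                                       decode_dt=0.04)
        assert rep_a.percent_whiffs_decoded > rep_n.percent_whiffs_decoded
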