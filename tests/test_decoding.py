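"""Decoding core: lag grids, lagged designs, ridge solve, CV, decoders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avmsi._exceptions import DegenerateSignalError, SingularSystemError
from avmsi.decoding import (
    LAMBDA_GRID,
    CovarianceAccumulator,
    EnvelopeDecoder,
    LagGrid,
    SumCovarianceDecoder,
    build_lagged_design,
    crossval_lambda,
    pearson_r,
    solve_ridge,
)


class TestLagGrid:
    @pytest.mark.parametrize(
        "lo,hi,n", [(0, 500, 33), (-500, 500, 65), (0, 0, 1), (-500, -500, 1)]
    )
    def test_lag_counts(self, lo, hi, n):
        assert LagGrid(lo, hi, 64.0).n_lags == n

    def test_spacing_is_sample_period(self):
        grid = LagGrid(-500, 500, 64.0)
        np.testing.assert_allclose(np.diff(grid.lag_times_ms), 15.625)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            LagGrid(100, 0, 64.0)
        with pytest.raises(ValueError):
            LagGrid(0, 100, -1.0)


class TestLaggedDesign:
    def test_hand_enumerated_shift_pad(self):
        eeg = np.array([[1.0, 2.0, 3.0]])
        R = build_lagged_design(eeg, LagGrid(0, 1000 / 64, 64.0))  # lags {0, 1}
        np.testing.assert_array_equal(R, [[1, 2], [2, 3], [3, 0]])

    def test_negative_lag_pads_front(self):
        eeg = np.array([[1.0, 2.0, 3.0]])
        R = build_lagged_design(eeg, LagGrid(-1000 / 64, 0, 64.0))  # lags {-1, 0}
        np.testing.assert_array_equal(R, [[0, 1], [1, 2], [2, 3]])

    def test_zero_lag_is_transpose(self):
        eeg = np.random.default_rng(0).standard_normal((4, 50))
        R = build_lagged_design(eeg, LagGrid(0, 0, 64.0))
        np.testing.assert_array_equal(R, eeg.T)

    def test_column_count(self):
        eeg = np.zeros((5, 100))
        R = build_lagged_design(eeg, LagGrid(0, 500, 64.0))
        assert R.shape == (100, 5 * 33)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            build_lagged_design(np.zeros((2, 10)), LagGrid(0, 500, 64.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_every_column_is_a_shifted_channel(self, seed):
        rng = np.random.default_rng(seed)
        n_ch, n_t = 3, 40
        eeg = rng.standard_normal((n_ch, n_t))
        grid = LagGrid(-3000 / 64, 2000 / 64, 64.0)
        R = build_lagged_design(eeg, grid)
        lags = grid.lags
        n, j = int(rng.integers(n_ch)), int(rng.integers(len(lags)))
        t = int(rng.integers(n_t))
        expected = eeg[n, t + lags[j]] if 0 <= t + lags[j] < n_t else 0.0
        assert R[t, n * len(lags) + j] == expected


class TestRidgeSolve:
    def _oracle(self, X, y, lam):
        n, p = X.shape
        Xa = np.column_stack([X, np.ones(n)])
        pen = lam * np.eye(p + 1)
        pen[p, p] = 0.0
        return np.linalg.solve(Xa.T @ Xa + pen, Xa.T @ y)

    @pytest.mark.parametrize("lam", [1e-6, 1.0, 1e4])
    def test_matches_dense_normal_equations_oracle(self, lam):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X = rng.standard_normal((20, 4))
            y = rng.standard_normal(20)
            coef, intercept = solve_ridge(CovarianceAccumulator.from_trial(X, y), lam)
            g = self._oracle(X, y, lam)
            np.testing.assert_allclose(coef[:, 0], g[:4], atol=1e-10)
            assert intercept[0] == pytest.approx(g[4], abs=1e-10)

    def test_heavy_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        acc = CovarianceAccumulator.from_trial(X, y)
        coef, _ = solve_ridge(acc, 1e12)
        assert np.linalg.norm(coef) < 1e-9 * np.linalg.norm(acc.Xty)

    def test_orthonormal_design_identity(self):
        # orthonormal centered columns, lambda=0 -> g = X'y exactly
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        Q = Q - Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)  # re-orthonormalize after centering
        y = rng.standard_normal(30)
        coef, _ = solve_ridge(CovarianceAccumulator.from_trial(Q, y), 0.0)
        np.testing.assert_allclose(coef[:, 0], Q.T @ y, atol=1e-10)

    def test_singular_at_zero_lambda_signaled(self):
        X = np.ones((10, 3))  # rank-1 columns, centered -> zero matrix
        y = np.arange(10.0)
        with pytest.raises(SingularSystemError):
            solve_ridge(CovarianceAccumulator.from_trial(X, y), 0.0)

    def test_negative_lambda_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError):
            solve_ridge(CovarianceAccumulator.from_trial(X, X[:, 0]), -1.0)

    def test_shrinkage_monotonicity(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        acc = CovarianceAccumulator.from_trial(X, y)
        norms = [
            np.linalg.norm(solve_ridge(acc, lam)[0]) for lam in 10.0 ** np.arange(-3, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestAccumulator:
    def test_additivity_and_order_invariance(self):
        rng = np.random.default_rng(0)
        trials = [
            (rng.standard_normal((30, 5)), rng.standard_normal(30)) for _ in range(4)
        ]
        fwd = CovarianceAccumulator(5)
        for R, y in trials:
            fwd.add_trial(R, y)
        rev = CovarianceAccumulator(5)
        for R, y in reversed(trials):
            rev.add_trial(R, y)
        np.testing.assert_allclose(fwd.XtX, rev.XtX, atol=1e-12)
        np.testing.assert_allclose(fwd.Xty, rev.Xty, atol=1e-12)

    def test_subtraction_recovers_leave_one_out(self):
        rng = np.random.default_rng(1)
        trials = [
            (rng.standard_normal((20, 3)), rng.standard_normal(20)) for _ in range(3)
        ]
        total = CovarianceAccumulator(3)
        for R, y in trials:
            total.add_trial(R, y)
        loo = total - CovarianceAccumulator.from_trial(*trials[0])
        direct = CovarianceAccumulator(3)
        for R, y in trials[1:]:
            direct.add_trial(R, y)
        np.testing.assert_allclose(loo.XtX, direct.XtX, atol=1e-10)
        np.testing.assert_allclose(loo.Xty, direct.Xty, atol=1e-10)
        assert loo.n_samples == direct.n_samples


class TestPearson:
    def test_constant_signals_signaled(self):
        with pytest.raises(DegenerateSignalError):
            pearson_r(np.ones(10), np.arange(10.0))
        with pytest.raises(DegenerateSignalError):
            pearson_r(np.arange(10.0), np.full(10, np.nan))

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 50.0),
        st.floats(-10.0, 10.0),
    )
    def test_invariant_to_positive_affine_rescaling(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        r1 = pearson_r(a, b)
        r2 = pearson_r(a, scale * b + shift)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestCrossval:
    def _make_trials(self, rng, n_trials=4, n_ch=3, n_t=120, noise=0.5):
        grid = LagGrid(0, 125, 64.0)
        w = rng.standard_normal(n_ch * grid.n_lags)
        trials, envs = [], []
        for _ in range(n_trials):
            eeg = rng.standard_normal((n_ch, n_t))
            R = build_lagged_design(eeg, grid)
            envs.append(R @ w + noise * rng.standard_normal(n_t))
            trials.append(eeg)
        return trials, envs, grid

    def test_grid_has_19_candidates(self):
        assert len(LAMBDA_GRID) == 19
        assert LAMBDA_GRID[0] == 1e-6
        assert LAMBDA_GRID[-1] == 1e30

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        trials, envs, grid = self._make_trials(rng)
        lam, curve = crossval_lambda(trials, envs, grid, lambdas=[13.7])
        assert lam == 13.7
        assert curve.shape == (1,)

    def test_matches_brute_force_grid_search(self):
        """Independent loop: refit each fold from scratch with a dense solver."""
        rng = np.random.default_rng(1)
        trials, envs, grid = self._make_trials(rng, noise=2.0)
        lambdas = 10.0 ** np.arange(-2, 9, 2)
        lam, curve = crossval_lambda(trials, envs, grid, lambdas=lambdas)

        designs = [build_lagged_design(e, grid) for e in trials]
        brute = np.zeros(len(lambdas))
        for li, l_ in enumerate(lambdas):
            rs = []
            for i in range(len(trials)):
                X = np.vstack([designs[j] for j in range(len(trials)) if j != i])
                y = np.concatenate([envs[j] for j in range(len(trials)) if j != i])
                Xc, yc = X - X.mean(0), y - y.mean()
                g = np.linalg.solve(Xc.T @ Xc + l_ * np.eye(X.shape[1]), Xc.T @ yc)
                pred = designs[i] @ g
                rs.append(np.corrcoef(pred, envs[i])[0, 1])
            brute[li] = np.mean(rs)
        np.testing.assert_allclose(curve, brute, atol=1e-8)
        assert lam == lambdas[np.flatnonzero(brute == brute.max()).max()]

    def test_requires_two_trials(self):
        rng = np.random.default_rng(2)
        trials, envs, grid = self._make_trials(rng, n_trials=1)
        with pytest.raises(ValueError):
            crossval_lambda(trials, envs, grid)


class TestEnvelopeDecoder:
    def test_in_sample_exact_fit_on_noiseless_trial(self):
        rng = np.random.default_rng(0)
        grid = LagGrid(0, 125, 64.0)
        eeg = rng.standard_normal((3, 200))
        R = build_lagged_design(eeg, grid)
        env = R @ rng.standard_normal(R.shape[1])
        dec = EnvelopeDecoder(tau_max_ms=125, lambdas=[1e-8]).fit([eeg], [env])
        assert dec.score([eeg], [env]) >= 0.999

    def test_zero_weight_decoder_signals_degenerate(self):
        dec = EnvelopeDecoder(tau_max_ms=125, lambdas=[1e-8])
        rng = np.random.default_rng(1)
        eeg = rng.standard_normal((2, 100))
        dec.fit([eeg], [rng.standard_normal(100)])
        dec.coef_ = np.zeros_like(dec.coef_)
        with pytest.raises(DegenerateSignalError):
            dec.score([eeg], [rng.standard_normal(100)])

    def test_noiseless_synthetic_cohort_reconstructs(self, rng):
        """Held-out accuracy approaches 1 when the generator has no noise."""
        from avmsi.studies import _simulate_study_subject

        trials = _simulate_study_subject(
            seed=7, n_channels=4, trials_per_cell=3, duration_s=60.0, noise_sd=0.0,
            gain_visual_by_gaze={"d": 0.0, "c": 0.0, "e": 0.0},
            gain_unatt=1e-9,  # competing stream is spatially collinear here
            auditory_undershoot=0.0,  # monophasic kernel: invertible in-band
        )
        av = [t for t in trials if t.modality == "AV"]
        dec = EnvelopeDecoder(tau_max_ms=400).fit(
            [t.eeg for t in av], [t.env_att for t in av]
        )
        idx = int(np.flatnonzero(dec._lambdas() == dec.lambda_)[0])
        assert np.nanmean(dec.cv_fold_scores_[idx]) > 0.99

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        dec = EnvelopeDecoder(tau_min_ms=-100, tau_max_ms=300, lambdas=[1.0])
        params = dec.get_params()
        assert params["tau_min_ms"] == -100
        dec2 = clone(dec)
        assert dec2.get_params() == params

    def test_weights_shape(self):
        rng = np.random.default_rng(2)
        trials = [rng.standard_normal((4, 100)) for _ in range(2)]
        envs = [rng.standard_normal(100) for _ in range(2)]
        dec = EnvelopeDecoder(tau_max_ms=250).fit(trials, envs)
        assert dec.weights_.shape == (4, LagGrid(0, 250, 64.0).n_lags)


class TestSumDecoder:
    def test_doubled_data_equals_summed_accumulators(self):
        """trials_A == trials_V -> equals a decoder fit on the concatenation."""
        rng = np.random.default_rng(0)
        trials = [rng.standard_normal((3, 150)) for _ in range(3)]
        envs = [rng.standard_normal(150) for _ in range(3)]
        lam = [100.0]
        sdec = SumCovarianceDecoder(tau_max_ms=250, lambdas=lam).fit(
            trials, envs, trials, envs
        )
        # doubling every trial doubles (X'X, X'y): solve with lambda/... the
        # summed statistics are exactly the doubled-concatenation statistics
        double = EnvelopeDecoder(tau_max_ms=250, lambdas=lam).fit(
            trials + trials, envs + envs
        )
        np.testing.assert_allclose(sdec.coef_, double.coef_, atol=1e-12)

    def test_matches_hand_summed_normal_equations(self):
        rng = np.random.default_rng(1)
        grid = LagGrid(0, 125, 64.0)
        t_a = [rng.standard_normal((2, 80)) for _ in range(2)]
        y_a = [rng.standard_normal(80) for _ in range(2)]
        t_v = [rng.standard_normal((2, 80)) for _ in range(2)]
        y_v = [rng.standard_normal(80) for _ in range(2)]
        lam = 50.0
        sdec = SumCovarianceDecoder(tau_max_ms=125, lambdas=[lam]).fit(t_a, y_a, t_v, y_v)
        X = np.vstack([build_lagged_design(e, grid) for e in t_a + t_v])
        y = np.concatenate(y_a + y_v)
        Xc, yc = X - X.mean(0), y - y.mean()
        g = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
        np.testing.assert_allclose(sdec.coef_, g, atol=1e-10)

    def test_lambda_selected_on_av_trials(self):
        rng = np.random.default_rng(2)
        trials = [rng.standard_normal((2, 100)) for _ in range(6)]
        envs = [rng.standard_normal(100) for _ in range(6)]
        sdec = SumCovarianceDecoder(tau_max_ms=125).fit(
            trials[:2], envs[:2], trials[2:4], envs[2:4],
            X_av=trials[4:], y_av=envs[4:],
        )
        assert sdec.lambda_ in LAMBDA_GRID
        assert sdec.cv_scores_.shape == (19,)

    def test_empty_unisensory_set_rejected(self):
        with pytest.raises(ValueError):
            SumCovarianceDecoder().fit([], [], [np.zeros((2, 50))], [np.zeros(50)])
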