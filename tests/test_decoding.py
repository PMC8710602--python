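"""Backward TRF estimation, reconstruction and leave-one-out evaluation."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from attentrf.decoding import (
    Decoder,
    LagSpec,
    StimulusReconstruction,
    TrialRecord,
    TrialSolver,
    build_lag_matrix,
    fisher_z,
    fit_ridge_decoder,
    loo_reconstruction_accuracy,
    pad_envelope,
    pearson_r,
    reconstruct_envelope,
)
from attentrf.dsp import EEGRecord, Envelope
from attentrf.simulate import ForwardTRF, gen_stream


def small_spec(n_lags=3):
    # lags -(n_lags-1)...0 samples at 64 Hz
    return LagSpec(-(n_lags - 1) * 1000.0 / 64.0, 0.0, 64.0)


class TestLagSpec:
    def test_default_grid_58_lags(self):
        spec = LagSpec()
        assert spec.n_lags == 58
        assert spec.lag_samples[0] == -57 and spec.lag_samples[-1] == 0
        assert spec.step_ms == pytest.approx(15.625)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            LagSpec(0.0, -900.0)


class TestBuildLagMatrix:
    def test_identity_single_lag(self, rng):
        x = rng.standard_normal(20)
        lm = build_lag_matrix(EEGRecord(x[None, :], 64.0), LagSpec(0, 0, 64.0))
        assert lm.values.shape == (1, 20)
        assert np.array_equal(lm.values[0], x)

    def test_two_lag_shift_oracle(self):
        lm = build_lag_matrix(
            EEGRecord(np.array([[1.0, 2.0, 3.0]]), 64.0), small_spec(2)
        )
        # rows grouped by lag (ascending tau): tau=-1 is undelayed, tau=0 delayed by 1
        expected = np.array([[1.0, 2.0, 3.0, 0.0], [0.0, 1.0, 2.0, 3.0]])
        assert np.array_equal(lm.values, expected)

    def test_study_scale_dimensions(self, rng):
        eeg = EEGRecord(rng.standard_normal((31, 768)), 64.0)
        lm = build_lag_matrix(eeg, LagSpec())
        assert lm.values.shape == (31 * 58, 768 + 57)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_lag_matrix(EEGRecord(np.zeros((2, 0)), 64.0))


def ridge_objective(w, V, s, lam):
    resid = s - w @ V
    return float(resid @ resid + lam * w @ w)


class TestFitRidgeDecoder:
    def test_infinite_shrinkage(self, rng):
        lm = build_lag_matrix(EEGRecord(rng.standard_normal((2, 40)), 64.0), small_spec())
        G_scale = np.trace(lm.values @ lm.values.T)
        d = fit_ridge_decoder(lm, rng.standard_normal(40), 1e12 * G_scale)
        assert np.linalg.norm(d.weights) < 1e-6

    def test_scalar_closed_form(self, rng):
        r = rng.standard_normal(30)
        s = rng.standard_normal(30)
        lm = build_lag_matrix(EEGRecord(r[None, :], 64.0), LagSpec(0, 0, 64.0))
        lam = 2.7
        d = fit_ridge_decoder(lm, s, lam)
        assert d.weights[0] == pytest.approx((r @ s) / (r @ r + lam), abs=1e-10)

    def test_objective_matches_numerical_minimizer(self, rng):
        V = rng.standard_normal((6, 40))
        s = rng.standard_normal(40)
        lam = 0.8
        lm = build_lag_matrix(EEGRecord(V, 64.0), LagSpec(0, 0, 64.0))
        d = fit_ridge_decoder(lm, s, lam)
        res = minimize(
            ridge_objective, np.zeros(6), args=(V, s, lam), jac=None, method="BFGS",
            options={"gtol": 1e-12},
        )
        assert ridge_objective(d.weights, V, s, lam) <= res.fun + 1e-8

    def test_dual_and_primal_solutions_agree(self, rng):
        # more rows than time points triggers the dual path; both are the
        # same normal-equation solution
        V = rng.standard_normal((30, 12))
        lam = 1.3
        s = rng.standard_normal(12)
        primal = np.linalg.solve(V @ V.T + lam * np.eye(30), V @ s)
        lm = build_lag_matrix(EEGRecord(V, 64.0), LagSpec(0, 0, 64.0))
        d = fit_ridge_decoder(lm, s, lam)
        assert np.allclose(d.weights, primal, atol=1e-8)

    def test_lambda_zero_singular_warns(self):
        V = np.array([[1.0, 2.0], [2.0, 4.0]])  # rank deficient
        lm = build_lag_matrix(EEGRecord(V, 64.0), LagSpec(0, 0, 64.0))
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            fit_ridge_decoder(lm, np.array([1.0, 0.5]), 0.0)

    def test_shrinkage_monotone_in_lambda(self, rng):
        lm = build_lag_matrix(EEGRecord(rng.standard_normal((4, 60)), 64.0), small_spec())
        s = rng.standard_normal(lm.n_times)
        norms = [
            np.linalg.norm(fit_ridge_decoder(lm, s, lam).weights)
            for lam in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert np.all(np.diff(norms) <= 1e-12)


class TestReconstructEnvelope:
    def test_zero_decoder(self, rng):
        lm = build_lag_matrix(EEGRecord(rng.standard_normal((2, 30)), 64.0), small_spec())
        d = Decoder(np.zeros(6), 2, small_spec(), 1.0)
        assert np.all(reconstruct_envelope(d, lm).samples == 0.0)

    def test_exact_recovery_of_copied_envelope(self, rng):
        env = rng.standard_normal(200)
        lm = build_lag_matrix(EEGRecord(env[None, :], 64.0), LagSpec(0, 0, 64.0))
        d = fit_ridge_decoder(lm, env, 0.0)
        s_hat = reconstruct_envelope(d, lm).samples
        assert pearson_r(s_hat, env) > 0.999

    def test_linearity(self, rng):
        lm = build_lag_matrix(EEGRecord(rng.standard_normal((2, 30)), 64.0), small_spec())
        d1 = Decoder(rng.standard_normal(6), 2, small_spec(), 1.0)
        d2 = Decoder(rng.standard_normal(6), 2, small_spec(), 1.0)
        both = Decoder(d1.weights + d2.weights, 2, small_spec(), 1.0)
        lhs = reconstruct_envelope(both, lm).samples
        rhs = reconstruct_envelope(d1, lm).samples + reconstruct_envelope(d2, lm).samples
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        lm = build_lag_matrix(EEGRecord(rng.standard_normal((2, 30)), 64.0), small_spec())
        with pytest.raises(ValueError):
            reconstruct_envelope(Decoder(np.zeros(5), 2, small_spec(), 1.0), lm)


class TestPearsonAndFisher:
    def test_perfect_correlations(self, rng):
        x = rng.standard_normal(50)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        a, b = [1, 2, 3, 4], [2, 4, 5, 9]
        # sums-of-products arithmetic oracle
        n = 4
        sa, sb = sum(a), sum(b)
        num = n * sum(x * y for x, y in zip(a, b)) - sa * sb
        den = np.sqrt(n * sum(x * x for x in a) - sa**2) * np.sqrt(
            n * sum(y * y for y in b) - sb**2
        )
        assert pearson_r(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_fisher_z_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert fisher_z(-0.3) == -fisher_z(0.3)
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestTrialSolver:
    """The structured solver must match the explicit lag-matrix solve exactly."""

    @pytest.mark.parametrize("n_ch,t0,n_lags", [(3, 50, 5), (2, 120, 12), (5, 80, 8)])
    def test_matches_explicit_normal_equations(self, rng, n_ch, t0, n_lags):
        eeg = EEGRecord(rng.standard_normal((n_ch, t0)), 64.0)
        env = rng.standard_normal(t0)
        spec = small_spec(n_lags)
        lam = 3.16
        solver = TrialSolver(eeg, spec, lam, standardize=False)
        d_fast = solver.fit(env)
        d_ref = fit_ridge_decoder(build_lag_matrix(eeg, spec), env, lam)
        assert np.allclose(d_fast.weights, d_ref.weights, atol=1e-8)

    def test_reconstruction_matches_explicit(self, rng):
        eeg = EEGRecord(rng.standard_normal((3, 60)), 64.0)
        spec = small_spec(4)
        solver = TrialSolver(eeg, spec, 1.0, standardize=False)
        d = solver.fit(rng.standard_normal(60))
        lm = build_lag_matrix(eeg, spec)
        assert np.allclose(solver.reconstruct(d), reconstruct_envelope(d, lm).samples, atol=1e-10)


def make_forward_trials(n_trials, duration_s=10.0, n_channels=6, snr=np.inf, seed=0):
    """Trials whose EEG is exactly kernel (x) target envelope (+ noise)."""
    rng_master = np.random.SeedSequence(seed)
    trf = ForwardTRF.speech_like(n_channels, seed=rng_master.spawn(1)[0])
    trials = []
    for i, ss in enumerate(rng_master.spawn(n_trials)):
        s_env, s_envm, s_noise = ss.spawn(3)
        env = gen_stream(duration_s, s_env)
        env_m = gen_stream(duration_s, s_envm)
        clean = np.stack([np.convolve(env, k)[: env.size] for k in trf.kernels])
        if np.isinf(snr):
            data = clean
        else:
            noise_std = np.sqrt(np.mean(clean**2) / snr)
            data = clean + noise_std * np.random.default_rng(s_noise).standard_normal(clean.shape)
        trials.append(
            TrialRecord(
                eeg=EEGRecord(data, 64.0),
                envelope_target=Envelope(env, trial_id=f"t{i}"),
                envelope_masker=Envelope(env_m, trial_id=f"t{i}"),
                trial_id=f"t{i}",
            )
        )
    return trials


class TestLeaveOneOut:
    def test_two_identical_trials_give_equal_scores(self, rng):
        trials = make_forward_trials(1, snr=5.0, seed=3) * 2
        res = loo_reconstruction_accuracy(trials, spec=small_spec(8))
        assert res[0].r == res[1].r

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            loo_reconstruction_accuracy(make_forward_trials(1))

    def test_noiseless_forward_model_recovers_envelope(self):
        trials = make_forward_trials(6, snr=np.inf, seed=11)
        res = loo_reconstruction_accuracy(trials)
        assert np.mean([x.r for x in res]) >= 0.9

    def test_mean_accuracy_nonincreasing_in_noise(self):
        # one-sided trend over 3 noise levels x 20 seeds
        snrs = [10.0, 0.1, 0.005]
        slopes = []
        for seed in range(20):
            means = []
            for snr in snrs:
                trials = make_forward_trials(4, duration_s=8.0, snr=snr, seed=100 + seed)
                res = loo_reconstruction_accuracy(trials, spec=small_spec(16))
                means.append(np.mean([x.r for x in res]))
            slopes.append(np.polyfit([0, 1, 2], means, 1)[0])
        t_res = stats.ttest_1samp(slopes, 0.0, alternative="less")
        assert t_res.pvalue < 0.05


class TestModelObjects:
    def test_fit_returns_results_with_summary(self):
        trials = make_forward_trials(4, duration_s=8.0, snr=1.0, seed=5)
        model = StimulusReconstruction(trials, train_on="target")
        res = model.fit()
        assert len(res.results) == 4
        assert -1 <= res.mean_r <= 1
        assert res.mean_z == pytest.approx(np.mean(np.arctanh(res.r)))
        text = res.summary()
        assert "ridge lambda" in text and "mean r" in text
        frame = res.to_frame()
        assert list(frame.columns) == ["trial_id", "condition", "decoder_kind", "r", "z"]

    def test_training_on_inferred_requires_inferred_envelopes(self):
        trials = make_forward_trials(3, duration_s=8.0, seed=6)
        with pytest.raises(ValueError, match="inferred"):
            StimulusReconstruction(trials, train_on="inferred").fit()

    def test_padded_envelope_grid(self):
        spec = LagSpec()
        padded = pad_envelope(np.ones(768), spec)
        assert padded.size == 768 + 57
        assert np.all(padded[:57] == 0.0)
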