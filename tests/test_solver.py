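import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import lsq_linear

from conftest import make_test_signal
from lpfsc import (
    LPFSCConfig,
    RFFrame,
    lpfsc_cost,
    lpfsc_denoise,
    lpfsc_denoise_frame,
    soft_threshold,
    tv_prox,
)
from lpfsc.filters import apply_highpass, design_highpass
from lpfsc.solver import optimality_residual


def tv_prox_oracle(y, lam):
    """Independent oracle: solve the dual box-constrained least squares
    min ||D^T z - y||^2 s.t. |z| <= lam, then s = y - D^T z."""
    n = len(y)
    if n == 1 or lam == 0:
        return np.asarray(y, float).copy()
    D = np.diff(np.eye(n), axis=0)
    res = lsq_linear(D.T, y, bounds=(-lam, lam), method="bvls", tol=1e-14)
    return y - D.T @ res.x


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,t,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
    )
    def test_scalar_examples(self, v, t, expected):
        assert soft_threshold(np.array([v]), t)[0] == expected

    @settings(max_examples=50, derandomize=True)
    @given(hnp.arrays(np.float64, 16, elements=st.floats(-10, 10)))
    def test_zero_threshold_is_identity_and_shrinkage_bounded(self, v):
        assert np.array_equal(soft_threshold(v, 0.0), v)
        out = soft_threshold(v, 0.7)
        assert np.all(np.abs(out) <= np.abs(v) + 1e-12)
        assert np.all(np.abs(v) - np.abs(out) <= 0.7 + 1e-12)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


class TestTVProx:
    def test_lam_zero_no_smoothing(self):
        y = np.random.default_rng(0).standard_normal(50)
        assert np.array_equal(tv_prox(y, 0.0), y)

    def test_large_lam_gives_constant_mean(self):
        y = np.array([1.0, 5.0, 2.0, 8.0])
        assert np.allclose(tv_prox(y, 100.0), y.mean(), atol=1e-12)

    def test_two_point_closed_form(self):
        assert np.allclose(tv_prox(np.array([0.0, 4.0]), 1.0), [1.0, 3.0])
        # lam beyond half the gap clamps to the midpoint
        assert np.allclose(tv_prox(np.array([0.0, 4.0]), 5.0), [2.0, 2.0])

    def test_matches_dual_oracle_on_random_signals(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(1, 40))
            y = rng.normal(0, 2, n)
            lam = float(rng.uniform(0, 3))
            assert np.allclose(tv_prox(y, lam), tv_prox_oracle(y, lam), atol=1e-8)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tv_prox(np.array([1.0, np.nan]), 1.0)
        with pytest.raises(ValueError):
            tv_prox(np.ones(3), -1.0)


class TestCost:
    cfg = LPFSCConfig()

    def test_zero_everything_is_zero(self):
        assert lpfsc_cost(np.zeros(64), np.zeros(64), self.cfg) == 0.0

    def test_zero_sparse_leaves_filter_term(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(128)
        hp = apply_highpass(design_highpass(self.cfg.fc, self.cfg.d), x)
        assert lpfsc_cost(x, np.zeros(128), self.cfg) == pytest.approx(
            0.5 * np.sum(hp**2), rel=1e-12
        )

    def test_matches_term_by_term_recomputation(self):
        rng = np.random.default_rng(3)
        x, u = rng.standard_normal((2, 16))
        filt = design_highpass(self.cfg.fc, self.cfg.d)
        expected = (
            0.5 * np.sum(apply_highpass(filt, x - u) ** 2)
            + self.cfg.lam0 * np.sum(np.abs(u))
            + self.cfg.lam1 * np.sum(np.abs(np.diff(u)))
        )
        assert lpfsc_cost(x, u, self.cfg) == pytest.approx(expected, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lpfsc_cost(np.zeros(8), np.zeros(9), self.cfg)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lam0=0.0, lam1=0.0),
            dict(rho=0.0),
            dict(tol=0.0),
            dict(max_iter=0),
            dict(over_relax=2.0),
            dict(fc=0.7),
            dict(normalize="bogus"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LPFSCConfig(**kwargs)

    def test_json_roundtrip(self):
        cfg = LPFSCConfig(fc=0.15, lam0=0.9, normalize="peak")
        assert LPFSCConfig.from_json(cfg.to_json()) == cfg


class TestDenoise:
    def test_zero_input_is_fixed_point(self):
        res = lpfsc_denoise(np.zeros(100))
        assert np.all(res.denoised == 0) and np.all(res.s_sparse == 0)
        assert res.converged

    def test_decomposition_identity_and_monotone_trace(self):
        _, x = make_test_signal(5)
        res = lpfsc_denoise(x, LPFSCConfig())
        assert np.array_equal(res.denoised, res.s_sparse + res.s_low)
        assert np.all(np.diff(res.cost_trace) <= 1e-8 * np.abs(res.cost_trace[:-1]))

    def test_solver_beats_randomized_candidates(self):
        cfg = LPFSCConfig(tol=1e-9, max_iter=2000, normalize="none")
        rng = np.random.default_rng(7)
        for seed in range(10):
            _, x = make_test_signal(seed, n=64)
            res = lpfsc_denoise(x, cfg)
            c_star = lpfsc_cost(x, res.s_sparse, cfg)
            for _ in range(20):
                cand = res.s_sparse + rng.normal(0, 0.05, 64)
                assert lpfsc_cost(x, cand, cfg) >= c_star - 1e-9
            # coordinate polish: perturbing single coordinates cannot improve
            for i in rng.integers(0, 64, 10):
                for dlt in (0.01, -0.01):
                    cand = res.s_sparse.copy()
                    cand[i] += dlt
                    assert lpfsc_cost(x, cand, cfg) >= c_star - 1e-9

    def test_first_order_optimality(self):
        cfg = LPFSCConfig(tol=1e-10, max_iter=3000)
        _, x = make_test_signal(11, n=64)
        res = lpfsc_denoise(x, cfg)
        assert optimality_residual(x, res, cfg) <= 1e-6

    def test_warm_start_fixed_point(self):
        cfg = LPFSCConfig(tol=1e-8, max_iter=1000)
        _, x = make_test_signal(2)
        res = lpfsc_denoise(x, cfg)
        res2 = lpfsc_denoise(x, cfg, u0=res.s_sparse)
        assert np.max(np.abs(res2.s_sparse - res.s_sparse)) <= cfg.tol

    def test_deterministic(self):
        _, x = make_test_signal(3)
        a = lpfsc_denoise(x)
        b = lpfsc_denoise(x)
        assert np.array_equal(a.denoised, b.denoised)
        assert np.array_equal(a.cost_trace, b.cost_trace)

    def test_denoising_improves_rmse_on_generative_model(self):
        wins = 0
        for seed in range(50):
            clean, x = make_test_signal(seed, snr_db=0.0)
            den = lpfsc_denoise(x).denoised
            if np.mean((den - clean) ** 2) < np.mean((x - clean) ** 2):
                wins += 1
        assert wins >= 49

    def test_lambda_sensitivity_bounded(self):
        clean, x = make_test_signal(99)
        rmses = []
        for lam in (0.8, 0.9, 1.0, 1.1, 1.2):
            den = lpfsc_denoise(x, LPFSCConfig(lam0=lam, lam1=lam)).denoised
            rmses.append(np.sqrt(np.mean((den - clean) ** 2)))
        assert (max(rmses) - min(rmses)) / min(rmses) < 0.25


class TestDenoiseFrame:
    def test_zero_frame(self):
        frame = RFFrame(data=np.zeros((64, 4)), fs=1e8)
        out = lpfsc_denoise_frame(frame)
        assert np.all(out.data == 0)

    def test_channel_permutation_commutes(self):
        rng = np.random.default_rng(4)
        frame = RFFrame(data=rng.standard_normal((128, 5)), fs=1e8)
        perm = np.array([3, 1, 4, 0, 2])
        direct = lpfsc_denoise_frame(frame.with_data(frame.data[:, perm]))
        permuted = lpfsc_denoise_frame(frame).data[:, perm]
        assert np.allclose(direct.data, permuted, atol=0)

    def test_scale_equivariance_under_normalization(self):
        rng = np.random.default_rng(5)
        frame = RFFrame(data=rng.standard_normal((128, 3)), fs=1e8)
        doubled = frame.with_data(frame.data * 2.0)
        out1 = lpfsc_denoise_frame(frame)
        out2 = lpfsc_denoise_frame(doubled)
        assert np.allclose(out2.data, 2.0 * out1.data, rtol=1e-10, atol=1e-12)
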