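import numpy as np
import pytest

from grasemap.fitting import (
    MultiEchoStack,
    fit_map,
    fit_pixel_lsq,
    fit_pixel_mle,
)
from grasemap.noise import NoiseModel, log_likelihood, sample_magnitude

from .oracles import grid_search_mle

TE_6EC = np.array([23.6, 35.4, 47.2, 59.0, 70.8, 82.6])


class TestPixelLSQ:
    def test_two_point_closed_form(self):
        te = np.array([23.6, 82.6])
        m = np.array([100.0, 100.0 * np.exp(-59.0 / 52.0)])
        for mode in ("log", "nonlinear"):
            s0, t2 = fit_pixel_lsq(m, te, mode=mode)
            assert t2 == pytest.approx(52.0, abs=1e-6)

    def test_modes_agree_on_noiseless_data(self):
        m = 80.0 * np.exp(-TE_6EC / 47.0)
        _, t2_log = fit_pixel_lsq(m, TE_6EC, mode="log")
        _, t2_nl = fit_pixel_lsq(m, TE_6EC, mode="nonlinear")
        assert abs(t2_log - t2_nl) < 0.01

    def test_log_mode_rejects_nonpositive(self):
        m = np.array([10.0, 5.0, 0.0, 1.0, 0.5, 0.2])
        with pytest.raises(ValueError):
            fit_pixel_lsq(m, TE_6EC, mode="log")


class TestPixelMLE:
    def test_noiseless_recovery(self):
        m = 100.0 * np.exp(-TE_6EC / 52.0)
        s0, t2, ok = fit_pixel_mle(m, TE_6EC, NoiseModel(1e-6, 1))
        assert ok
        assert t2 == pytest.approx(52.0, abs=0.01)
        assert s0 == pytest.approx(100.0, abs=0.01)

    def test_all_zero_series_flagged_not_raised(self):
        s0, t2, ok = fit_pixel_mle(np.zeros(6), TE_6EC, NoiseModel(1.0, 1))
        assert not ok and t2 == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        nm = NoiseModel(5.0, 1)
        rng = np.random.default_rng(seed)
        m = sample_magnitude(100.0 * np.exp(-TE_6EC / 52.0), nm, rng)
        s0, t2, ok = fit_pixel_mle(m, TE_6EC, nm)
        s0_g, t2_g = grid_search_mle(m, TE_6EC, nm)
        assert ok
        assert abs(t2 - t2_g) <= 0.25 + 1e-9
        assert abs(s0 - s0_g) <= 0.25 + 1e-9

    def test_never_degrades_loglinear_initializer(self):
        nm = NoiseModel(4.0, 1)
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = sample_magnitude(80.0 * np.exp(-TE_6EC / 60.0), nm, rng)
            s0, t2, _ = fit_pixel_mle(m, TE_6EC, nm)
            floor = nm.sigma / 2.0
            y = np.log(np.maximum(m, floor))
            slope, icpt = np.polyfit(TE_6EC, y, 1)
            t2_init = np.clip(-1.0 / slope if slope < 0 else 1000.0, 1.0, 1000.0)
            s0_init = np.exp(icpt)
            assert log_likelihood(m, TE_6EC, s0, t2, nm) >= log_likelihood(
                m, TE_6EC, min(s0_init, 2 * m.max()), t2_init, nm
            ) - 1e-9


class TestBiasProperties:
    def test_mle_bias_below_2pct_at_moderate_snr(self):
        # first-echo SNR >= 20, T2 = 52 ms, 500 replicates per condition
        truth = 100.0 * np.exp(-TE_6EC / 52.0)
        rng = np.random.default_rng(42)
        for L in (1, 8):
            for snr in (20.0, 50.0):
                nm = NoiseModel(truth[0] / snr, L)
                fits = [
                    fit_pixel_mle(sample_magnitude(truth, nm, rng), TE_6EC, nm)[1]
                    for _ in range(500)
                ]
                bias = abs(np.mean(fits) - 52.0) / 52.0
                assert bias < 0.02, f"L={L}, SNR={snr}: bias {bias:.3%}"

    def test_mle_less_biased_than_log_lsq_at_low_snr(self):
        # paired comparison on identical noise draws; the Rician floor
        # inflates the log-linear fit, which ML corrects
        truth = 100.0 * np.exp(-TE_6EC / 52.0)
        nm = NoiseModel(5.0, 1)  # S0/sigma = 20
        rng = np.random.default_rng(7)
        mle, lsq = [], []
        for _ in range(500):
            m = sample_magnitude(truth, nm, rng)
            mle.append(fit_pixel_mle(m, TE_6EC, nm)[1])
            lsq.append(fit_pixel_lsq(m, TE_6EC, mode="log")[1])
        assert abs(np.mean(mle) - 52.0) < abs(np.mean(lsq) - 52.0)
        assert np.mean(lsq) > np.mean(mle)  # noise floor biases LSQ upward


class TestFitMap:
    def test_uniform_noiseless_stack(self):
        vols = np.tile((100.0 * np.exp(-TE_6EC / 52.0))[:, None, None], (1, 4, 5))
        stack = MultiEchoStack(vols, TE_6EC, noise=NoiseModel(1e-6, 1))
        res = fit_map(stack, method="mle")
        assert res.t2_map == pytest.approx(np.full((4, 5), 52.0), abs=0.01)
        assert res.converged_mask.all()

    def test_masked_fit_touches_only_mask(self):
        vols = np.tile((50.0 * np.exp(-TE_6EC / 60.0))[:, None, None], (1, 4, 4))
        stack = MultiEchoStack(vols, TE_6EC, noise=NoiseModel(0.5, 1))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 3] = True
        res = fit_map(stack, mask=mask, method="mle")
        assert res.converged_mask.sum() == 2
        assert np.all(res.t2_map[~mask] == 0.0)

    def test_shape_mismatch_rejected(self):
        vols = np.ones((6, 4, 4))
        stack = MultiEchoStack(vols, TE_6EC)
        with pytest.raises(ValueError):
            fit_map(stack, mask=np.ones((3, 3), dtype=bool), method="lsq_nonlinear")

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        vols = sample_magnitude(
            np.tile((100.0 * np.exp(-TE_6EC / 52.0))[:, None, None], (1, 3, 3)),
            NoiseModel(3.0, 1),
            rng,
        )
        stack = MultiEchoStack(vols, TE_6EC, noise=NoiseModel(3.0, 1))
        a = fit_map(stack, method="mle")
        b = fit_map(stack, method="mle")
        assert np.array_equal(a.t2_map, b.t2_map)

    def test_metadata_recorded(self):
        vols = np.tile((10.0 * np.exp(-TE_6EC / 40.0))[:, None, None], (1, 2, 2))
        stack = MultiEchoStack(vols, TE_6EC, noise=NoiseModel(0.1, 4))
        res = fit_map(stack, method="mle")
        assert res.meta["sigma"] == 0.1
        assert res.meta["n_channels"] == 4
        assert res.method == "mle"
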