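import numpy as np
import pytest

from thetamark import var_theory
from thetamark.connectivity import (fit_mvar, gc_pipeline, ms_coherence,
                                    permutation_gc_test, spectral_gc,
                                    time_reverse_control)
from thetamark.synthetic import SimConfig, gen_coupled_recording


def _simulate_var(A, n, seed, sigma_sd=(1.0, 1.0)):
    """Independent oracle-side VAR simulator: plain time loop, no scaling."""
    rng = np.random.default_rng(seed)
    p = A.shape[0]
    x = np.zeros((n + 500, 2))
    e = rng.standard_normal((n + 500, 2)) * np.asarray(sigma_sd)
    for t in range(p, n + 500):
        for k in range(p):
            x[t] += A[k] @ x[t - 1 - k]
        x[t] += e[t]
    return x[500:, 0], x[500:, 1]


@pytest.fixture(scope="module")
def known_var2():
    cfg = SimConfig(seed=0)
    A, sigma = cfg.var_coefficients()
    return A, sigma, cfg.fs


class TestCoherence:
    def test_self_coherence_is_100(self, rng):
        x = rng.standard_normal(500 * 30)
        c = ms_coherence(x, x, 500.0)
        assert np.all(c.msc > 99.999)

    def test_independent_noise_small_sample_bias(self, rng):
        # K Welch blocks per epoch -> mean MSC approximately 100/K %
        x = rng.standard_normal(500 * 120)
        y = rng.standard_normal(500 * 120)
        c = ms_coherence(x, y, 500.0)
        K = (5000 - 256) // 256
        assert float(c.msc.mean()) == pytest.approx(100.0 / K, rel=0.15)

    def test_pure_delay_keeps_coherence(self, rng):
        x = rng.standard_normal(500 * 60)
        y = np.roll(x, 10)          # 20 ms delay
        c = ms_coherence(x, y, 500.0)
        assert c.band_summary["theta"] > 95.0

    def test_rescaling_invariance(self, rng):
        x = rng.standard_normal(500 * 30)
        y = rng.standard_normal(500 * 30) + 0.5 * x
        c1 = ms_coherence(x, y, 500.0)
        c2 = ms_coherence(3.0 * x, 0.2 * y, 500.0)
        assert np.allclose(c1.msc, c2.msc, atol=1e-8)

    def test_needs_one_full_epoch(self, rng):
        with pytest.raises(ValueError, match="epoch"):
            ms_coherence(rng.standard_normal(100), rng.standard_normal(100),
                         500.0)


class TestFitMVAR:
    def test_recovers_known_coefficients(self, known_var2):
        A, sigma, fs = known_var2
        x, y = _simulate_var(A, int(300 * fs), seed=7)
        model = fit_mvar(x, y, fs, max_order=6)
        assert model.order == 2
        assert np.max(np.abs(model.A - A)) < 0.05
        assert model.stable

    def test_white_noise_gives_small_order_and_cross_terms(self):
        orders, crosses = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(500 * 20)
            y = rng.standard_normal(500 * 20)
            m = fit_mvar(x, y, 500.0, max_order=6)
            orders.append(m.order)
            crosses.append(np.max(np.abs(m.A[:, 0, 1])))
        assert np.median(orders) <= 2
        assert np.median(crosses) < 0.02

    def test_order_recovery_rate(self, known_var2):
        A, sigma, fs = known_var2
        hits = 0
        for s in range(10):
            x, y = _simulate_var(A, int(60 * fs), seed=100 + s)
            hits += fit_mvar(x, y, fs, max_order=5).order == 2
        assert hits >= 9


class TestSpectralGC:
    def test_zero_coupling_gives_zero_gc(self):
        cfg = SimConfig(seed=3, coupling_direction="none", noise_sd=0.0,
                        duration=120.0)
        rec = gen_coupled_recording(cfg)
        gc = gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), cfg.fs,
                         max_order=4)
        assert gc.theta_fwd < 0.05
        assert gc.theta_rev < 0.05

    def test_matches_closed_form_of_generating_model(self, pure_var_recording):
        rec, cfg = pure_var_recording
        A, sigma = cfg.var_coefficients()
        gc = gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), cfg.fs,
                         max_order=6)
        theory = var_theory.spectral_gc_from_coeffs(A, sigma, gc.freqs, cfg.fs)
        m = (gc.freqs >= 4) & (gc.freqs < 8)
        assert gc.theta_fwd == pytest.approx(theory["0->1"][m].sum(), rel=0.05)
        # peak within one bin of the 6 Hz oscillator's spectral peak
        peak_est = gc.freqs[np.argmax(gc.gc_fwd)]
        peak_thr = gc.freqs[np.argmax(theory["0->1"])]
        assert abs(peak_est - peak_thr) <= gc.freqs[1] - gc.freqs[0]
        assert gc.theta_fwd > gc.theta_rev

    def test_spectral_integral_matches_time_domain(self, pure_var_recording):
        # Geweke decomposition: the spectrum integrates to the time-domain GC
        rec, cfg = pure_var_recording
        A, sigma = cfg.var_coefficients()
        F_true = var_theory.time_domain_gc(A, sigma, "0->1", ar_order=500)
        gc = gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), cfg.fs,
                         max_order=6)
        est = 2 / cfg.fs * np.trapezoid(gc.gc_fwd, gc.freqs)
        assert est == pytest.approx(F_true, rel=0.02)

    def test_channel_rescaling_invariance(self, pure_var_recording):
        rec, cfg = pure_var_recording
        x, y = rec.channel("PFC"), rec.channel("BNST")
        g1 = gc_pipeline(x, y, cfg.fs, max_order=4)
        g2 = gc_pipeline(5.0 * x, 0.1 * y, cfg.fs, max_order=4)
        assert g1.theta_fwd == pytest.approx(g2.theta_fwd, rel=1e-6)
        assert g1.theta_rev == pytest.approx(g2.theta_rev, abs=1e-9)

    def test_nonnegative_everywhere(self, pure_var_recording):
        rec, cfg = pure_var_recording
        gc = gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), cfg.fs,
                         max_order=6)
        assert np.all(gc.gc_fwd >= 0)
        assert np.all(gc.gc_rev >= 0)


class TestPermutation:
    def test_strong_coupling_significant(self):
        cfg = SimConfig(seed=5, duration=60.0)
        rec = gen_coupled_recording(cfg)
        gc = permutation_gc_test(rec.channel("PFC"), rec.channel("BNST"),
                                 cfg.fs, n_perm=199, seed=0, max_order=8)
        assert gc.p_fwd <= 0.01

    def test_independent_signals_not_significant(self):
        cfg = SimConfig(seed=6, coupling_direction="none", duration=60.0)
        rec = gen_coupled_recording(cfg)
        gc = permutation_gc_test(rec.channel("PFC"), rec.channel("BNST"),
                                 cfg.fs, n_perm=199, seed=0, max_order=8)
        assert gc.p_fwd > 0.05

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError, match="100"):
            permutation_gc_test(rng.standard_normal(5000),
                                rng.standard_normal(5000), 500.0, n_perm=10)


class TestTimeReversal:
    def test_direction_flips(self):
        cfg = SimConfig(seed=7, duration=60.0)
        rec = gen_coupled_recording(cfg)
        fwd = gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), cfg.fs,
                          max_order=12)
        rev = time_reverse_control(rec.channel("PFC"), rec.channel("BNST"),
                                   cfg.fs, max_order=12)
        assert fwd.theta_fwd > fwd.theta_rev
        assert rev.theta_rev > rev.theta_fwd

    def test_double_reversal_is_identity(self):
        cfg = SimConfig(seed=8, duration=30.0)
        rec = gen_coupled_recording(cfg)
        x, y = rec.channel("PFC"), rec.channel("BNST")
        once = gc_pipeline(x[::-1], y[::-1], cfg.fs, max_order=6)
        twice = gc_pipeline(x[::-1][::-1], y[::-1][::-1], cfg.fs, max_order=6)
        direct = gc_pipeline(x, y, cfg.fs, max_order=6)
        assert twice.theta_fwd == pytest.approx(direct.theta_fwd, rel=1e-12)
        assert once.theta_fwd != pytest.approx(direct.theta_fwd, rel=1e-3)
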