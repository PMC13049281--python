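"""Forward model: direction-averaged kurtosis, exchange kernel and functional."""

import numpy as np
import pytest

import ogsekit as ok
from ogsekit.karger import (
    ExchangeKernel,
    compute_h,
    compute_kvar_bar,
    compute_q4,
    predict_mk,
    regime_decomposition,
)

GM = dict(f_ic=0.43, alpha_d=1.70, alpha_c=10.22)


def mc_kvar(f_ic, alpha_d, alpha_c, v_omega, n=1_000_000, seed=7):
    """Monte-Carlo direction average: the independent oracle for Kvar_bar."""
    xi = np.random.default_rng(seed).uniform(0.0, 1.0, n)
    a = alpha_d + alpha_c * v_omega
    integrand = 3 * f_ic * (1 - f_ic) / (a * xi**2 / (1 - xi**2) + (1 - f_ic)) ** 2
    return integrand.mean()


class TestKvarBar:
    def test_vanishes_for_pure_compartments(self):
        assert compute_kvar_bar(0.0, 2.0, 5.0, 0.3) == 0.0
        assert compute_kvar_bar(1.0, 2.0, 5.0, 0.3) == 0.0

    def test_bounded_by_perpendicular_closed_form(self):
        """The xi = 0 integrand value 3 f/(1-f) bounds the direction average."""
        bound = 3 * 0.43 / (1 - 0.43)
        assert bound == pytest.approx(2.263, abs=1e-3)
        for v in (0.1, 0.3, 0.8):
            kv = compute_kvar_bar(0.43, 1.7, 10.22, v)
            assert 0 < kv < bound

    def test_matches_monte_carlo_direction_average(self, protocol):
        """64-node Gauss-Legendre equals a 10^6-sample Monte-Carlo average
        within 0.1% at the gray-matter medians."""
        for s in protocol:
            gl = compute_kvar_bar(GM["f_ic"], GM["alpha_d"], GM["alpha_c"], s.v_omega)
            mc = mc_kvar(GM["f_ic"], GM["alpha_d"], GM["alpha_c"], s.v_omega)
            assert gl == pytest.approx(mc, rel=1e-3)

    def test_strictly_decreasing_in_dispersion_factor(self):
        v = np.linspace(0.1, 1.0, 20)
        kv = compute_kvar_bar(0.43, 1.7, 10.22, v)
        assert np.all(np.diff(kv) < 0)

    def test_out_of_range_parameters_raise(self):
        with pytest.raises(ValueError):
            compute_kvar_bar(1.2, 2.0, 5.0, 0.3)
        with pytest.raises(ValueError):
            compute_kvar_bar(0.5, 0.5, 5.0, 0.3)
        with pytest.raises(ValueError):
            compute_kvar_bar(0.5, 2.0, 5.0, -0.1)


class TestExchangeKernel:
    def test_normalization_identity(self, protocol):
        """2 * integral q4 = 1 holds within 1e-4 for every protocol waveform."""
        for s in protocol:
            k = compute_q4(s)
            assert 2 * np.trapezoid(k.q4, k.lags) == pytest.approx(1.0, abs=1e-4)
            assert np.all(k.q4 >= 0)

    def test_against_direct_double_loop(self):
        """The fast autocorrelation equals the direct O(n^2) summation."""
        s = ok.compute_spectrum(
            ok.build_waveform(ok.WaveformSpec(40.0, 1, 12.0, raster=0.1))
        )
        k = compute_q4(s)
        q2 = s.q_of_t**2
        dt = 0.1
        b = q2.sum() * dt
        direct = np.array(
            [np.dot(q2[: len(q2) - i], q2[i:]) * dt / b**2 for i in range(len(q2))]
        )
        assert k.q4 == pytest.approx(direct, abs=1e-12 * direct.max())

    def test_two_burst_toy_concentrates_mass_at_separation(self):
        """q supported on two disjoint bursts puts q4 mass near lag 0 and near
        the burst separation, and nowhere else."""
        dt = 0.01
        t = np.arange(0, 60, dt)
        q = np.zeros_like(t)
        q[(t >= 0) & (t < 5)] = 1.0
        q[(t >= 40) & (t < 45)] = 1.0
        b = (q**2).sum() * dt
        from scipy.signal import fftconvolve

        acorr = fftconvolve(q**2, (q**2)[::-1], mode="full")[len(q) - 1:] * dt / b**2
        lags = np.arange(len(acorr)) * dt
        near_zero = acorr[lags < 6].sum() * dt
        near_sep = acorr[(lags > 34) & (lags < 46)].sum() * dt
        elsewhere = acorr[(lags >= 6) & (lags <= 34)].sum() * dt
        # hand-computed: each triangle carries mass 1/4 (positive lags)
        assert near_zero == pytest.approx(0.25, abs=1e-3)
        assert near_sep == pytest.approx(0.25, abs=1e-3)
        assert elsewhere < 1e-12


class TestExchangeFunctional:
    def test_limits(self, protocol):
        k = compute_q4(protocol["30Hz-N1"])
        assert compute_h(k, 1e9) == pytest.approx(1.0, abs=1e-4)
        assert compute_h(k, 1e-3) == pytest.approx(0.0, abs=1e-3)
        with pytest.raises(ValueError):
            compute_h(k, 0.0)

    def test_in_unit_interval_and_increasing_in_tex(self, protocol):
        for s in protocol:
            k = compute_q4(s)
            hs = [compute_h(k, tex) for tex in (1, 5, 14, 50, 141, 200)]
            assert np.all(np.diff(hs) > 0)
            assert all(0 < h <= 1 for h in hs)

    @pytest.mark.parametrize("t_ex", [5.0, 13.76, 50.0, 141.0])
    def test_against_brute_force_double_integral(self, protocol, t_ex):
        """h from the autocorrelation shortcut equals direct double
        integration of exp(-t/tex) q^2(u) q^2(u+t) within 1e-6."""
        for s in protocol:
            dt = s.waveform.spec.raster
            q2 = s.q_of_t**2
            b = q2.sum() * dt
            n = len(q2)
            acorr = np.array([np.dot(q2[: n - i], q2[i:]) for i in range(n)]) * dt / b**2
            lags = np.arange(n) * dt
            h_direct = 2 * np.trapezoid(np.exp(-lags / t_ex) * acorr, lags)
            h_fast = compute_h(compute_q4(s), t_ex)
            assert h_fast == pytest.approx(h_direct, abs=1e-6)


class TestPrediction:
    def test_components_combine_exactly(self, protocol, gm_median):
        pred = predict_mk(protocol, gm_median)
        assert pred.mk == pytest.approx(pred.kvar_bar * pred.h + gm_median.k_inf)
        assert np.all(pred.mk >= gm_median.k_inf)
        assert np.all((pred.h > 0) & (pred.h <= 1))

    def test_no_exchange_limit_reduces_to_kvar_plus_offset(self, protocol, gm_median):
        slow = gm_median.replace(t_ex=200.0)
        pred = predict_mk(protocol, slow)
        # h close to its no-exchange ceiling; MK dominated by Kvar + K_inf
        assert np.all(pred.mk <= pred.kvar_bar + slow.k_inf + 1e-12)

    def test_gm_kurtosis_increases_across_fixed_n_series(self, protocol, gm_median):
        """At the gray-matter medians, predicted MK rises with frequency over
        the four one-oscillation waveforms."""
        pred = predict_mk(protocol, gm_median).as_dict()
        series = [pred[l] for l in ("30Hz-N1", "40Hz-N1", "50Hz-N1", "60Hz-N1")]
        assert np.all(np.diff(series) > 0)

    def test_kurtosis_decreases_across_fixed_t_series(self, protocol, gm_median, wm_median):
        """Both tissue classes show decreasing MK over the fixed-duration
        series (structural disorder dominates)."""
        for params in (gm_median, wm_median):
            pred = predict_mk(protocol, params).as_dict()
            series = [pred[l] for l in ("30Hz-N1", "65Hz-N2", "90Hz-N3")]
            assert np.all(np.diff(series) < 0)

    def test_empty_protocol_raises(self, gm_median):
        import ogsekit.protocol as prot

        empty = prot.Protocol(spectra=(), b_target=2.0)
        with pytest.raises(ValueError):
            predict_mk(empty, gm_median)


class TestRegimeDecomposition:
    def test_kvar_decreases_and_h_increases_fixed_n(self, gm_median):
        df = regime_decomposition(gm_median, "fixed_N",
                                  frequencies=np.arange(23.0, 90.0, 3.0))
        assert np.all(np.diff(df.kvar_bar) < 0)
        # h rises except at the single documented mixing-time clip discontinuity
        steps = np.diff(df.h)
        assert (steps <= 0).sum() <= 1
        assert df.h.iloc[-1] > df.h.iloc[0]

    def test_fixed_t_h_flat_relative_to_fixed_n(self, gm_median):
        df_t = regime_decomposition(gm_median, "fixed_T")
        df_n = regime_decomposition(gm_median, "fixed_N",
                                    frequencies=np.arange(23.0, 53.0, 3.0))
        tv_t = df_t.h.max() - df_t.h.min()
        tv_n = df_n.h.max() - df_n.h.min()
        assert tv_t < 0.5 * tv_n
        assert np.all(np.diff(df_t.kvar_bar) < 0)
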