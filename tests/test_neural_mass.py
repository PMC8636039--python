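import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mebci import neural_mass as nm


class TestSigmoid:
    def test_midpoint_equals_e0(self):
        assert nm.sigmoid(6.0) == pytest.approx(2.5)

    def test_saturation(self):
        assert nm.sigmoid(1e4) == pytest.approx(5.0)
        assert nm.sigmoid(-1e4) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero(self):
        # 5 / (1 + e^{0.56*6}) evaluated independently
        expected = 5.0 / (1.0 + np.exp(3.36))
        assert nm.sigmoid(0.0) == pytest.approx(expected, rel=1e-12)
        assert nm.sigmoid(0.0) == pytest.approx(0.1678, abs=5e-4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            nm.sigmoid(np.nan)
        with pytest.raises(ValueError):
            nm.sigmoid(np.inf)

    @given(st.floats(-500, 500))
    def test_bounded_and_increasing(self, v):
        s = nm.sigmoid(v)
        assert 0.0 <= s <= 5.0
        assert nm.sigmoid(v + 1e-3) >= s

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            nm.SigmoidParams(e0=-1.0)
        with pytest.raises(ValueError):
            nm.SigmoidParams(r=0.0)


class TestDerivatives:
    def test_zero_state_no_input_line1(self):
        pp = nm.BAND_PARAMS["low"]
        d = nm.nmm_derivatives(nm.NMMState(), pp, p=0.0)
        expected = pp.A * pp.a * nm.sigmoid(0.0)  # 2.7*40*0.1678 ~ 18.12
        assert d.dy0 == pytest.approx(expected, rel=1e-12)
        assert d.dy0 == pytest.approx(18.12, abs=0.02)

    def test_zero_state_with_input_line2(self):
        pp = nm.BAND_PARAMS["low"]
        d = nm.nmm_derivatives(nm.NMMState(), pp, p=60.0)
        expected = pp.A * pp.a * (nm.sigmoid(0.0) + 60.0 / 108.0)
        assert d.dy1 == pytest.approx(expected, rel=1e-12)
        assert d.dy1 == pytest.approx(78.1, abs=0.2)

    def test_velocity_passthrough(self):
        s = nm.NMMState(dy0=1.0, dy1=-2.0, dy2=0.5, dy3=3.0)
        d = nm.nmm_derivatives(s, nm.BAND_PARAMS["low"])
        assert (d.y0, d.y1, d.y2, d.y3) == (1.0, -2.0, 0.5, 3.0)

    def test_zero_gains_pure_decay(self):
        tiny = 1e-300  # gains must be > 0; use a value that zeroes the drive
        pp = nm.PopulationParams("low", tiny, tiny, tiny, 40.0, 20.0, 300.0)
        s = nm.NMMState(y0=1.0, y1=1.0, y2=1.0, y3=1.0,
                        dy0=0.1, dy1=0.1, dy2=0.1, dy3=0.1)
        d = nm.nmm_derivatives(s, pp, p=0.0)
        assert d.dy0 == pytest.approx(-2 * 40 * 0.1 - 40**2 * 1.0)
        assert d.dy2 == pytest.approx(-2 * 20 * 0.1 - 20**2 * 1.0)
        assert d.dy3 == pytest.approx(-2 * 300 * 0.1 - 300**2 * 1.0)

    def test_nested_variant_differs_only_in_fast_line(self):
        s = nm.NMMState(y0=0.2, y2=0.3)
        pp = nm.BAND_PARAMS["high"]
        d_state = nm.nmm_derivatives(s, pp, fast_inhibition="state")
        d_nested = nm.nmm_derivatives(s, pp, fast_inhibition="nested")
        assert d_state.dy0 == d_nested.dy0
        assert d_state.dy2 == d_nested.dy2
        assert d_state.dy3 != d_nested.dy3

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            nm.nmm_derivatives(nm.NMMState(), nm.BAND_PARAMS["low"],
                               fast_inhibition="bogus")


class TestExogenousNoise:
    def test_moments(self):
        spec = nm.ExogenousInputSpec(mean=60, variance=100, seed=3, n=100_000)
        x = nm.exogenous_noise(spec)
        assert abs(x.mean() - 60.0) < 0.3
        assert abs(x.var() - 100.0) < 3.0

    def test_zero_variance(self):
        spec = nm.ExogenousInputSpec(mean=60, variance=0, seed=0, n=100)
        assert np.all(nm.exogenous_noise(spec) == 60.0)

    def test_seed_determinism(self):
        spec = nm.ExogenousInputSpec(seed=11, n=1000)
        assert np.array_equal(nm.exogenous_noise(spec), nm.exogenous_noise(spec))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            nm.ExogenousInputSpec(variance=-1)
        with pytest.raises(ValueError):
            nm.ExogenousInputSpec(n=0)
        with pytest.raises(ValueError):
            nm.ExogenousInputSpec(dt=0)


class TestIntegration:
    def test_bounded_oscillation(self):
        spec = nm.ExogenousInputSpec(mean=60, variance=0, seed=0)
        v = nm.integrate_population(nm.BAND_PARAMS["high"], input_spec=spec,
                                    t_total=4.0, burn_in=1.0)
        assert np.all(np.abs(v) < 1e3)
        assert np.all(np.isfinite(v))

    def test_rk4_order(self):
        # noise-free Richardson on the trajectory sup-norm:
        # error(dt) / error(dt/2) ~ 16 for dt = 1 ms
        pp = nm.BAND_PARAMS["low"]
        state0 = nm.NMMState(y0=0.05, y1=0.4, y2=0.2, y3=0.01)
        t_total, base = 0.3, 6.25e-5

        def run(dt):
            spec = nm.ExogenousInputSpec(mean=60, variance=0, seed=0, dt=dt)
            return nm.integrate_population(
                pp, input_spec=spec, t_total=t_total, burn_in=0.0, state0=state0
            )

        ref = run(base)
        errs = {}
        for dt in (1e-3, 5e-4):
            k = int(round(dt / base))
            errs[dt] = np.max(np.abs(run(dt) - ref[k - 1:: k]))
        ratio = errs[1e-3] / errs[5e-4]
        assert 16 * 0.8 < ratio < 16 * 1.2

    def test_seed_determinism(self):
        spec = nm.ExogenousInputSpec(mean=60, variance=100, seed=21)
        a = nm.integrate_population(nm.BAND_PARAMS["medium"], input_spec=spec,
                                    t_total=3.0, burn_in=0.5)
        b = nm.integrate_population(nm.BAND_PARAMS["medium"], input_spec=spec,
                                    t_total=3.0, burn_in=0.5)
        assert np.array_equal(a, b)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            nm.integrate_population(nm.BAND_PARAMS["low"], t_total=1.0,
                                    burn_in=2.0)

    def test_divergence_reported(self):
        pp = nm.PopulationParams("low", A=1e9, B=3.2, G=27, a=40, b=20, g=300)
        spec = nm.ExogenousInputSpec(mean=60, variance=0, seed=0)
        with pytest.raises(nm.DivergenceError):
            nm.integrate_population(pp, input_spec=spec, t_total=3.0,
                                    burn_in=0.0, state0=nm.NMMState(y0=1e5))

    def test_batch_matches_single(self):
        pp = nm.BAND_PARAMS["low"]
        noise = nm.exogenous_noise(nm.ExogenousInputSpec(seed=5, n=1500))
        single = nm.integrate_populations_batch(
            [pp], noise[None, :], 1e-3,
            state0=nm.equilibrium_state(pp).as_array()[None, :],
        )[0]
        batch = nm.integrate_populations_batch(
            [pp, pp], np.stack([noise, noise]), 1e-3,
            state0=np.stack([nm.equilibrium_state(pp).as_array()] * 2),
        )
        assert np.allclose(single, batch[0])
        assert np.allclose(batch[0], batch[1])


class TestBandPeaks:
    @pytest.mark.parametrize("band,f_lo,f_hi", [
        ("low", 4.0, 12.0),
        ("medium", 12.0, 30.0),
        ("high", 30.0, 100.0),
    ])
    def test_dominant_peak_in_band(self, band, f_lo, f_hi):
        spec = nm.ExogenousInputSpec(mean=60, variance=100, seed=2)
        v = nm.integrate_population(nm.BAND_PARAMS[band], input_spec=spec,
                                    t_total=12.0, burn_in=2.0)
        peak = nm.dominant_frequency(v, 1000.0, 1.0, 100.0)
        assert f_lo <= peak <= f_hi

    def test_peak_shifts_with_g(self):
        # high-band oscillation frequency moves monotonically over a
        # 3-point G grid (noise-free limit cycle, zero-crossing estimate)
        peaks = []
        for gval in (60.0, 75.0, 90.0):
            base = nm.BAND_PARAMS["high"]
            pp = nm.PopulationParams("high", base.A, base.B, gval, base.a,
                                     base.b, base.g)
            st = nm.equilibrium_state(pp)
            st = nm.NMMState(st.y0 * 1.001, st.y1, st.y2, st.y3)
            spec = nm.ExogenousInputSpec(mean=60, variance=0, seed=0)
            v = nm.integrate_population(pp, input_spec=spec, t_total=6.0,
                                        burn_in=2.0, state0=st)
            t = v - v.mean()
            zc = np.where((t[:-1] < 0) & (t[1:] >= 0))[0]
            peaks.append(1000.0 * (len(zc) - 1) / (zc[-1] - zc[0]))
        assert peaks[0] < peaks[1] < peaks[2]


class TestMixing:
    def test_identity_weight(self):
        x = [np.arange(10.0), np.ones(10), np.zeros(10)]
        w = nm.PopulationWeights(1.0, 0.0, 0.0)
        assert np.array_equal(nm.mix_populations(x, w), x[0])

    def test_reference_weights_accepted(self):
        w = nm.REFERENCE_WEIGHTS["mRB"]
        assert (w.w_low, w.w_medium, w.w_high) == (0.1190, 0.3332, 0.5478)

    def test_linearity(self, rng):
        x = [rng.standard_normal(50) for _ in range(3)]
        w1 = nm.PopulationWeights(0.1, 0.2, 0.3)
        w2 = nm.PopulationWeights(0.2, 0.4, 0.6)
        assert np.allclose(2 * nm.mix_populations(x, w1),
                           nm.mix_populations(x, w2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nm.mix_populations(
                [np.zeros(5), np.zeros(6), np.zeros(5)],
                nm.PopulationWeights(1, 1, 1),
            )

    def test_weight_invariants(self):
        with pytest.raises(ValueError):
            nm.PopulationWeights(-0.1, 0.5, 0.5)
        with pytest.raises(ValueError):
            nm.PopulationWeights(0.0, 0.0, 0.0)


class TestBandWeights:
    def test_pure_sinusoid(self):
        fs = 1000.0
        t = np.arange(0, 8.0, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        w = nm.band_weights_from_reference(x, fs)
        assert w.w_low > 0.9
        assert w.w_medium < 0.05
        assert w.w_high < 0.05

    def test_white_noise_bandwidth_fractions(self):
        fs = 1000.0
        x = np.random.default_rng(0).standard_normal((4, 16000, 3))
        w = nm.band_weights_from_reference(x, fs)
        expect = np.array([8.0, 18.0, 25.0]) / 51.0
        got = w.as_array()
        assert np.allclose(got, expect, atol=0.03)

    def test_empty_band_after_nyquist_clip(self):
        fs = 50.0  # Nyquist 25 Hz kills the high band (30-55)
        x = np.random.default_rng(0).standard_normal(2000)
        with pytest.raises(ValueError):
            nm.band_weights_from_reference(x, fs)

    def test_empty_reference(self):
        with pytest.raises(ValueError):
            nm.band_weights_from_reference(np.empty(0), 1000.0)

    def test_report_formatting_matches_4_decimals(self):
        w = nm.REFERENCE_WEIGHTS["mRB"]
        assert f"{w.w_low:.4f}" == "0.1190"


class TestEquilibrium:
    def test_high_band_selects_active_branch(self):
        st = nm.equilibrium_state(nm.BAND_PARAMS["high"])
        v = 108.0 * st.y1 - 33.75 * st.y2 - 108.0 * st.y3
        assert v > 5.0  # the quiet equilibrium sits near 0.8

    def test_is_fixed_point(self):
        st = nm.equilibrium_state(nm.BAND_PARAMS["low"])
        d = nm.nmm_derivatives(st, nm.BAND_PARAMS["low"], p=60.0)
        assert abs(d.dy0) < 1e-6 and abs(d.dy1) < 1e-6
        assert abs(d.dy2) < 1e-6 and abs(d.dy3) < 1e-6
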