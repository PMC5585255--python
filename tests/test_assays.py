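import numpy as np
import pytest

from trpgate.assays import (
    CalciumTrace,
    GapFreeRecording,
    MSTTrace,
    RampRecording,
    TitrationCurve,
    build_titration_curve,
    calcium_response_auc,
    estimate_npo,
    fit_binding_isotherm,
    mass_action_bound_fraction,
    normalize_thermophoresis,
    ramp_current_density,
)
from trpgate.errors import ConfigurationError, WindowingError
from trpgate.synthetic import AssaySimConfig, simulate_mst_titration, simulate_mst_traces


def flat_trace(cold=100.0, hot=80.0, conc=1.0, replicate=0):
    t = np.arange(0.0, 45.0, 0.1)
    f = np.where(t < 5.0, cold, np.where(t < 35.0, hot, cold))
    return MSTTrace(t, f, ir_on_s=5.0, ir_off_s=35.0, concentration_uM=conc,
                    replicate=replicate)


class TestNormalize:
    def test_hot_over_cold_ratio(self):
        assert normalize_thermophoresis(flat_trace(100, 80)) == pytest.approx(0.8)

    def test_flat_trace_is_unity(self):
        assert normalize_thermophoresis(flat_trace(100, 100)) == pytest.approx(1.0)

    def test_swapped_windows_rejected(self):
        tr = flat_trace()
        with pytest.raises(WindowingError):
            normalize_thermophoresis(tr, cold_window=(30, 35), hot_window=(0, 5))

    def test_zero_cold_mean_rejected(self):
        tr = flat_trace(cold=0.0, hot=10.0)
        with pytest.raises(WindowingError):
            normalize_thermophoresis(tr)


class TestTitrationCurve:
    def test_differencing_against_lowest_concentration(self):
        traces = [flat_trace(100, 100, conc=0.1), flat_trace(100, 95, conc=1.0),
                  flat_trace(100, 90, conc=10.0), flat_trace(100, 85, conc=100.0)]
        curve = build_titration_curve(traces)
        np.testing.assert_allclose(curve.delta_fnorm, [0.0, -0.05, -0.10, -0.15],
                                   atol=1e-12)

    def test_identical_traces_give_zero_curve(self):
        traces = [flat_trace(100, 90, conc=c) for c in (0.1, 1, 10, 100)]
        curve = build_titration_curve(traces)
        np.testing.assert_allclose(curve.delta_fnorm, 0.0, atol=1e-12)

    def test_duplicate_concentration_same_replicate_rejected(self):
        traces = [flat_trace(conc=1.0), flat_trace(conc=1.0)]
        with pytest.raises(ConfigurationError):
            build_titration_curve(traces)

    def test_trace_pipeline_matches_direct_titration(self):
        cfg = AssaySimConfig(kd_uM=12.8, noise_frac=0.0)
        direct = simulate_mst_titration(cfg)
        from_traces = build_titration_curve(simulate_mst_traces(cfg))
        # ΔF_norm from traces is referenced to the lowest concentration;
        # the direct curve to zero ligand — they differ by fb(c_min) ≈ 0.2%
        np.testing.assert_allclose(
            from_traces.delta_fnorm, direct.delta_fnorm, atol=2e-4 * abs(cfg.amplitude) / 0.03
        )


class TestBindingFit:
    def test_noiseless_hyperbola_recovers_kd(self):
        conc = np.geomspace(0.027, 225, 16)
        y = 1.0 * conc / (10.0 + conc)
        curve = TitrationCurve(conc, y, np.zeros(16, int))
        fit = fit_binding_isotherm(curve, model="hyperbola")
        assert fit.identifiable
        assert fit.kd_uM == pytest.approx(10.0, abs=0.01)

    def test_noiseless_mass_action_recovers_kd(self):
        cfg = AssaySimConfig(kd_uM=10.0, noise_frac=0.0)
        fit = fit_binding_isotherm(simulate_mst_titration(cfg))
        assert fit.kd_uM == pytest.approx(10.0, abs=0.1)

    def test_flat_response_flagged_unidentifiable(self):
        conc = np.geomspace(0.027, 225, 16)
        curve = TitrationCurve(conc, np.zeros(16), np.zeros(16, int))
        fit = fit_binding_isotherm(curve)
        assert not fit.identifiable
        assert fit.kd_uM is None

    def test_noisy_flat_response_flagged(self):
        rng = np.random.default_rng(0)
        conc = np.geomspace(0.027, 225, 16)
        curve = TitrationCurve(conc, rng.normal(0, 1e-3, 16), np.zeros(16, int))
        fit = fit_binding_isotherm(curve)
        assert not fit.identifiable
        assert fit.kd_uM is None

    def test_mass_action_and_hyperbola_agree_when_protein_is_trace(self):
        """At 20 nM protein and Kd ≈ 13 µM (protein ≪ Kd), ligand depletion
        is negligible and the two models differ by < 1%."""
        cfg = AssaySimConfig(kd_uM=12.8, noise_frac=0.0)
        curve = simulate_mst_titration(cfg)
        kd_ma = fit_binding_isotherm(curve, "mass_action").kd_uM
        kd_hy = fit_binding_isotherm(curve, "hyperbola").kd_uM
        assert abs(kd_ma - kd_hy) / kd_ma < 0.01

    def test_bound_fraction_half_saturation(self):
        fb = mass_action_bound_fraction(np.array([10.0]), 10.0, 0.00002)
        assert fb[0] == pytest.approx(0.5, rel=1e-3)

    def test_bound_fraction_saturates(self):
        fb = mass_action_bound_fraction(np.array([1e7]), 10.0, 0.02)
        assert fb[0] == pytest.approx(1.0, rel=1e-5)


class TestCalciumAuc:
    def _trace(self, time, ratio, stim=(10.0, 40.0)):
        return CalciumTrace(np.asarray(time, float), np.asarray(ratio, float), stim)

    def test_baseline_only_is_zero(self):
        t = np.arange(0, 60, 0.1)
        assert calcium_response_auc(self._trace(t, np.ones_like(t))) == pytest.approx(0.0)

    def test_rectangle(self):
        t = np.arange(0.0, 120.0, 0.5)
        r = np.ones_like(t)
        r[(t >= 30.0) & (t <= 90.0)] += 1.0
        auc = calcium_response_auc(self._trace(t, r, stim=(30.0, 90.0)))
        assert auc == pytest.approx(60.0, abs=0.5)  # trapezoid edges half-count

    def test_triangle_matches_fine_trapezoid_oracle(self):
        t = np.arange(0.0, 40.0, 0.001)
        r = np.ones_like(t)
        rise = (t >= 10.0) & (t <= 15.0)
        fall = (t > 15.0) & (t <= 20.0)
        r[rise] += (t[rise] - 10.0) / 5.0
        r[fall] += (20.0 - t[fall]) / 5.0
        auc = calcium_response_auc(self._trace(t, r, stim=(10.0, 20.0)))
        assert auc == pytest.approx(5.0, abs=1e-6)

    def test_auc_is_linear_in_amplitude(self):
        t = np.arange(0.0, 40.0, 0.01)
        r = np.ones_like(t)
        resp = (t >= 10.0) & (t <= 20.0)
        r[resp] += np.sin(np.pi * (t[resp] - 10.0) / 10.0)
        base = calcium_response_auc(self._trace(t, r, stim=(10.0, 20.0)))
        scaled = calcium_response_auc(self._trace(t, 1 + 3 * (r - 1), stim=(10.0, 20.0)))
        assert scaled == pytest.approx(3 * base, rel=1e-9)

    def test_overlapping_windows_rejected(self):
        t = np.arange(0, 60, 0.1)
        with pytest.raises(WindowingError):
            calcium_response_auc(
                self._trace(t, np.ones_like(t)),
                baseline_window=(0, 20), response_window=(10, 40),
            )


class TestRampDensity:
    def test_linear_ramp(self):
        v = np.linspace(-100, 100, 401)
        rec = RampRecording(v, 2.0 * v, capacitance_pF=20.0)
        assert ramp_current_density(rec, 100.0) == pytest.approx(10.0)

    def test_flat_zero_current(self):
        v = np.linspace(-100, 100, 401)
        rec = RampRecording(v, np.zeros_like(v), 15.0)
        assert ramp_current_density(rec) == 0.0

    def test_interpolation_off_grid(self):
        v = np.linspace(-100, 99.0, 200)  # +100 not on the grid... clamp to +99
        rec = RampRecording(v, 3.0 * v, 10.0)
        assert ramp_current_density(rec, 98.5) == pytest.approx(3.0 * 98.5 / 10.0)

    def test_bad_capacitance_rejected(self):
        v = np.linspace(-100, 100, 11)
        with pytest.raises(ConfigurationError):
            ramp_current_density(RampRecording(v, v, 0.0))

    def test_voltage_outside_span_rejected(self):
        v = np.linspace(-100, 100, 11)
        with pytest.raises(ConfigurationError):
            ramp_current_density(RampRecording(v, v, 10.0), at_voltage_mV=150.0)


class TestNpo:
    def _rec(self, levels, i_single=6.0):
        levels = np.asarray(levels, dtype=float)
        return GapFreeRecording(np.arange(levels.size) / 1000.0,
                                levels * i_single, i_single)

    def test_half_open_single_channel(self):
        levels = np.zeros(1000)
        levels[::2] = 1
        assert estimate_npo(self._rec(levels)) == pytest.approx(0.5)

    def test_always_closed(self):
        assert estimate_npo(self._rec(np.zeros(1000))) == 0.0

    def test_three_level_weighted_sum(self):
        levels = np.concatenate([np.zeros(250), np.ones(500), np.full(250, 2.0)])
        assert estimate_npo(self._rec(levels)) == pytest.approx(1.0)

    def test_additivity_of_superposed_recordings(self):
        rng = np.random.default_rng(5)
        a = (rng.random(4000) < 0.25).astype(float)
        b = (rng.random(4000) < 0.40).astype(float)
        npo_a = estimate_npo(self._rec(a))
        npo_b = estimate_npo(self._rec(b))
        npo_ab = estimate_npo(self._rec(a + b))
        assert npo_ab == pytest.approx(npo_a + npo_b, abs=1e-9)

    def test_nonzero_offset_baseline_is_subtracted(self):
        levels = np.zeros(2000)
        levels[:500] = 1
        rec = GapFreeRecording(np.arange(2000) / 1000.0,
                               levels * 6.0 + 3.7, 6.0)  # holding offset
        assert estimate_npo(rec) == pytest.approx(0.25)
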