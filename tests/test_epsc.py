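import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from grinsyn.epsc import (
    CompensationSpec,
    ConductanceTrace,
    EPSCMeasures,
    Sweep,
    average_sweeps,
    blank_stimulus_artifact,
    correct_series_resistance,
    fit_decay,
    measure_epsc,
    read_sweep_csv,
    response_ratio,
    rs_comp_fraction,
    split_ampa_nmda,
    to_conductance,
    write_sweep_csv,
)
from grinsyn.sim.synapse import biexp_conductance, biexp_integral
from grinsyn.synth import forward_rs_distort

FS = 25000.0


def make_sweep(samples, v_hold=-100.0, rs=10.0, t0=0.02, cm=100.0):
    return Sweep(np.asarray(samples, dtype=float), fs=FS, t0_stim=t0,
                 v_hold=v_hold, rs=rs, cm=cm)


# ---------------------------------------------------------------------------
# series-resistance compensation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rs, expected", [(3.0, 0.0), (2.0, 0.0), (12.0, 75.0)])
def test_compensation_fraction_formula(rs, expected):
    assert rs_comp_fraction(rs) == pytest.approx(expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
def test_compensation_fraction_monotone_and_clamped(rs1, rs2):
    lo, hi = sorted([rs1, rs2])
    assert rs_comp_fraction(lo) <= rs_comp_fraction(hi)
    assert rs_comp_fraction(min(lo, 3.0)) >= 0.0


def test_zero_fraction_correction_is_identity():
    sw = make_sweep(np.sin(np.arange(1000) / 40.0) * 50.0, rs=3.0)
    out = correct_series_resistance(sw, CompensationSpec(rs_final=3.0))
    assert np.array_equal(out.samples, sw.samples)


def test_dc_driving_force_correction():
    # steady state: 200 pA at 20 mV driving force with 10 MOhm compensated
    # -> 200 * 20/18 = 222.2 pA
    sw = make_sweep(np.full(2000, 200.0), v_hold=20.0, rs=13.0, t0=0.04)
    out = correct_series_resistance(sw, CompensationSpec(rs_final=3.0))
    assert out.samples[1000] == pytest.approx(200.0 * 20.0 / 18.0, rel=1e-9)


def test_unphysical_compensation_detected():
    # current so large its voltage error exceeds the driving force
    sw = make_sweep(np.full(500, 5000.0), v_hold=20.0, rs=13.0, t0=0.01)
    with pytest.raises(ValueError, match="unphysical"):
        correct_series_resistance(sw, CompensationSpec(rs_final=3.0))


def test_distort_correct_round_trip_recovers_waveform():
    t_ms = np.arange(int(0.5 * FS)) / FS * 1e3
    ideal = biexp_conductance(t_ms - 20.0, 1.5, 3.0, 80.0) * 20.0  # pA at +20
    sw = make_sweep(ideal, v_hold=20.0, rs=12.0)
    dist = forward_rs_distort(sw, 12.0, 100.0, 20.0)
    # full correction (fraction -> 1)
    corr = correct_series_resistance(dist, CompensationSpec(rs_final=1e-9))
    m0 = measure_epsc(ConductanceTrace(ideal / 20.0, fs=FS, t0_stim=0.02), polarity="+")
    m1 = measure_epsc(ConductanceTrace(corr.samples / 20.0, fs=FS, t0_stim=0.02), polarity="+")
    assert m1.peak == pytest.approx(m0.peak, rel=0.02)
    assert m1.tau_w == pytest.approx(m0.tau_w, rel=0.03)


# ---------------------------------------------------------------------------
# artifact blanking
# ---------------------------------------------------------------------------

class TestBlanking:
    def test_flat_trace_unchanged(self):
        sw = make_sweep(np.full(2000, -5.0))
        out = blank_stimulus_artifact(sw)
        assert np.allclose(out.samples, -5.0)

    def test_spike_on_flat_baseline_removed(self):
        y = np.zeros(2000)
        i0 = int(0.02 * FS)
        y[i0:i0 + 10] = 300.0
        out = blank_stimulus_artifact(make_sweep(y))
        assert np.allclose(out.samples, 0.0)

    def test_linear_ramp_preserved(self):
        y = np.linspace(0.0, 10.0, 2000)
        out = blank_stimulus_artifact(make_sweep(y))
        assert np.allclose(out.samples, y, atol=1e-9)

    def test_window_outside_sweep_rejected(self):
        sw = make_sweep(np.zeros(100), t0=0.002)
        with pytest.raises(ValueError):
            blank_stimulus_artifact(sw, window=(0.002, 1.0))

    def test_charge_invariant_when_artifact_carries_no_net_charge(self):
        t_ms = np.arange(int(0.4 * FS)) / FS * 1e3
        g = biexp_conductance(t_ms - 20.0, 1.0, 3.0, 80.0) * 20.0
        i0 = int(0.02 * FS)
        art = np.zeros_like(g)
        art[i0:i0 + 10] = 500.0
        art[i0 + 10:i0 + 20] = -500.0  # zero net planted charge
        blanked = blank_stimulus_artifact(make_sweep(g + art, v_hold=20.0))
        q_clean = np.trapezoid(g[i0:], dx=1e3 / FS)
        q_blanked = np.trapezoid(blanked.samples[i0:], dx=1e3 / FS)
        assert q_blanked == pytest.approx(q_clean, rel=0.02)


# ---------------------------------------------------------------------------
# conductance conversion and component separation
# ---------------------------------------------------------------------------

class TestSeparation:
    def test_ohms_law_conversion(self):
        assert to_conductance(make_sweep([-100.0], v_hold=-100.0)).samples[0] == 1.0
        assert to_conductance(make_sweep([20.0], v_hold=20.0)).samples[0] == 1.0
        assert to_conductance(make_sweep([0.0], v_hold=-60.0)).samples[0] == 0.0

    def test_conversion_near_reversal_rejected(self):
        with pytest.raises(ValueError):
            to_conductance(make_sweep([5.0], v_hold=3.0))

    def test_ohm_forward_model_round_trip_is_identity(self, rng):
        g = np.abs(rng.normal(size=500))
        for v in (-100.0, -40.0, 20.0):
            sw = make_sweep(g * v, v_hold=v)
            back = to_conductance(sw)
            assert np.allclose(back.samples, g, atol=1e-14)

    def test_identical_traces_give_zero_nmda(self):
        g = ConductanceTrace(np.ones(100), fs=FS)
        ampa, nmda = split_ampa_nmda(g, ConductanceTrace(np.ones(100), fs=FS))
        assert np.allclose(nmda.samples, 0.0)
        assert np.allclose(ampa.samples, 1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            split_ampa_nmda(ConductanceTrace(np.ones(100), fs=FS),
                            ConductanceTrace(np.ones(99), fs=FS))

    def test_noiseless_mixed_sweeps_recover_components_pointwise(self):
        t_ms = np.arange(int(0.5 * FS)) / FS * 1e3
        ga = biexp_conductance(t_ms - 20.0, 2.0, 0.3, 3.0)
        gn = biexp_conductance(t_ms - 20.0, 1.5, 3.0, 80.0)
        g_m100 = ConductanceTrace(ga, fs=FS, t0_stim=0.02, source_v_hold=-100.0)
        g_p20 = ConductanceTrace(ga + gn, fs=FS, t0_stim=0.02, source_v_hold=20.0)
        ampa, nmda = split_ampa_nmda(g_m100, g_p20)
        assert np.max(np.abs(ampa.samples - ga)) < 1e-9
        assert np.max(np.abs(nmda.samples - gn)) < 1e-9


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

class TestAveraging:
    def test_single_sweep_is_baseline_zeroed(self):
        sw = make_sweep(np.full(2000, 7.0))
        out = average_sweeps([sw])
        assert np.allclose(out.samples, 0.0)

    def test_sweep_plus_negation_cancels(self):
        y = np.sin(np.arange(2000) / 50.0)
        out = average_sweeps([make_sweep(y), make_sweep(-y)])
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_mixed_holding_potentials_rejected(self):
        with pytest.raises(ValueError):
            average_sweeps([make_sweep(np.zeros(100), v_hold=-100.0),
                            make_sweep(np.zeros(100), v_hold=20.0)])

    def test_noise_shrinks_like_sqrt_n(self, rng):
        template = np.zeros(4000)
        def rms(n):
            sweeps = [make_sweep(template + rng.normal(0, 5.0, 4000))
                      for _ in range(n)]
            return np.sqrt(np.mean(average_sweeps(sweeps).samples ** 2))
        r4, r64 = rms(4), rms(64)
        assert r64 < r4 / 2.5  # expect ~1/4

# ---------------------------------------------------------------------------
# decay fitting and measures
# ---------------------------------------------------------------------------

class TestDecayFit:
    def test_pure_single_exponential_falls_back_and_recovers_tau(self):
        t = np.arange(int(1.0 * FS)) / FS * 1e3
        m = fit_decay(np.exp(-t / 80.0), FS)
        assert m.fit_kind == "single"
        assert m.tau_w == pytest.approx(80.0, rel=0.01)

    def test_equal_mixture_weighted_tau(self):
        t = np.arange(int(1.0 * FS)) / FS * 1e3
        y = 0.5 * np.exp(-t / 10.0) + 0.5 * np.exp(-t / 90.0)
        m = fit_decay(y, FS)
        assert m.fit_kind == "double"
        assert m.tau1 < m.tau2
        assert m.tau_w == pytest.approx(50.0, abs=0.05)
        assert m.tau_w == pytest.approx(
            (m.a1 * m.tau1 + m.a2 * m.tau2) / (m.a1 + m.a2))

    def test_noisy_mixture_median_recovery(self):
        t = np.arange(int(1.0 * FS)) / FS * 1e3
        y = 0.5 * np.exp(-t / 10.0) + 0.5 * np.exp(-t / 90.0)
        taus = []
        for seed in range(50):
            noise = np.random.default_rng(seed).normal(0, 1.0 / 20.0, y.size)
            taus.append(fit_decay(y + noise, FS).tau_w)
        assert np.median(taus) == pytest.approx(50.0, rel=0.05)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(np.ones(30), FS)


class TestMeasures:
    def test_rectangular_pulse_charge(self):
        y = np.zeros(int(0.3 * FS))
        i0 = int(0.02 * FS)
        d_ms = 10.0
        y[i0:i0 + int(d_ms * FS / 1e3)] = 3.0
        m = measure_epsc(ConductanceTrace(y, fs=FS, t0_stim=0.02), fit=False)
        assert m.charge == pytest.approx(3.0 * d_ms, rel=0.01)

    def test_biexponential_charge_matches_closed_form(self):
        t_ms = np.arange(int(1.0 * FS)) / FS * 1e3
        g = biexp_conductance(t_ms - 20.0, 1.0, 3.0, 80.0)
        m = measure_epsc(ConductanceTrace(g, fs=FS, t0_stim=0.02), fit=False)
        expected = biexp_integral(1.0, 3.0, 80.0)  # ~90.9 nS*ms
        assert expected == pytest.approx(90.9, abs=0.2)
        assert m.charge == pytest.approx(expected, rel=0.005)

    def test_linear_ramp_rise_time(self):
        y = np.zeros(int(0.2 * FS))
        i0 = int(0.02 * FS)
        n_ramp = int(1e-3 * FS)
        y[i0:i0 + n_ramp] = np.linspace(0, 1.0, n_ramp)
        y[i0 + n_ramp:] = 1.0
        m = measure_epsc(ConductanceTrace(y, fs=FS, t0_stim=0.02), fit=False)
        assert m.rise_20_80 == pytest.approx(0.6, abs=0.06)

    def test_low_peak_flagged_low_confidence(self, rng):
        y = rng.normal(0, 1.0, int(0.2 * FS))
        m = measure_epsc(ConductanceTrace(y, fs=FS, t0_stim=0.02), fit=False)
        assert m.low_confidence


class TestResponseRatio:
    def test_ratio_values(self):
        a = EPSCMeasures(peak=2.0)
        b = EPSCMeasures(peak=4.0)
        pct, ln = response_ratio(a, b, "peak")
        assert pct == pytest.approx(50.0)
        assert ln == pytest.approx(np.log(0.5))
        pct_eq, ln_eq = response_ratio(a, a, "peak")
        assert pct_eq == pytest.approx(100.0)
        assert ln_eq == pytest.approx(0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            response_ratio(EPSCMeasures(peak=1.0), EPSCMeasures(peak=0.0), "peak")


def test_sweep_csv_round_trip(tmp_path, rng):
    sw = make_sweep(rng.normal(size=200), v_hold=-60.0, rs=8.5)
    path = tmp_path / "sweep.csv"
    write_sweep_csv(sw, path)
    back = read_sweep_csv(path)
    assert back.v_hold == sw.v_hold
    assert back.rs == sw.rs
    assert back.fs == sw.fs
    assert np.allclose(back.samples, sw.samples, atol=1e-5)
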