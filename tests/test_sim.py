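import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from grinsyn.sim import (
    DEFAULT_CONFIG,
    StimProtocol,
    SynapseSpec,
    biexp_conductance,
    biexp_integral,
    biexp_peak_time,
    build_model,
    charge_matched_gmax,
    count_spikes,
    currentscape,
    mg_block_factor,
    place_synapses,
    run_experiment_grid,
    run_train,
    spine_summaries,
)

PASSIVE = {
    "channels": {
        "soma": {"na": 0, "kdr": 0, "ka": 0, "ih": 0, "car": 0, "kca": 0,
                 "leak": 0.00055},
        "apical": {"na": 0, "kdr": 0, "ka": 0, "ih": 0, "car": 0, "kca": 0,
                   "leak": 0.00055},
    },
    "spine": {"car": 0.0, "kca": 0.0},
}


@pytest.fixture(scope="module")
def model():
    return build_model(validate=False)


@pytest.fixture(scope="module")
def passive_model():
    return build_model(PASSIVE, validate=False)


# ---------------------------------------------------------------------------
# synaptic conductance waveform
# ---------------------------------------------------------------------------

class TestBiexp:
    def test_peak_normalization_and_zero_onset(self):
        tp = biexp_peak_time(3.0, 80.0)
        assert biexp_conductance(np.array([tp]), 1.0, 3.0, 80.0)[0] == pytest.approx(1.0)
        assert biexp_conductance(np.array([0.0, -5.0]), 1.0, 3.0, 80.0)[0] == 0.0
        assert biexp_conductance(np.array([-5.0]), 1.0, 3.0, 80.0)[0] == 0.0

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            biexp_conductance(np.array([1.0]), 1.0, 80.0, 3.0)

    def test_kinetic_scaling_preserves_charge_by_quadrature(self):
        q_wt, _ = quad(lambda t: biexp_conductance(t, 1.0, 3.0, 80.0), 0, 4000)
        q_k, _ = quad(lambda t: biexp_conductance(t, 0.5, 6.0, 160.0), 0, 4000)
        assert abs(q_k / q_wt - 1.0) < 1e-3
        assert q_wt == pytest.approx(biexp_integral(1.0, 3.0, 80.0), rel=1e-6)

    def test_charge_matched_peak_values(self):
        assert charge_matched_gmax(1.0, 1.0) == 1.0
        assert charge_matched_gmax(1.0, 2.0) == pytest.approx(0.5)
        assert charge_matched_gmax(1.0, 1.5) == pytest.approx(2.0 / 3.0)
        with pytest.raises(ValueError):
            charge_matched_gmax(1.0, 0.0)


class TestMgBlock:
    def test_no_magnesium_means_no_block(self):
        v = np.linspace(-100, 40, 20)
        assert np.allclose(mg_block_factor(v, mg=0.0), 1.0)

    def test_strictly_increasing_in_voltage(self):
        v = np.linspace(-110, 40, 200)
        b = mg_block_factor(v)
        assert np.all(np.diff(b) > 0)
        assert np.all((b >= 0) & (b <= 1))

    def test_value_at_minus_70(self):
        # 1/(1 + (1/3.57) e^{0.062*70}) = 0.0446
        assert mg_block_factor(-70.0) == pytest.approx(0.0446, abs=0.002)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

class TestModelConstruction:
    def test_rest_is_stable_fixed_point(self, model):
        res = run_train(model, StimProtocol(n_syn=0, n_stim=0, duration_ms=1000.0),
                        None, seed=0)
        assert np.max(np.abs(res.vm_soma - model.v_init)) < 0.01

    def test_passive_membrane_time_constant(self):
        # uniform leak g = 5.5e-4 S/cm2, cm = 1 uF/cm2 -> tau_m = C/g ~ 1.82 ms
        tau_expect = 1e-6 / 5.5e-4 * 1e3  # ms
        # drive a uniform step by displacing the leak reversal and compare
        # the relaxation time constant against the closed form
        proto = StimProtocol(n_syn=0, n_stim=0, duration_ms=20.0)
        m2 = build_model(PASSIVE, validate=False)
        m2.e_leak = m2.e_leak + 10.0
        res = run_train(m2, proto, None, seed=0)
        v = res.vm_soma - res.vm_soma[0]
        vss = v[-1]
        # time to reach 1 - 1/e of the step response
        i = np.argmax(v >= vss * (1 - np.exp(-1)))
        tau_meas = res.t_ms[i]
        assert tau_meas == pytest.approx(tau_expect, rel=0.05)

    def test_doubling_leak_halves_input_resistance(self):
        # isopotential limit: read steady-state depolarisation to a fixed
        # current injected via the leak-reversal displacement
        dv = {}
        for factor in (1.0, 2.0):
            cfg = {"channels": {
                "soma": dict(PASSIVE["channels"]["soma"], leak=0.00055 * factor),
                "apical": dict(PASSIVE["channels"]["apical"], leak=0.00055 * factor),
            }, "spine": PASSIVE["spine"]}
            m = build_model(cfg, validate=False)
            g_total = m.g_leak.sum()  # uS; uniform potential at rest
            dv[factor] = 1.0 / g_total  # MOhm-like input resistance proxy
        assert dv[1.0] / dv[2.0] == pytest.approx(2.0, rel=1e-9)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            build_model({"channels": {"soma": {"na": -0.1}}}, validate=False)


# ---------------------------------------------------------------------------
# synapse placement
# ---------------------------------------------------------------------------

class TestPlacement:
    def test_deterministic_per_seed(self, model):
        p1, i1 = place_synapses(model, 40, seed=3)
        p2, i2 = place_synapses(model, 40, seed=3)
        assert np.array_equal(p1, p2) and np.array_equal(i1, i2)

    def test_positions_within_cable(self, model):
        pos, idx = place_synapses(model, 1, seed=0)
        assert 0 <= pos[0] <= model.apical_length_um
        assert 1 <= idx[0] < model.n

    def test_uniform_distribution(self, model):
        pos, _ = place_synapses(model, 10_000, seed=1)
        stat = kstest(pos / model.apical_length_um, "uniform")
        assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class TestRunTrain:
    def test_zero_synapses_flat_no_spikes(self, model):
        res = run_train(model, StimProtocol(n_syn=0, duration_ms=100.0), None)
        s = spine_summaries(res)
        assert s["spikes"] == 0
        assert abs(s["soma_vm_integral_mVms"]) < 1.0

    def test_identical_seed_bit_identical(self, model):
        proto = StimProtocol(n_syn=10, freq_hz=80.0, tail_ms=50.0)
        a = run_train(model, proto, SynapseSpec(), seed=4)
        b = run_train(model, proto, SynapseSpec(), seed=4)
        assert np.array_equal(a.vm_soma, b.vm_soma)
        assert np.array_equal(a.ca_spine_mean, b.ca_spine_mean)

    def test_single_synapse_voltage_clamp_limit(self, passive_model):
        # passive cell, one synapse: the spine EPSC tracks the
        # driving-force-weighted biexponential (voltage excursion small)
        syn = SynapseSpec(ampa=type(SynapseSpec().ampa)(0.3, 3.0, 0.05),
                          nmda_wt=type(SynapseSpec().nmda_wt)(3.0, 80.0, 0.0001),
                          mg_mM=0.0)
        proto = StimProtocol(n_syn=1, n_stim=1, freq_hz=20.0, tail_ms=60.0)
        res = run_train(passive_model, proto, syn, seed=2)
        i_ampa = res.spine_currents["ampa"]  # nA
        t_rel = res.t_ms - proto.t_start_ms
        g = biexp_conductance(t_rel, 0.05e-3, 0.3, 3.0)  # uS
        expect = g * res.vm_spine_mean
        mask = g > 0.1 * g.max()
        err = np.abs(i_ampa[mask] - expect[mask]) / np.abs(expect[mask]).max()
        assert err.max() < 0.05

    def test_spine_head_charge_balance_passive(self, passive_model):
        # with channels blocked, synaptic charge into the head equals the
        # charge leaving through neck + leak (capacitive term returns to zero)
        syn = SynapseSpec(mg_mM=0.0)
        proto = StimProtocol(n_syn=1, n_stim=1, freq_hz=20.0, tail_ms=600.0)
        res = run_train(passive_model, proto, syn, seed=2)
        dt = res.t_ms[1] - res.t_ms[0]
        q = {k: np.trapezoid(v, dx=dt) for k, v in res.spine_currents.items()}
        q_in = q["nmda"] + q["ampa"]
        q_out = q["leak"] + q["neck"]
        assert q_in + q_out == pytest.approx(0.0, abs=0.02 * abs(q_in))

    def test_blow_up_reported_with_location(self):
        bad = build_model(validate=False)
        # corrupt one compartment: a negative total conductance makes the
        # linear system lose diagonal dominance and the solution diverge
        bad.g_leak[10] = -10.0 * abs(bad.g_leak).max()
        with pytest.raises(FloatingPointError, match="compartment"):
            run_train(bad, StimProtocol(n_syn=40, freq_hz=200.0),
                      SynapseSpec(), seed=0)


class TestSpikeCounting:
    def test_flat_trace(self):
        assert count_spikes(np.full(1000, -65.0), dt_ms=0.1) == 0

    def test_three_separated_spikes(self):
        v = np.full(3000, -65.0)
        for i in (100, 1100, 2100):
            v[i:i + 20] = 20.0
        assert count_spikes(v, dt_ms=0.1) == 3

    def test_sinusoid_crossings_with_2ms_spacing(self):
        t = np.arange(0, 10.0, 0.05)  # ms
        # start in the trough so every one of the 5 cycles crosses upward
        v = 10 * np.sin(2 * np.pi * t / 2.0 - np.pi / 2)
        assert count_spikes(v, t_ms=t) == 5

    def test_refractory_window_merges_fast_chatter(self):
        v = np.full(200, -65.0)
        v[50:52] = 10.0
        v[53:55] = 10.0  # 0.3 ms later: same spike
        assert count_spikes(v, dt_ms=0.1) == 1


class TestSummariesAndCurrentscape:
    def test_quiescent_integrals_zero(self, model):
        res = run_train(model, StimProtocol(n_syn=0, duration_ms=50.0), None)
        s = spine_summaries(res)
        assert s["spine_ca_integral_uMms"] == pytest.approx(0.0, abs=1e-6)
        assert s["spikes"] == 0

    def test_constant_depolarisation_integral(self, model):
        res = run_train(model, StimProtocol(n_syn=0, duration_ms=100.0), None)
        res.vm_soma = res.vm_soma + 10.0  # +10 mV for the whole 100 ms
        s = spine_summaries(res)
        assert s["soma_vm_integral_mVms"] == pytest.approx(1000.0, rel=0.01)

    def test_ca_integral_matches_trapezoid(self, model):
        res = run_train(model, StimProtocol(n_syn=5, freq_hz=80.0, tail_ms=100.0),
                        SynapseSpec(), seed=0)
        s = spine_summaries(res)
        dt = res.t_ms[1] - res.t_ms[0]
        manual = np.trapezoid(np.maximum(res.ca_spine_mean - res.ca_rest, 0), dx=dt)
        assert s["spine_ca_integral_uMms"] == pytest.approx(manual)

    def test_currentscape_shares_normalized(self, model):
        res = run_train(model, StimProtocol(n_syn=10, freq_hz=200.0, tail_ms=60.0),
                        SynapseSpec(), seed=1)
        cs = currentscape(res)
        tot_in = cs["inward"].sum(axis=0)
        tot_out = cs["outward"].sum(axis=0)
        active = cs["inward_total_nA"] > 0
        assert np.allclose(tot_in[active], 1.0)
        assert np.all((cs["inward"] >= 0) & (cs["inward"] <= 1.0 + 1e-12))
        assert np.all(tot_out[cs["outward_total_nA"] > 0] > 0.999)

    def test_nmda_share_grows_during_high_frequency_train(self, model):
        # depolarisation-dependent Mg unblock: the NMDA share of inward spine
        # current is larger late in a 200 Hz train than at its start
        res = run_train(model, StimProtocol(n_syn=40, freq_hz=200.0),
                        SynapseSpec(), seed=0)
        cs = currentscape(res)
        i_n = cs["names"].index("nmda")
        t = cs["t_ms"]
        early = (t > 10.0) & (t < 14.0)    # first interval
        late = (t > 30.0) & (t < 34.0)     # after 5th stimulus
        active = cs["inward_total_nA"] > 1e-6
        share_early = np.mean(cs["inward"][i_n][early & active])
        share_late = np.mean(cs["inward"][i_n][late & active])
        assert share_late > share_early


class TestExperimentGrid:
    def test_grid_shape_and_matched_seeds(self, model):
        df = run_experiment_grid(
            model, genotypes=(1.0, 2.0), n_syns=(5,), freqs=(80.0,),
            seeds=range(2), n_stim=2, tail_ms=30.0)
        assert len(df) == 2 * 1 * 1 * 2
        assert set(df["kinetic_scale"]) == {1.0, 2.0}

    def test_wt_row_duplicates_direct_run(self, model):
        proto = StimProtocol(n_syn=5, freq_hz=80.0, n_stim=2, tail_ms=30.0)
        direct = spine_summaries(run_train(model, proto, SynapseSpec(), seed=1))
        df = run_experiment_grid(
            model, genotypes=(1.0,), n_syns=(5,), freqs=(80.0,), seeds=[1],
            n_stim=2, tail_ms=30.0)
        row = df.iloc[0]
        for key, val in direct.items():
            assert row[key] == pytest.approx(val)
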