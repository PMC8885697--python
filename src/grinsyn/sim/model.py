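"""Reduced CA1-like compartmental neuron with two-compartment spines.

A soma plus a single tapered apical cable (~50 compartments) stands in for
the full CA1 pyramidal morphology.  Six Hodgkin-Huxley-style conductances
are distributed over the compartments: fast Na, delayed-rectifier K, A-type
K, h-current, high-voltage-activated R-type Ca, and a Ca-activated
medium-AHP K current.  Spines are a head compartment (with R-type Ca,
KCa, leak, and the synaptic conductances) joined to the dendrite by a
purely resistive neck; the head holds a single-compartment calcium pool
with fast endogenous buffering and first-order extrusion.

All internal units are (mV, ms, nF, uS, nA, uM); channel densities in the
configuration are in S/cm2 as is conventional.  Kinetic parameters are
taken as-is at the working temperature (35 C folded into the rate
constants rather than applied as explicit Q10 factors).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEFAULT_CONFIG", "NeuronModel", "build_model"]

FARADAY = 96485.33  # C/mol

DEFAULT_CONFIG = {
    "morphology": {
        "soma_L_um": 20.0,
        "soma_diam_um": 20.0,
        "apical_L_um": 400.0,
        "apical_diam_prox_um": 2.5,
        "apical_diam_dist_um": 0.5,
        "n_apical": 50,
        "ra_ohm_cm": 150.0,
        "cm_uF_cm2": 1.0,
    },
    # densities in S/cm2; calibrated once so that rest sits near -65 mV, a
    # single 40-synapse volley is subthreshold, and a 5-stimulus 200 Hz
    # WT train elicits somatic spiking (see docs/methods.md)
    "channels": {
        "soma": {"na": 0.07, "kdr": 0.035, "ka": 0.01, "ih": 0.0002,
                 "car": 0.0003, "kca": 0.0002, "leak": 0.00055},
        "apical": {"na": 0.0233, "kdr": 0.0117, "ka": 0.01, "ih": 0.0002,
                   "car": 0.0, "kca": 0.0, "leak": 0.00055},
        "ka_gradient": 2.0,   # A-type density multiplier at the distal tip
    },
    "spine": {
        "head_diam_um": 0.5,
        "neck_L_um": 1.0,
        "neck_diam_um": 0.1,
        "car": 0.02,
        "kca": 0.1,
        "leak": 0.00025,
        "ca_tau_ms": 15.0,
        "ca_buffer_ratio": 20.0,
        "ca_rest_uM": 0.05,
    },
    "soma_ca": {"shell_um": 0.1, "tau_ms": 60.0, "buffer_ratio": 20.0,
                "rest_uM": 0.05},
    "reversals": {"na": 50.0, "k": -90.0, "h": -30.0, "ca": 120.0},
    "kca_kd_uM": 0.8,
    "v_init": -65.0,
    "temp_C": 35.0,
}


# ---------------------------------------------------------------------------
# Channel kinetics (rates in /ms, potentials in mV)
# ---------------------------------------------------------------------------

def _vtrap(x, a):
    """x / (1 - exp(-x/a)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / a) < 1e-6
    with np.errstate(over="ignore"):
        out = np.where(small, a * (1.0 + x / (2.0 * a)),
                       x / (1.0 - np.exp(-np.where(small, 1.0, x) / a)))
    return out


def na_gates(v):
    am = 0.182 * _vtrap(v + 35.0, 9.0)
    bm = 0.124 * _vtrap(-(v + 35.0), 9.0)
    m_inf = am / (am + bm)
    tau_m = 1.0 / (am + bm)
    ah = 0.024 * _vtrap(v + 50.0, 5.0)
    bh = 0.0091 * _vtrap(-(v + 75.0), 5.0)
    tau_h = 1.0 / (ah + bh)
    h_inf = 1.0 / (1.0 + np.exp((v + 65.0) / 6.2))
    return m_inf, tau_m, h_inf, tau_h


def kdr_gates(v):
    an = 0.02 * _vtrap(v - 25.0, 9.0)
    bn = 0.002 * _vtrap(-(v - 25.0), 9.0)
    return an / (an + bn), 1.0 / (an + bn)


def ka_gates(v):
    a_inf = 1.0 / (1.0 + np.exp(-(v + 18.0) / 15.0))
    b_inf = 1.0 / (1.0 + np.exp((v + 66.0) / 7.0))
    return a_inf, np.full_like(np.asarray(v, float), 0.5), b_inf, \
        np.full_like(np.asarray(v, float), 15.0)


def ih_gates(v):
    r_inf = 1.0 / (1.0 + np.exp((v + 81.0) / 8.0))
    return r_inf, np.full_like(np.asarray(v, float), 40.0)


def car_gates(v):
    m_inf = 1.0 / (1.0 + np.exp(-(v + 14.0) / 6.7))
    h_inf = 1.0 / (1.0 + np.exp((v + 65.0) / 11.8))
    return m_inf, np.full_like(np.asarray(v, float), 1.5), h_inf, \
        np.full_like(np.asarray(v, float), 65.0)


def kca_activation(ca, kd):
    return ca / (ca + kd)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class NeuronModel:
    """Discretized soma + apical cable with per-compartment conductances."""

    config: dict
    n: int                      # number of cable nodes (soma = node 0)
    length_um: np.ndarray       # per node
    diam_um: np.ndarray
    area_cm2: np.ndarray
    x_um: np.ndarray            # center distance from soma along the apical cable
    C: np.ndarray               # nF per node
    g_ax: np.ndarray            # uS, coupling node i <-> i+1, length n-1
    gbar: dict = field(default_factory=dict)   # uS per node per channel
    g_leak: np.ndarray = None   # uS
    e_leak: np.ndarray = None   # mV, leak-balanced at v_init
    v_init: float = -65.0
    # spine template
    spine_c: float = 0.0        # nF
    spine_g_neck: float = 0.0   # uS
    spine_gbar_car: float = 0.0
    spine_gbar_kca: float = 0.0
    spine_g_leak: float = 0.0
    spine_e_leak: float = 0.0
    spine_ca_phi: float = 0.0   # uM/ms per nA of Ca current
    soma_ca_phi: float = 0.0

    @property
    def apical_length_um(self) -> float:
        return self.config["morphology"]["apical_L_um"]

    def reversals(self):
        return self.config["reversals"]

    def steady_gates(self, v):
        """Steady-state gating variables at potential(s) v."""
        m, _, h, _ = na_gates(v)
        ndr, _ = kdr_gates(v)
        a, _, b, _ = ka_gates(v)
        r, _ = ih_gates(v)
        cm, _, ch, _ = car_gates(v)
        return {"na_m": m, "na_h": h, "kdr_n": ndr, "ka_a": a, "ka_b": b,
                "ih_r": r, "car_m": cm, "car_h": ch}

    def ionic_g_and_ge(self, gates, kca_w, ca_pools_w=None):
        """Total ionic conductance (uS) and conductance-weighted reversal sums.

        Returns (g_tot, ge_tot) per cable node for the implicit voltage
        update; ``kca_w`` is the KCa activation at the soma (node 0).
        """
        rev = self.reversals()
        g_na = self.gbar["na"] * gates["na_m"] ** 3 * gates["na_h"]
        g_kdr = self.gbar["kdr"] * gates["kdr_n"]
        g_ka = self.gbar["ka"] * gates["ka_a"] * gates["ka_b"]
        g_ih = self.gbar["ih"] * gates["ih_r"]
        g_car = self.gbar["car"] * gates["car_m"] ** 3 * gates["car_h"]
        g_kca = np.zeros(self.n)
        g_kca[0] = self.gbar["kca"][0] * kca_w
        g_tot = g_na + g_kdr + g_ka + g_ih + g_car + g_kca + self.g_leak
        ge = (g_na * rev["na"] + (g_kdr + g_ka + g_kca) * rev["k"]
              + g_ih * rev["h"] + g_car * rev["ca"] + self.g_leak * self.e_leak)
        return g_tot, ge, g_car


def _cylinder_area_cm2(L_um, diam_um):
    return np.pi * diam_um * L_um * 1e-8


def build_model(config: dict | None = None, validate: bool = True,
                drift_tol_mv_per_ms: float = 0.01) -> NeuronModel:
    """Build the reduced neuron from a configuration dictionary.

    Missing keys fall back to :data:`DEFAULT_CONFIG`.  The leak reversal of
    every compartment (and of the spine head template) is balanced so that
    the configured ``v_init`` is an exact fixed point with all gates at
    steady state; with ``validate=True`` a short input-free integration
    checks that this rest is also dynamically stable.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and key in cfg:
                cfg[key] = {**cfg[key], **val}
            else:
                cfg[key] = val

    morph = cfg["morphology"]
    n_ap = int(morph["n_apical"])
    n = 1 + n_ap
    length = np.empty(n)
    diam = np.empty(n)
    length[0] = morph["soma_L_um"]
    diam[0] = morph["soma_diam_um"]
    seg_len = morph["apical_L_um"] / n_ap
    length[1:] = seg_len
    xs = (np.arange(n_ap) + 0.5) * seg_len
    diam[1:] = morph["apical_diam_prox_um"] + (
        morph["apical_diam_dist_um"] - morph["apical_diam_prox_um"]
    ) * xs / morph["apical_L_um"]
    x_um = np.concatenate([[0.0], xs])

    area = _cylinder_area_cm2(length, diam)
    C = cfg["morphology"]["cm_uF_cm2"] * area * 1e3  # uF/cm2 * cm2 -> uF=1e3 nF

    ra = morph["ra_ohm_cm"]
    # half-segment axial resistances (MOhm) -> coupling conductance in uS
    r_half = ra * (length * 1e-4 / 2.0) / (np.pi * (diam * 1e-4 / 2.0) ** 2) * 1e-6
    g_ax = 1.0 / (r_half[:-1] + r_half[1:])  # 1/MOhm = uS

    ch = cfg["channels"]
    names = ["na", "kdr", "ka", "ih", "car", "kca"]
    gbar = {}
    for name in names:
        dens = np.empty(n)
        dens[0] = ch["soma"].get(name, 0.0)
        dens[1:] = ch["apical"].get(name, 0.0)
        if name == "ka":
            dens[1:] *= 1.0 + (ch.get("ka_gradient", 1.0) - 1.0) * xs / morph["apical_L_um"]
        if any(d < 0 for d in np.atleast_1d(dens)):
            raise ValueError(f"negative channel density for {name}")
        gbar[name] = dens * area * 1e6  # S/cm2 * cm2 -> S = 1e6 uS
    g_leak = np.empty(n)
    g_leak[0] = ch["soma"]["leak"]
    g_leak[1:] = ch["apical"]["leak"]
    g_leak = g_leak * area * 1e6

    model = NeuronModel(
        config=cfg, n=n, length_um=length, diam_um=diam, area_cm2=area,
        x_um=x_um, C=C, g_ax=g_ax, gbar=gbar, g_leak=g_leak,
        e_leak=np.zeros(n), v_init=float(cfg["v_init"]),
    )

    # spine template
    sp = cfg["spine"]
    head_area = np.pi * sp["head_diam_um"] ** 2 * 1e-8  # sphere surface, cm2
    model.spine_c = cfg["morphology"]["cm_uF_cm2"] * head_area * 1e3
    neck_r = ra * (sp["neck_L_um"] * 1e-4) / (
        np.pi * (sp["neck_diam_um"] * 1e-4 / 2.0) ** 2) * 1e-6  # MOhm
    model.spine_g_neck = 1.0 / neck_r
    model.spine_gbar_car = sp["car"] * head_area * 1e6
    model.spine_gbar_kca = sp["kca"] * head_area * 1e6
    model.spine_g_leak = sp["leak"] * head_area * 1e6
    head_vol_L = (np.pi / 6.0) * sp["head_diam_um"] ** 3 * 1e-15  # um3 -> L
    model.spine_ca_phi = 1e-9 / (2.0 * FARADAY) / (
        head_vol_L * sp["ca_buffer_ratio"]) * 1e3  # uM/ms per nA
    sc = cfg["soma_ca"]
    soma_shell_L = area[0] * sc["shell_um"] * 1e-4 * 1e-3  # cm2*cm -> cm3 -> L
    model.soma_ca_phi = 1e-9 / (2.0 * FARADAY) / (
        soma_shell_L * sc["buffer_ratio"]) * 1e3

    _balance_leak(model)
    if validate:
        _check_rest(model, drift_tol_mv_per_ms)
    return model


def _balance_leak(model: NeuronModel) -> None:
    """Set per-compartment (and spine) leak reversal so v_init is a fixed point."""
    v0 = model.v_init
    rev = model.reversals()
    gates = model.steady_gates(np.full(model.n, v0))
    ca0 = model.config["soma_ca"]["rest_uM"]
    w0 = kca_activation(ca0, model.config["kca_kd_uM"])
    g_tot, ge, _ = model.ionic_g_and_ge(gates, w0)
    # remove the provisional leak contribution (e_leak was 0)
    g_act = g_tot - model.g_leak
    ge_act = ge - model.g_leak * model.e_leak
    i_act = g_act * v0 - ge_act  # nA of active current at rest (outward > 0)
    model.e_leak = v0 + i_act / model.g_leak

    # spine head: CaR + KCa + leak only
    cm0, _, ch0, _ = car_gates(np.array(v0))
    g_car = model.spine_gbar_car * float(cm0) ** 3 * float(ch0)
    ca_sp = model.config["spine"]["ca_rest_uM"]
    g_kca = model.spine_gbar_kca * kca_activation(ca_sp, model.config["kca_kd_uM"])
    i_act = g_car * (v0 - rev["ca"]) + g_kca * (v0 - rev["k"])
    model.spine_e_leak = v0 + i_act / model.spine_g_leak


def _check_rest(model: NeuronModel, tol: float) -> None:
    from grinsyn.sim.run import run_train, StimProtocol

    proto = StimProtocol(n_syn=0, freq_hz=20.0, n_stim=0, duration_ms=100.0)
    res = run_train(model, proto, None, seed=0)
    drift = np.abs(np.diff(res.vm_soma)) / (res.t_ms[1] - res.t_ms[0])
    if drift.max() > tol:
        raise ValueError(
            f"resting potential unstable: max |dV/dt| = {drift.max():.3g} mV/ms")
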