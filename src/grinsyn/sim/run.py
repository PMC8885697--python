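"""Train simulation on the reduced neuron: integration, summaries, grids.

The cable (soma + apical chain) is advanced by an implicit (backward Euler)
voltage update with explicit, exponential-Euler gating, at the acquisition
time step of 25 us.  Spine heads are eliminated analytically from the linear
system each step (each head couples to exactly one dendritic compartment
through its neck resistance), leaving a tridiagonal solve for the cable.
All synapses are activated synchronously at the protocol's stimulus times;
the only randomness is spine placement, controlled by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from grinsyn.sim.model import NeuronModel, car_gates
from grinsyn.sim.synapse import SynapseSpec

__all__ = [
    "StimProtocol",
    "SimResult",
    "place_synapses",
    "run_train",
    "count_spikes",
    "spine_summaries",
    "currentscape",
    "run_experiment_grid",
]


@dataclass
class StimProtocol:
    """Synchronous stimulation protocol: n_stim pulses at freq_hz to n_syn spines."""

    n_syn: int = 40
    freq_hz: float = 200.0
    n_stim: int = 5
    t_start_ms: float = 10.0
    tail_ms: float = 250.0
    duration_ms: float | None = None
    dt_ms: float = 0.025
    record_dt_ms: float = 0.1

    def stim_times_ms(self) -> np.ndarray:
        if self.n_stim < 1:
            return np.array([])
        return self.t_start_ms + np.arange(self.n_stim) * 1000.0 / self.freq_hz

    def total_ms(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        times = self.stim_times_ms()
        last = times[-1] if times.size else self.t_start_ms
        return last + self.tail_ms


@dataclass
class SimResult:
    """Recorded state of one simulated train (ensemble means over spines)."""

    t_ms: np.ndarray
    vm_soma: np.ndarray
    vm_spine_mean: np.ndarray
    ca_spine_mean: np.ndarray
    ca_soma: np.ndarray
    spine_currents: dict          # name -> mean current over spines, nA
    v_rest: float
    ca_rest: float
    n_syn: int
    seed: int
    kinetic_scale: float
    attach_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        for arr in [self.vm_soma, self.vm_spine_mean, self.ca_spine_mean]:
            if not np.all(np.isfinite(arr)):
                raise ValueError("simulation produced non-finite output")


def place_synapses(model: NeuronModel, n: int, seed: int):
    """Spine positions drawn uniformly along the apical cable; deterministic per seed.

    Returns ``(positions_um, attach_idx)`` where ``attach_idx`` are cable
    node indices (1..n_apical).
    """
    rng = np.random.default_rng(seed)
    L = model.apical_length_um
    pos = rng.uniform(0.0, L, size=n)
    seg = L / (model.n - 1)
    idx = np.clip((pos // seg).astype(int) + 1, 1, model.n - 1)
    return pos, idx


def run_train(model: NeuronModel, protocol: StimProtocol,
              syn: SynapseSpec | None, seed: int = 0) -> SimResult:
    """Integrate a synchronous synaptic train; deterministic given the seed.

    ``syn`` may be None (or ``protocol.n_syn`` zero) for an input-free run.
    Raises on numerical blow-up, naming the first offending compartment.
    """
    from grinsyn.sim._kernel import step_loop

    dt = protocol.dt_ms
    nt = int(round(protocol.total_ms() / dt))
    decim = max(int(round(protocol.record_dt_ms / dt)), 1)
    rev = model.reversals()
    kd = model.config["kca_kd_uM"]
    sp_cfg = model.config["spine"]
    sc_cfg = model.config["soma_ca"]

    n_syn = protocol.n_syn if syn is not None else 0
    if n_syn > 0:
        _, attach = place_synapses(model, n_syn, seed)
        t_steps = np.arange(nt + 1) * dt
        stim = protocol.stim_times_ms()
        g_ampa_t, g_nmda_t = syn.conductance_trains(t_steps, stim)
        g_ampa_t = np.ascontiguousarray(g_ampa_t * 1e-3)  # nS -> uS
        g_nmda_t = np.ascontiguousarray(g_nmda_t * 1e-3)
        mg = syn.mg_mM
        ca_frac = syn.ca_fraction
    else:
        attach = np.array([], dtype=np.int64)
        g_ampa_t = np.zeros(1)
        g_nmda_t = np.zeros(1)
        mg = 1.0
        ca_frac = 0.0

    v = np.full(model.n, model.v_init)
    gates = model.steady_gates(v)
    v0s = np.array(model.v_init)
    vh = np.full(n_syn, model.v_init)
    car_m_h = np.full(n_syn, float(car_gates(v0s)[0]))
    car_h_h = np.full(n_syn, float(car_gates(v0s)[2]))
    ca_h = np.full(n_syn, sp_cfg["ca_rest_uM"])

    n_rec = nt // decim + 1
    rec = {k: np.empty(n_rec) for k in
           ["vs", "vh", "cah", "cas", "nmda", "ampa", "car", "kca", "leak", "neck"]}

    irec, blow_t, blow_c = step_loop(
        nt, dt, decim,
        v, gates["na_m"], gates["na_h"], gates["kdr_n"], gates["ka_a"],
        gates["ka_b"], gates["ih_r"], gates["car_m"], gates["car_h"],
        model.C, model.g_ax, model.g_leak, model.e_leak,
        model.gbar["na"], model.gbar["kdr"], model.gbar["ka"],
        model.gbar["ih"], model.gbar["car"], model.gbar["kca"],
        rev["na"], rev["k"], rev["h"], rev["ca"],
        sc_cfg["rest_uM"], model.soma_ca_phi, sc_cfg["tau_ms"],
        sc_cfg["rest_uM"], kd,
        attach.astype(np.int64), vh, car_m_h, car_h_h, ca_h,
        model.spine_c, model.spine_g_neck, model.spine_gbar_car,
        model.spine_gbar_kca, model.spine_g_leak, model.spine_e_leak,
        model.spine_ca_phi, sp_cfg["ca_tau_ms"], sp_cfg["ca_rest_uM"], ca_frac,
        g_ampa_t, g_nmda_t, mg, 3.57, 0.062,
        rec["vs"], rec["vh"], rec["cah"], rec["cas"],
        rec["nmda"], rec["ampa"], rec["car"], rec["kca"], rec["leak"],
        rec["neck"],
    )
    if blow_c >= 0:
        raise FloatingPointError(
            f"numerical blow-up at t = {blow_t:.3f} ms, compartment {blow_c}")

    t_rec = np.arange(irec) * (decim * dt)
    names = ["nmda", "ampa", "car", "kca", "leak", "neck"]
    return SimResult(
        t_ms=t_rec, vm_soma=rec["vs"][:irec], vm_spine_mean=rec["vh"][:irec],
        ca_spine_mean=rec["cah"][:irec], ca_soma=rec["cas"][:irec],
        spine_currents={k: rec[k][:irec] for k in names},
        v_rest=model.v_init, ca_rest=sp_cfg["ca_rest_uM"],
        n_syn=n_syn, seed=seed,
        kinetic_scale=syn.kinetic_scale if syn is not None else 1.0,
        attach_idx=attach,
    )


def count_spikes(vm, t_ms=None, threshold: float = 0.0,
                 refractory_ms: float = 1.0, dt_ms: float | None = None) -> int:
    """Positive-going threshold crossings separated by a refractory window."""
    vm = np.asarray(vm, dtype=float)
    if t_ms is None:
        t_ms = np.arange(vm.size) * (dt_ms if dt_ms else 1.0)
    t_ms = np.asarray(t_ms, dtype=float)
    up = np.flatnonzero((vm[1:] >= threshold) & (vm[:-1] < threshold)) + 1
    count = 0
    last = -np.inf
    for i in up:
        if t_ms[i] - last >= refractory_ms:
            count += 1
            last = t_ms[i]
    return count


def spine_summaries(result: SimResult) -> dict:
    """Per-train summary integrals (above rest) and the spike count.

    Membrane-potential integrals are in mV*ms of depolarisation relative to
    rest; the calcium integral is in uM*ms above the resting concentration.
    """
    dt = result.t_ms[1] - result.t_ms[0] if result.t_ms.size > 1 else 1.0
    soma_int = float(np.trapezoid(result.vm_soma - result.v_rest, dx=dt))
    spine_int = float(np.trapezoid(result.vm_spine_mean - result.v_rest, dx=dt))
    ca_int = float(np.trapezoid(np.maximum(result.ca_spine_mean - result.ca_rest, 0.0),
                                dx=dt))
    nmda_q = float(np.trapezoid(np.abs(result.spine_currents["nmda"]), dx=dt))
    return {
        "spikes": count_spikes(result.vm_soma, result.t_ms),
        "soma_vm_integral_mVms": soma_int,
        "spine_vm_integral_mVms": spine_int,
        "spine_ca_integral_uMms": ca_int,
        "peak_ca_uM": float(result.ca_spine_mean.max()),
        "nmda_charge_pC": nmda_q,  # nA * ms = pC (per-spine mean)
    }


def currentscape(result: SimResult) -> dict:
    """Fractional shares of inward and outward spine-head currents over time.

    At each recorded time point, inward (negative) and outward (positive)
    currents are separately normalized to fractions in [0, 1]; where the
    total of a class is zero its fractions are zero.
    """
    names = list(result.spine_currents)
    I = np.vstack([result.spine_currents[k] for k in names])
    inward = np.where(I < 0, -I, 0.0)
    outward = np.where(I > 0, I, 0.0)

    def norm(M):
        tot = M.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(tot > 0, M / np.where(tot > 0, tot, 1.0), 0.0)
        return F

    return {"names": names, "t_ms": result.t_ms,
            "inward": norm(inward), "outward": norm(outward),
            "inward_total_nA": inward.sum(axis=0),
            "outward_total_nA": outward.sum(axis=0)}


def run_experiment_grid(
    model: NeuronModel,
    genotypes=(1.0, 1.5, 2.0),
    n_syns=(40, 200),
    freqs=(20.0, 40.0, 80.0, 200.0),
    seeds=range(10),
    syn_template: SynapseSpec | None = None,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Run the full genotype x synapse-count x frequency x seed grid.

    Seeds are shared across genotypes, so spine placement is matched within a
    seed and per-seed comparisons between kinetic profiles are paired.
    Returns one long-format summary row per run.
    """
    base = syn_template or SynapseSpec()
    rows = []
    for n_syn in n_syns:
        for freq in freqs:
            for seed in seeds:
                for k in genotypes:
                    syn = SynapseSpec(
                        kinetic_scale=k, ampa=base.ampa, nmda_wt=base.nmda_wt,
                        mg_mM=base.mg_mM, ca_fraction=base.ca_fraction)
                    proto = StimProtocol(n_syn=n_syn, freq_hz=freq,
                                         **protocol_kwargs)
                    res = run_train(model, proto, syn, seed=seed)
                    row = {"kinetic_scale": k, "n_syn": n_syn,
                           "freq_hz": freq, "seed": seed}
                    row.update(spine_summaries(res))
                    rows.append(row)
    return pd.DataFrame(rows)
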