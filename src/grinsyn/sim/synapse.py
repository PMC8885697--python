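"""Synaptic conductance waveforms and charge-matched kinetic scaling.

AMPA and NMDA conductances are peak-normalized differences of two
exponentials.  A "mutant-like" NMDA conductance is produced by scaling both
time constants by a kinetic factor k (k = 1.5 for gain-of-function-like,
k = 2.0 for loss-of-function-like slowing) and dividing the peak conductance
by k, which leaves the conductance time-integral (charge transfer at fixed
driving force) exactly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseSpec",
    "biexp_peak_time",
    "biexp_conductance",
    "biexp_integral",
    "charge_matched_gmax",
    "mg_block_factor",
]


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of exp(-t/tau_decay) - exp(-t/tau_rise), in ms."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def _peak_factor(tau_rise: float, tau_decay: float) -> float:
    tp = biexp_peak_time(tau_rise, tau_decay)
    return np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)


def biexp_conductance(t, gmax: float, tau_rise: float, tau_decay: float):
    """Peak-normalized difference-of-exponentials conductance.

    g(t) = gmax * (exp(-t/tau_decay) - exp(-t/tau_rise)) / N for t >= 0
    (zero before), with N such that the maximum equals ``gmax``.  Units
    follow ``gmax``; ``t`` and the time constants are in ms.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    return gmax * g / _peak_factor(tau_rise, tau_decay)


def biexp_integral(gmax: float, tau_rise: float, tau_decay: float) -> float:
    """Closed-form time-integral of the peak-normalized conductance.

    integral = gmax * (tau_decay - tau_rise) / N (units of gmax * ms).
    """
    return gmax * (tau_decay - tau_rise) / _peak_factor(tau_rise, tau_decay)


def charge_matched_gmax(gmax_wt: float, k: float) -> float:
    """Peak conductance equalizing charge with the WT synapse under k-scaling.

    Scaling both time constants by k stretches the waveform in time without
    changing its peak, multiplying the integral by k; dividing the peak by k
    restores it.  So the charge-matched peak is simply ``gmax_wt / k``
    (1 nS -> 666.7 pS at k = 1.5, 500 pS at k = 2).
    """
    if k <= 0:
        raise ValueError("kinetic scale must be positive")
    return gmax_wt / k


def mg_block_factor(v, mg: float = 1.0, kd0: float = 3.57, gamma: float = 0.062):
    """Voltage-dependent magnesium block of the NMDAR conductance.

    Boltzmann form B(v) = 1 / (1 + (mg/kd0) * exp(-gamma * v)) with the
    classic constants kd0 = 3.57 mM and gamma = 0.062 /mV; ``mg`` is the
    extracellular Mg2+ concentration in mM.  Returns a factor in [0, 1],
    strictly increasing in v.
    """
    if mg < 0:
        raise ValueError("mg concentration must be non-negative")
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + (mg / kd0) * np.exp(-gamma * v))
    return float(out) if out.ndim == 0 else out


@dataclass
class ReceptorKinetics:
    tau_rise: float   # ms
    tau_decay: float  # ms
    gmax: float       # nS
    e_rev: float = 0.0

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")


@dataclass
class SynapseSpec:
    """AMPA + NMDA synapse with a kinetic scale applied to the NMDA component.

    The NMDA time constants are multiplied by ``kinetic_scale`` and its peak
    conductance divided by it (charge matching).  ``ca_fraction`` is the
    fraction of NMDAR current carried by calcium into the spine head.
    """

    kinetic_scale: float = 1.0
    ampa: ReceptorKinetics = field(default_factory=lambda: ReceptorKinetics(0.3, 3.0, 0.5))
    nmda_wt: ReceptorKinetics = field(default_factory=lambda: ReceptorKinetics(3.0, 80.0, 1.0))
    mg_mM: float = 1.0
    ca_fraction: float = 0.1

    def __post_init__(self):
        if self.kinetic_scale <= 0:
            raise ValueError("kinetic scale must be positive")

    @property
    def nmda(self) -> ReceptorKinetics:
        k = self.kinetic_scale
        return ReceptorKinetics(
            self.nmda_wt.tau_rise * k,
            self.nmda_wt.tau_decay * k,
            charge_matched_gmax(self.nmda_wt.gmax, k),
            self.nmda_wt.e_rev,
        )

    def conductance_trains(self, t_ms: np.ndarray, stim_times_ms):
        """Summed AMPA and NMDA conductance time courses (nS) for a stimulus train."""
        g_a = np.zeros_like(t_ms)
        g_n = np.zeros_like(t_ms)
        a, n = self.ampa, self.nmda
        for ts in stim_times_ms:
            g_a += biexp_conductance(t_ms - ts, a.gmax, a.tau_rise, a.tau_decay)
            g_n += biexp_conductance(t_ms - ts, n.gmax, n.tau_rise, n.tau_decay)
        return g_a, g_n
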