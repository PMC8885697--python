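"""Synthetic ground-truth generators for every pipeline input.

Two forward models: (1) mutation property tables with a planted
two-correlated-factor structure, cluster centres and missingness, mirroring
the structure of compiled heterologous-expression datasets; (2) paired
whole-cell recordings of evoked mixed AMPA/NMDA EPSCs over a holding-potential
series, forward-distorted by series resistance, stimulus artifact and
Gaussian noise.  Every generator is a pure function of its seed and emits a
truth record consumed by the test suites of the processing modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from grinsyn.tables import PropertyTable, PROPERTY_COLUMNS, INVERTED_COLUMNS
from grinsyn.epsc import Sweep
from grinsyn.sim.synapse import biexp_conductance, mg_block_factor

__all__ = [
    "MutationGenSpec",
    "EPSCGenSpec",
    "RecordingPair",
    "gen_mutation_table",
    "gen_epsc_pair",
    "forward_rs_distort",
]

# WT reference measurements used to exponentiate planted log10 effects
WT_REFERENCE = {
    "glu_ec50_uM": 3.0,
    "gly_ec50_uM": 1.0,
    "deact_tau_ms": 50.0,
    "current_density_pA_pF": 100.0,
    "open_prob": 0.5,
    "surface_rel": 1.0,
}

# factor 1 drives the activation/gating properties (potencies, deactivation,
# open probability); factor 2 drives expression (current density, surface)
DEFAULT_LOADING_TEMPLATE = np.array([
    # f1    f2
    [0.90, 0.10],   # glu potency
    [0.60, 0.10],   # gly potency
    [0.55, 0.00],   # deactivation tau
    [0.15, 0.90],   # current density
    [0.55, 0.15],   # open probability
    [0.10, 0.75],   # surface level
])

DEFAULT_CLUSTER_CENTERS = np.array([
    [1.3, 0.3],     # gain-of-function for factor 1
    [-1.3, -0.4],   # loss-of-function for factor 1
    [-0.5, -1.6],   # severe loss for factor 2
    [0.0, 0.0],     # WT-like
])


@dataclass
class MutationGenSpec:
    """Planted-structure generator spec for mutation property tables."""

    n_mutations: int = 20
    loading_template: np.ndarray = field(
        default_factory=lambda: DEFAULT_LOADING_TEMPLATE.copy())
    factor_correlation: float = 0.5
    cluster_centers: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLUSTER_CENTERS.copy())
    cluster_spread: float = 0.25
    noise_sd: float = 0.10          # log10 units
    missing_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_fraction < 0.5:
            raise ValueError("missing_fraction must be in [0, 0.5)")


def gen_mutation_table(spec: MutationGenSpec):
    """Generate a property table with planted factors and clusters.

    Cluster labels are assigned round-robin (every centre gets at least one
    mutation when n >= k); factor scores are the cluster centre plus
    correlated within-cluster noise (correlation ``factor_correlation``);
    scores map through the loading template to 6 log10-effect columns which
    are exponentiated against the WT reference (EC50 columns inverted so a
    positive potency effect lowers EC50).  Returns ``(PropertyTable, truth)``
    where truth carries the planted scores, labels and masked cells.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_mutations
    k = spec.cluster_centers.shape[0]
    labels = np.arange(n) % k
    rng.shuffle(labels)

    s = spec.cluster_spread
    rho = spec.factor_correlation
    cov = np.array([[s**2, rho * s**2], [rho * s**2, s**2]])
    scores = spec.cluster_centers[labels] + rng.multivariate_normal(
        np.zeros(2), cov, size=n)

    effects = scores @ spec.loading_template.T
    effects += rng.normal(0.0, spec.noise_sd, size=effects.shape)

    wt = pd.Series(WT_REFERENCE)[PROPERTY_COLUMNS]
    values = np.empty_like(effects)
    for j, col in enumerate(PROPERTY_COLUMNS):
        sign = -1.0 if col in INVERTED_COLUMNS else 1.0
        values[:, j] = wt[col] * 10.0 ** (sign * effects[:, j])

    # mask cells at random, keeping >= 2 observed per column
    mask = np.zeros_like(values, dtype=bool)
    if spec.missing_fraction > 0:
        n_cells = values.size
        n_miss = int(round(spec.missing_fraction * n_cells))
        flat = rng.permutation(n_cells)
        for cell in flat:
            if n_miss == 0:
                break
            i, j = divmod(cell, values.shape[1])
            if (~mask[:, j]).sum() > 2:
                mask[i, j] = True
                n_miss -= 1
    data = pd.DataFrame(np.where(mask, np.nan, values),
                        index=[f"M{i + 1:02d}" for i in range(n)],
                        columns=PROPERTY_COLUMNS)
    truth = {
        "scores": scores,
        "labels": labels,
        "factor_correlation": rho,
        "masked_values": values[mask],
        "mask": mask,
        "loading_template": spec.loading_template.copy(),
    }
    return PropertyTable(data, wt.astype(float)), truth


# ---------------------------------------------------------------------------
# Paired-recording EPSC forward model
# ---------------------------------------------------------------------------

@dataclass
class EPSCGenSpec:
    """Forward model of a paired recording over a holding-potential series.

    The "transfected" cell's NMDA component has its time constants scaled by
    ``genotype_kinetic_scale`` and amplitude by ``genotype_amp_scale``; the
    untransfected cell is WT-like.  ``mg_mode`` controls the magnesium block
    in the forward model: "oracle" (NMDA silent at -100 mV, unattenuated
    elsewhere — the exact construction the subtraction protocol inverts),
    "idealized" (NMDA silent at -100 mV, Boltzmann-blocked elsewhere), or
    "realistic" (Boltzmann factor everywhere, leaving the residual NMDA
    conductance at -100 mV that the subtraction protocol ignores).
    """

    ampa_g_nS: float = 2.0
    nmda_g_nS: float = 1.5
    ampa_tau_rise_ms: float = 0.3
    ampa_tau_decay_ms: float = 3.0
    nmda_tau_rise_ms: float = 3.0
    nmda_tau_decay_ms: float = 80.0
    genotype_kinetic_scale: float = 1.0
    genotype_amp_scale: float = 1.0
    v_holds_mV: tuple = (-100.0, -80.0, -60.0, -40.0, -20.0, 0.0, 20.0)
    rs_MOhm: float = 12.0
    cm_pF: float = 100.0
    rs_distort: bool = True
    noise_sd_pA: float = 5.0
    artifact_amp_pA: float = 200.0
    artifact_width_ms: float = 0.6
    n_sweeps: int = 10
    fs_Hz: float = 25000.0
    t0_stim_s: float = 0.02
    duration_s: float = 0.52
    mg_mode: str = "idealized"
    mg_mM: float = 1.0
    seed: int = 0


@dataclass
class RecordingPair:
    """Matched transfected/untransfected sweep sets, keyed by holding potential."""

    transfected: dict    # v_hold -> list[Sweep]
    untransfected: dict
    pair_id: str = "pair0"


def _ideal_cell_current(spec: EPSCGenSpec, t_ms, v, transfected: bool):
    """Noise-free current (pA) at holding potential v for one cell."""
    k = spec.genotype_kinetic_scale if transfected else 1.0
    amp = spec.genotype_amp_scale if transfected else 1.0
    t_rel = t_ms - spec.t0_stim_s * 1e3
    g_a = biexp_conductance(t_rel, spec.ampa_g_nS,
                            spec.ampa_tau_rise_ms, spec.ampa_tau_decay_ms)
    g_n = biexp_conductance(t_rel, spec.nmda_g_nS * amp,
                            spec.nmda_tau_rise_ms * k, spec.nmda_tau_decay_ms * k)
    if spec.mg_mode == "oracle":
        blk = 0.0 if v <= -99.0 else 1.0
    elif spec.mg_mode == "idealized":
        blk = 0.0 if v <= -99.0 else mg_block_factor(v, spec.mg_mM)
    elif spec.mg_mode == "realistic":
        blk = mg_block_factor(v, spec.mg_mM)
    else:
        raise ValueError(f"unknown mg_mode {spec.mg_mode!r}")
    return (g_a + g_n * blk) * v  # nS * mV = pA, e_rev = 0


def forward_rs_distort(ideal: Sweep, rs: float, cm: float,
                       v_hold: float, e_rev: float = 0.0) -> Sweep:
    """Forward model of series-resistance distortion of an ideal current.

    Point-wise driving-force attenuation (the recorded current sees a
    holding potential reduced by its own voltage error I*rs) followed by a
    first-order RC low-pass with tau = rs * cm.  This is the physical
    distortion that offline compensation aims to undo.
    """
    if rs <= 0 or cm <= 0:
        raise ValueError("rs and cm must be positive")
    vd = v_hold - e_rev
    if vd == 0:
        # at the reversal potential the ideal current is zero; only the RC
        # filtering stage applies
        i_rec = ideal.samples.copy()
    else:
        # I_rec = I_id * (vd - I_rec*rs)/vd  =>  linear point-wise solution
        i_rec = ideal.samples / (1.0 + ideal.samples * rs * 1e-3 / vd)
    tau_ms = rs * cm * 1e-3
    dt_ms = 1e3 / ideal.fs
    d = np.exp(-dt_ms / tau_ms)
    filt = signal.lfilter([1.0 - d], [1.0, -d], i_rec)
    return replace(ideal, samples=filt, rs=rs, cm=cm, v_hold=v_hold)


def gen_epsc_pair(spec: EPSCGenSpec):
    """Generate a matched recording pair with ground truth.

    For each cell and holding potential, the ideal conductance transients are
    converted to current, optionally distorted by the series resistance
    forward model, given a stimulus artifact (one-sided exponential spike at
    the stimulus time), and sampled ``n_sweeps`` times with independent
    Gaussian noise.  Returns ``(RecordingPair, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_Hz))
    t_ms = np.arange(n) * 1e3 / spec.fs_Hz
    i0 = int(round(spec.t0_stim_s * spec.fs_Hz))
    w = max(int(round(spec.artifact_width_ms * 1e-3 * spec.fs_Hz)), 1)
    artifact = np.zeros(n)
    artifact[i0:i0 + w] = spec.artifact_amp_pA * np.exp(-np.arange(w) / (w / 4.0))

    def make_cell(transfected):
        out = {}
        for v in spec.v_holds_mV:
            ideal = _ideal_cell_current(spec, t_ms, v, transfected)
            sw = Sweep(ideal, fs=spec.fs_Hz, t0_stim=spec.t0_stim_s, v_hold=v,
                       rs=spec.rs_MOhm, cm=spec.cm_pF,
                       cell_id="tr" if transfected else "untr")
            if spec.rs_distort:
                sw = forward_rs_distort(sw, spec.rs_MOhm, spec.cm_pF, v)
            sweeps = []
            for _ in range(spec.n_sweeps):
                noisy = sw.samples + artifact + rng.normal(0.0, spec.noise_sd_pA, n)
                sweeps.append(replace(sw, samples=noisy))
            out[v] = sweeps
        return out

    pair = RecordingPair(transfected=make_cell(True),
                         untransfected=make_cell(False))
    k = spec.genotype_kinetic_scale
    truth = {
        "ampa_g_nS": spec.ampa_g_nS,
        "nmda_g_nS_untr": spec.nmda_g_nS,
        "nmda_g_nS_tr": spec.nmda_g_nS * spec.genotype_amp_scale,
        "nmda_tau_rise_ms_tr": spec.nmda_tau_rise_ms * k,
        "nmda_tau_decay_ms_tr": spec.nmda_tau_decay_ms * k,
        "kinetic_scale": k,
        "amp_scale": spec.genotype_amp_scale,
        "mg_block_p20": (1.0 if spec.mg_mode == "oracle"
                         else float(mg_block_factor(20.0, spec.mg_mM))),
    }
    return pair, truth
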