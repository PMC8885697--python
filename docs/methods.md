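# Methods

This note records the models, numerical choices and calibrations behind the
three pipelines, what the synthetic generators do and do not emulate, and
the known limitations.

## Variant classification

**Normalisation.** Each of the six receptor properties is expressed as
log10(value / WT) with a sign convention making "more function" positive:
EC50s are inverted into potencies (1/EC50), the deactivation time constant
enters un-inverted (slower channel closure means more charge per activation),
and current density, open probability and surface level enter directly.
Log base 10 was chosen because compiled mutation effects span roughly four
orders of magnitude and decade units read naturally; any base is
monotone-equivalent for PCA on standardized columns.

**Imputation.** Missing cells are completed by low-rank alternating least
squares on the column-wise rank transform, followed by piecewise-linear
interpolation of completed ranks against the observed (rank, value) pairs of
each column; completed ranks outside the observed range are clamped to the
column extremes, and observed cells are never altered. Default rank is 2,
matching the number of retained components. Convergence is declared when
the largest imputed-cell change falls below `tol` (default 1e-6 rank units);
non-convergence within `max_iter` raises with the last residual.

**Component extraction.** PCA is computed on the correlation matrix
(z-scored columns) because the properties live on heterogeneous scales;
variance fractions are eigenvalue fractions. The retained 2-column loading
matrix (eigenvectors × √eigenvalue) is rotated by varimax (default) or
promax (power 4). Scores are regression scores: standardized data projected
through the rotated pattern via `(PᵀP)⁻¹`. One structural fact matters for
interpretation: regression scores of an *orthogonally* rotated solution have
exactly identity sample correlation, so the inter-factor association is
always computed on the promax (oblique) scores, whatever rotation produced
the reported pattern matrix.

**Cluster number.** The elbow of the within-cluster sum-of-squares curve is
automated as the k maximising the second difference of log(within-SS); the
log makes the statistic scale-free, so it finds the k where the scatter
collapses rather than the large early drops that dominate the raw curve for
symmetric cluster layouts. A candidate elbow is accepted only if it explains
at least 80% of the k=1 scatter — k-means on a single isotropic Gaussian
explains at most ~70% at small k, so structureless score clouds fall back to
the configured minimum (default 1). K-means itself runs 100 seeded restarts.

**Calibrated bootstrap intervals.** Kendall's tau-b (exhaustive pair
counting with tie correction) is accompanied by a BCa bootstrap interval
whose nominal level is calibrated by a nested bootstrap: for each outer
resample, an inner bootstrap locates the original estimate in that
resample's own bootstrap distribution (u_b); the empirical distribution of
|2u_b − 1| is the central-coverage curve of nominal-level percentile
intervals, and its (1−α) quantile is the calibrated level at which the
final BCa interval (bias correction from the outer ECDF, acceleration from
the jackknife) is read off. Defaults are 20,000 outer and 200 inner
resamples; everything is deterministic given the seed. The p-value inverts
the BCa quantile map at zero.

## EPSC processing

**Pipeline order.** Blank the stimulus artifact (linear interpolation across
a window anchored two samples before the stimulus, extending 1 ms past it),
compensate series resistance offline, average baseline-subtracted sweeps
(baseline: 10 ms ending 1 ms before the stimulus), convert to conductance by
Ohm's law with reversal at 0 mV, subtract the −100 mV (AMPA) conductance
from the +20 mV trace to isolate the NMDA component, then measure.

**Series-resistance compensation.** The compensated resistance is
`Rs_c = fraction × Rs` with `fraction = max(1 − Rs_final/Rs, 0)`,
`Rs_final = 3 MΩ`. Stage one rescales the driving force point-wise,
`I′ = I·Vd/(Vd − I·Rs_c)` (the product I·Rs_c is the voltage error),
assuming a linear I–V through the reversal; a voltage error reaching the
driving force raises an "unphysical compensation" error. Stage two undoes
the Rs·Cm low-pass to first order, `I″ = I′ + Rs_c·Cm·dI′/dt`, with the
derivative computed on a zero-phase 4-pole-equivalent Bessel-smoothed copy
band-limited to 1 kHz. The bandwidth choice is deliberate: the RC corner
being restored sits near 1/(2π·Rs·Cm) ≈ 130 Hz for typical 12 MΩ/100 pF
recordings, while the noise gain of differentiation grows quadratically with
bandwidth; 1 kHz keeps the correction intact for synaptic kinetics
(rise ≥ 0.3 ms) at a fraction of the noise cost. The distort→correct
round trip on synthetic sweeps (the operational definition of this
correction) recovers peak within 2% and weighted tau within 3% at
signal-to-noise 10.

**Measurements.** The peak location is detected on a 0.5 ms boxcar-smoothed
copy; the amplitude is then re-estimated by local quadratic regression on
the raw trace over a window adapted to the transient width (half the span
above 80% of the smoothed peak, clamped to 0.2–1.5 ms). The two-stage
scheme exists because the maximum of a smoothed noisy trace is upward-biased
by selection (≈2–3% at SNR 10), which would swamp the quantities of
interest. Rise time is the interpolated 20→80% interval on the rising
phase; charge is the trapezoidal integral from stimulus to sweep end. Decay
is fit from the peak with a two-component exponential plus offset by
separable least squares (amplitudes and offset linear in the data for trial
time constants; time constants optimised on a log scale by bounded
least-squares from integral-method initial estimates). A double fit is
rejected — and refit as a single exponential — when an amplitude is
negative, the time constants separate by less than 1.5×, the fast component
is quicker than 0.2 ms (a sub-sample component only ever fits peak noise),
or the slow component reaches the fit-window bound (a tau longer than the
window is indistinguishable from the offset).

## Reduced neuron simulation

**Morphology and channels.** A soma (20 × 20 µm cylinder) plus a single
tapered apical cable (400 µm, 2.5 → 0.5 µm, 50 compartments), axial
resistivity 150 Ω·cm, specific capacitance 1 µF/cm². Six channel types in
standard Hodgkin–Huxley form: fast Na (m³h), delayed-rectifier K, A-type K
(with a 2× linear distal density gradient), h-current, high-voltage-activated
R-type Ca (m³h, ohmic with E_Ca = 120 mV), and a calcium-activated
medium-AHP K current (Michaelis activation in [Ca], K_d 0.8 µM, τ 30 ms).
Rates are used as written at the working temperature of 35 °C (no separate
Q10 factors). Spines are a head (0.5 µm sphere) carrying R-type Ca, KCa,
leak and the synaptic conductances, joined to the dendrite by a purely
resistive neck (1 µm × 0.1 µm ⇒ ≈190 MΩ).

**Synapses.** AMPA: rise 0.3 ms, decay 3 ms, peak 500 pS. NMDA (wildtype):
rise 3 ms, decay 80 ms, peak 1 nS, with Jahr–Stevens magnesium block
B(V) = 1/(1 + (mg/3.57 mM)·e^(−0.062·V)) at 1 mM Mg²⁺. Mutant-like
profiles scale both NMDA time constants by k (1.5 gain-of-function-like, 2.0
loss-of-function-like) and the peak by 1/k, preserving the conductance
integral exactly (the peak-normalized waveform stretches in time without
changing peak value). All synapses of a train fire synchronously; the only
randomness is spine placement, drawn uniformly along the apical cable from
the run's seed, and seeds are shared across genotypes so comparisons are
paired.

**Spine calcium.** Single-compartment head pool: influx is 10% of the NMDAR
current plus all R-type current, divided by 2F, the head volume, and an
instantaneous endogenous buffer ratio of 20; extrusion is first order with
τ = 15 ms toward a 0.05 µM rest. The soma holds an analogous 0.1 µm shell
pool (τ = 60 ms) feeding the somatic mAHP current. These are declared
calibration constants, not measured values.

**Integration.** Backward-Euler voltage update at dt = 25 µs with explicit
exponential-Euler gating; the spine heads are eliminated analytically from
the linear system each step (each head couples to one dendritic compartment
through its neck conductance), leaving a tridiagonal Thomas solve over the
cable; synaptic conductances are evaluated at the new time point. Outputs
are decimated to 0.1 ms. Halving dt changes the soma depolarisation
integral by ≲0.15%. The leak reversal of every compartment is balanced at
build time so the configured rest (−65 mV) is an exact fixed point; a short
input-free run verifies dynamic stability.

**Calibration.** Channel densities in the shipped default configuration
were set once against three qualitative constraints: rest at −65 mV, a
single 40-synapse volley subthreshold, and a 5-stimulus 200 Hz wildtype
train eliciting somatic spiking (first spike on the 4th–5th stimulus).
Under these defaults, at 40 synapses/200 Hz the matched-seed orderings
"spike count WT ≥ GOF ≥ LOF" and "spine-calcium integral largest for WT"
hold in 10/10 seeds. Absolute magnitudes (peak spine [Ca²⁺], integral
values) are not calibrated to any measured neuron and should be read only
comparatively. Soma depolarisation integrals can be negative for spiking
trains because the medium AHP outlasts the train; the integral is taken
relative to rest without clipping.

**Problem sizes.** The shipped experiment grid runs 3 genotypes × 40
synapses × {40, 200} Hz × 10 seeds with a 250 ms post-train tail; one train
integrates in ~0.1 s, the grid in a few seconds. The 200-synapse and
20/80 Hz conditions are available through the same interface.

## Synthetic data: what it does and does not emulate

The mutation-table generator plants two correlated factor scores per
mutation around four cluster centres (gain-of-function, two loss-of-function
types, wildtype-like), maps them through a 6 × 2 loading template, adds
log-normal measurement noise (0.10 decades), exponentiates against wildtype
reference values, and masks 10% of cells at random. It emulates the
low-rank structure, missingness and scale heterogeneity of compiled
mutation datasets — not literature-specific biases (non-random missingness,
inter-laboratory offsets, correlated assay errors).

The recording generator produces ideal biexponential AMPA+NMDA conductances
converted to currents over a −100…+20 mV series, with the NMDA component
Boltzmann-blocked ("idealized" mode silences it entirely at −100 mV, the
assumption the subtraction protocol makes; "realistic" mode leaves the
genuinely blocked residual so the protocol's systematic error can be
quantified), then applies the series-resistance forward model (point-wise
driving-force attenuation plus an Rs·Cm RC low-pass), a stimulus artifact,
and white Gaussian noise. It does not emulate trial-to-trial amplitude
variability, failures, paired-pulse dynamics, line noise or baseline drift —
so passing tests demonstrate correctness of the analysis under its stated
model, not robustness to every pathology of real recordings.

## Known limitations

* The classification pipeline's cluster count on small tables (n ≈ 20) is
  sensitive to the elbow heuristic; the cluster label boundaries are
  summaries, not biology.
* The offline compensation contract is defined by the distort→correct
  round trip on the synthetic forward model; real pipette artifacts
  (capacitance transients, partial electronic compensation) are out of
  scope.
* The reduced neuron reproduces qualitative orderings between NMDA kinetic
  profiles, not quantitative firing rates or calcium concentrations of any
  full CA1 model; channel kinetics are generic formulations, and spine
  geometry and calcium handling are single-compartment simplifications.
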