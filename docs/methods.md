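# Methods

## Model

Each population is a homogeneous ensemble of leaky integrate-and-fire
neurons with instantaneous ("shot-noise") synapses:

    tau_m dv/dt = -v + dv * sum_i delta(t - t_i),    v >= v_th  =>  v -> v_r = 0.

Voltages are measured relative to rest/reset (v_r = 0); the threshold sits
15 mV above it; tau_m = 10 ms; the refractory period is zero.  Instead of
simulating neurons, the solver evolves the voltage probability density
p(t, v) through the continuity equation dp/dt = -dJ/dv, where the flux J has
a leak part (advection toward 0 at speed |v|/tau_m) and a synaptic part
(displacement of probability mass by the jump `dv` at the presynaptic event
rate lambda_in).  Mass crossing threshold is absorbed and re-injected at the
reset; the absorbed mass per time step, divided by dt, is the population
output rate lambda_out(t).  This mean-field description is exact in the
limit of an infinite, uncorrelated population.

### Finite-volume discretization

The domain [v_min, v_th] is split into uniform bins (half-open
[edge_i, edge_{i+1}); a value on an edge belongs to the upper bin).  Leak
moves mass across each interior boundary at rate |v_boundary| / (tau_m *
dv_donor), always toward 0; no leak flux crosses threshold or v_min.  A
boundary lying exactly at 0 has zero advection speed, which would strand the
sub-zero boundary layer one bin below reset; that single boundary is crossed
at the donor cell's mean speed instead (an O(bin width) regularization).

A synaptic jump `w` displaces each bin's mass by `w`; non-integer
displacements are split between the two straddled destination bins by linear
interpolation, preserving total mass and the mean jump exactly.  Excitatory
mass displaced past threshold is re-injected at the reset bin and recorded
as firing flux; inhibitory mass that would cross v_min accumulates in the
lowest bin (hard wall).

Both operators are sparse matrices on the mass vector; a step is the action
of exp(dt (L + sum_s lambda_s S_s)).  Two evaluators are provided and agree
to ~1e-12: a dense matrix exponential of the generator augmented with a
firing-flux accumulator row (reference), and a sub-stepped truncated Taylor
series (default; sub-steps chosen so the sub-step generator norm is <= 2,
then terms to machine precision).  The coupled-network loop runs the same
Taylor scheme in a numba kernel, with per-target operators pre-composed per
distinct synaptic weight.

### Network coupling

Connections deliver in_degree x (delayed source rate) to the target's
operator for the connection's weight.  All populations advance
synchronously from rates read before the step (Jacobi update), so results
are order-independent and bit-deterministic.  Delays round to the nearest
step; a connection may instead carry a discretized delay kernel (a list of
(delay, fraction) terms).  Delay buffers start from each source's t = 0
rate.

## Column parameterization

Constants are transcribed in `src/popcolumn/data/potjans_diesmann_column.yaml`
from the Potjans-Diesmann (2014) tables: population sizes, the 8x8
connection-probability matrix (with the L4e -> L2/3e entry doubled to 0.088
so a single excitatory weight serves all projections), external background
in-degrees, the 8 Hz background rate, exponential-PSC parameters
(w = 87.8 pA, tau_s = 0.5 ms, C_m = 250 pF), g = 4, and mean delays
(1.5 ms excitatory, 0.75 ms inhibitory).

* **Synaptic weights.**  The voltage jump equals the total delivered charge
  over the capacitance: dv = w tau_s / C_m = 0.1756 mV; inhibitory
  jumps are -4 x that = -0.7024 mV.
* **Background rescaling.**  The background rate is divided by 8.54 and the
  background weight multiplied by 8.54 (to 1.4996 mV), preserving the mean
  drive exactly while raising its variance; this damps the intrinsic
  oscillations of the original parameterization.
* **In-degrees.**  The source tables define connection probability C as the
  probability of at least one synapse between a random pair, with synapses
  drawn pairwise-independently; the expected in-degree is then
  K/N_post = ln(1-C) / ln(1 - 1/(N_pre N_post)) / N_post ~= -N_pre ln(1-C).
  The small-C approximation C x N_pre underweights the dense L5i -> L5e
  projection (C = 0.3726) by ~25%; with the linear form the L5 steady rates
  come out ~60% high and the step perturbations ~60% strong, so the
  synapse-count form is used.  (`in_degree` implements the linear product;
  `synapse_count_in_degree` the conversion actually used by `build_column`.)
* **Delay kernels.**  The source model draws per-synapse delays from a
  normal distribution with sd = mean/2, truncated at the resolution.  A
  single discrete delay per connection turns the strong, fast E-I loops into
  an artificial few-hundred-Hz relaxation oscillation (rates swinging
  between 0 and >2000 Hz) in the deterministic density model, so
  `build_column` discretizes the truncated normal onto the dt grid as a
  delay kernel.  Scalar delays remain the default for hand-built networks.
* **Grid.**  Uniform 0.1 mV bins on [-15, 15] mV.  The lower bound must sit
  well below the deepest sub-reset excursions: with a wall at -5 mV the most
  strongly inhibited population (L6e) rests ~70% above its converged rate
  (1.88 vs 1.09 Hz; grids to -40 mV and bins to 0.05 mV change rates by
  <1%), and the L4 -> L5e gain curve flattens.  At 0.1 mV bins a residual
  O(h) bias remains in deeply fluctuation-driven regimes (single population
  at ~2 Hz reads ~15% high; the cross-validation tests therefore use finer
  grids where sub-Hz absolute accuracy matters).

## Protocols and analyses

Simulations follow a fixed protocol: Gaussian initial density (mean 0, sd
5 mV), 100 ms background-only settling, then 100 ms of drive, dt = 0.1 ms.
Drives model 100 independent presynaptic sources per target neuron at the
excitatory weight; target specificity selects the e population, the i
population, or both ("balanced").  Steady states are means over the final
20 ms before onset and the final 20 ms of the run; windows drifting by more
than 5% of their mean are flagged.  Sinusoidal drive uses a raised cosine,
baseline + A (1 - cos 2 pi f t)/2, which starts continuously, stays
non-negative, and has fundamental amplitude A/2 (used as A_in for gains).

Linearity is quantified by (i) the homogeneity extrapolation error
|(F10 - F0) - 2 (F5 - F0)| from 5 and 10 Hz steps, (ii) additivity of layer
pairs (sum of single-drive perturbations vs the joint drive), and (iii)
total harmonic distortion.  THD is reported in two labeled forms: the
power-ratio form sum_{i>=2} V_i^2 / V_1 (with V_i the spectral power of
harmonic i), and the conventional amplitude ratio
sqrt(sum_{i>=2} A_i^2) / A_1.  Harmonic amplitudes come from a joint
least-squares fit on an integer number of periods (default up to 64
harmonics or Nyquist, whichever is lower); the measure is flagged undefined
when the fundamental is below 0.05 Hz.  Amplitude-response cutoffs are the
-3 dB point relative to the peak gain of the sweep, interpolated log-log
between the bracketing frequencies (robust for band-pass transformations).

The sensitivity ensemble multiplies every connection probability by an
independent unit-mean Gaussian (sd = 5% of the entry, floored at 0),
rebuilds the column, and recomputes the homogeneity errors; models failing
to reach stationarity are recorded and excluded, never silently dropped.
Tests run 50 models; larger ensembles are a CLI flag away.

## The spiking oracle

`popcolumn.oracle` is an independent implementation of the same model at the
single-neuron level: explicit neurons, exact exponential decay between grid
times, Poisson background spike trains, realized recurrent connectivity
with per-synapse truncated-normal delays, zero refractory period (2 ms
optional).  For desk-scale runs the population sizes are scaled down with
in-degrees preserved (synapse counts per pair drawn Poisson, so effective
multiplicities above 1 are well defined).  The density solver is validated
against it: single-population steady states and step transients agree
within Monte-Carlo error, and the full column's background steady state
agrees per population to within a few percent at 1/10 scale.

What the oracle does not capture of real data — and hence what passing
tests do and do not show — mirrors the model's own idealizations:
homogeneous populations, a single synaptic weight per connection type,
instantaneous synapses, no adaptation or plasticity.  Desk-scale ensembles
additionally carry genuine finite-size correlations: with in-degrees
preserved at 1/10 scale, shared-input correlations raise steady rates by
~2-3% relative to the mean-field limit, which is visible once Monte-Carlo
error drops below that level (20 trials).

## Known limitations and discrepancies

* The mean-field density model is exact only for infinite uncorrelated
  populations; at 1/10 scale the spiking column runs systematically ~2-3%
  above it (finite-size correlations), so "within 3 SE" comparisons fail for
  some populations once SE < 1%.
* With the synapse-count in-degrees the laminar subtraction and steady
  rates are quantitatively reproduced, but the L5 subcircuit sits below the
  inhibition-stabilization threshold: excitatory drive onto L5i raises L5i
  monotonically (no paradoxical dip).  With linear C x N in-degrees the
  paradoxical dip-and-reversal appears textbook-like, but steady rates and
  step perturbations are then ~60% too strong.  The two regimes could not
  be reconciled in a single configuration; the package ships the
  synapse-count convention.
* The balanced L4 -> L5e amplitude response is lowpass, but its converged
  -3 dB cutoff is ~27-28 Hz (robust to grid depth, bin width, and drive
  amplitude, and consistent with the spiking oracle's modulation amplitudes
  at 8 and 30 Hz), i.e. an effective time constant of ~6 ms rather than
  tau_m.  The corresponding acceptance check asserts the 15 +/- 3 Hz band
  and is expected to fail under this implementation.
* Conductance-based or non-instantaneous synapses, weight distributions
  within a connection, refractory dynamics in the density solver, and
  spatially extended connectivity are out of scope.
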