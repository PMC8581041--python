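# Methods

## The model

spikescape simulates the classic biophysical circuit for two-alternative
perceptual decisions: a fully connected network of leaky integrate-and-fire
neurons, N_E = 1600 pyramidal cells and N_I = 400 interneurons.  Two
selective pools S1 and S2 (each a fraction f = 0.15 of the excitatory
cells) encode the two choices; the remaining excitatory cells are
non-selective (NS).  Every neuron obeys

    C_m dV/dt = -g_L (V - V_L) - I_syn,          V <= V_th,

with a spike emitted when V reaches V_th = -50 mV, followed by a reset to
V_reset = -55 mV held for an absolute refractory period (2 ms excitatory,
1 ms inhibitory).  Membrane parameters: C_m = 0.5 nF / 0.2 nF and
g_L = 25 nS / 20 nS for excitatory / inhibitory cells, V_L = -70 mV.

Synaptic input is conductance-based with four channels: external AMPA
(background 2.4 kHz Poisson per neuron, plus the stimulus), recurrent AMPA,
recurrent NMDA with the magnesium voltage gate
1/(1 + [Mg]exp(-0.062 V)/3.57), [Mg] = 1 mM, and GABA.  Gating variables
are per presynaptic neuron: AMPA and GABA decay exponentially (2 ms, 5 ms)
and jump by 1 per spike; NMDA has a two-variable rise/saturation form
(rise 2 ms, decay 100 ms, alpha = 0.5 /ms) that keeps s_NMDA in [0, 1].
Conductances onto excitatory cells: g_ext,AMPA = 2.1, g_rec,AMPA = 0.05,
g_NMDA = 0.165, g_GABA = 1.3 nS; onto inhibitory cells: 1.62, 0.04, 0.13,
1.0 nS.

Connection weights are population-structured: within-pool synapses of S1
and S2 carry the potentiated weight w+ > 1; S1<->S2 and NS->S1/S2 carry the
depressed weight w- = 1 - f(w+ - 1)/(1 - f), which keeps the spontaneous
recurrent drive onto a selective cell invariant in w+
(f·w+ + (1-f)·w- = 1); every other weight is 1, including all inhibitory
synapses (inhibition's sign enters through V - V_I).  Self-connections are
included; at full size their contribution is O(1/N).

A motion stimulus of strength mu and coherence c adds independent Poisson
trains at mu(1+c) Hz to every S1 neuron and mu(1-c) Hz to every S2 neuron,
merged into the same external-AMPA channel as the background (the current
equation has a single external AMPA term).

## Numerics of the simulator

The coupled membrane/gating ODEs are integrated with Heun's second-order
Runge-Kutta at dt = 0.02 ms.  Delta inputs (recurrent spikes, external
Poisson events) are not RK-integrable and are applied as discrete jumps at
step boundaries; only the smooth decay/rise terms get the RK2 treatment.
Spikes are detected at step ends without sub-step interpolation — at
dt = 0.02 ms the timing error is far below the refractory period.  Because
weights depend only on the (source population, target population) pair,
recurrent drive is accumulated as per-population sums of presynaptic gating
variables, making each step O(N) rather than O(N^2); the voltage-dependent
NMDA gate is evaluated per postsynaptic neuron at both RK stages.

External Poisson input is sampled exactly: the rate is uniform within a
population, so each population's per-step event count is Poisson
(n·lambda·dt) and events scatter uniformly over the population's neurons
(superposition property).  All randomness flows from one seeded generator
with a fixed draw order, so a trial is bit-reproducible from (config,
stimulus, duration, seed) and independent of internal chunking.

A non-finite membrane potential or gating value aborts the run with the
step and neuron identified.

### Reduced-scale networks

A `scale` factor k divides every population count by k and multiplies the
recurrent conductances by k, preserving the mean synaptic drive per cell.
Finite-size fluctuations grow roughly as sqrt(k): reduced networks switch
between attractors far more often than the full circuit, decision basins
become shallower and broader, and their firing-rate positions shift
somewhat.  This is deliberate: analysis-facing runs use k = 4 or k = 8 so
that a single CPU can sample the stationary distribution in minutes, and
the frequent spontaneous switches are what make barrier and MFPT
measurements possible at desk-run durations.  Full-size (k = 1) runs
reproduce the slow, strongly committed dynamics (winner ~30 spikes/s at
w+ = 1.7, mu = 40) but need hours to sample a landscape; the CLI exposes
`--scale` for both regimes.

## Rates, landscape, convergence

Population rates are box-window counts: spikes of a population inside a
sliding window (50 ms, stepped by 5 ms) divided by population size and
window length; windows are right-aligned and partial windows are dropped.
Rates are quantized in steps of 1/(N_pop · window); landscape bins are
never made narrower than 1.5 quanta, otherwise the histogram shreds into
disconnected stripes.

The potential is U(r1, r2) = -ln P_ss(r1, r2) on a rectangular grid
(default 40-50 bins per axis spanning [0, max + one bin]).  U is defined
only on visited bins; unvisited bins are NaN, never floored, and barrier
paths may not traverse them.  Convergence of P_ss is monitored with the
relative Euclidean distance sigma = ||P_after - P_before||_2 /
||P_before||_2 between successive accumulations; stationary-landscape runs
stop when sigma drops below 0.06% or a trial budget is exhausted (the
result is flagged either way).

Minima are found by a watershed flood: visited bins join a union-find
structure in ascending U; a bin with no previously added neighbor seeds a
basin, and the bin that first connects two basins is their minimax saddle
(provably the min over 8-connected paths of the max U — the same value an
exhaustive path search returns).  The flood yields each basin's depth
(persistence: lowest escape saddle minus the minimum); minima shallower
than 0.5 U-units are sampling noise and pruned, as are minima in
disconnected visited islands carrying under 2% of the probability.  Minima
are labeled by winner-loser asymmetry: DS1/DS2 when |r1 - r2| is at least
5 spikes/s (about half the separation between the two decision basins in
this circuit), otherwise SS or DU according to whether the mean rate is
below or above 10 spikes/s.  A single 3x3 boxcar pass over U (visited
bins only) precedes the search by default.

Barrier metrics follow the saddle construction: BH1 = U_saddle - U_1,
BH2 = U_saddle - U_2, RB1 = BH1 - BH2 for the decision pair, and the same
construction for SS -> DS1 (RB_SS).

## Probability flux

The plane is coarse-grained into N1 x N2 equal boxes (default 20 x 20,
coarser than the landscape grid because each face needs many crossings).
For adjacent boxes, w_ab = (N_ab - N_ba)/t_total with directed face
crossings counted along the linearly interpolated segment between
consecutive samples (multi-box jumps cross several faces, ordered by the
segment parameter).  The flux vector at a box averages the net rates
through its two faces per direction; rates across the domain boundary are
zero by convention.  Gradient (equilibrium) dynamics give J -> 0; nonzero
curl marks broken detailed balance.

Pooling across trials counts crossings per trial — never across the seam
between two concatenated trials.  Per-box standard errors come from
across-block dispersion (default 10 contiguous blocks, or the trials
themselves); curl-direction statistics exclude boxes with ||J|| below 2
block-SEs.

## Kinetics

Attractor regions are ellipses (default circular, 5 spikes/s radius)
centered on landscape minima; overlapping regions are rejected.  When a
finite sample resolves only one of the two decision states as a minimum,
kinetic analyses may place the partner region at its mirror image across
the r1 = r2 diagonal — exact for the zero-coherence circuit, a close
approximation at the few-percent coherences studied — and the relative
barrier falls back to the potential difference read at the mirrored bin.  The MFPT
clock arms when the trajectory first enters the source region, a sample is
recorded at the first subsequent entry into the destination, and the clock
re-arms at the next source visit — the classic alternating estimator whose
expectation is the Kramers escape time (dwell plus failed excursions).
Observation windows that end mid-transition are dropped (censoring count
reported).  Transition paths use the tighter delimitation: from the last
point inside the source region to the first point inside the destination.
Average paths resample every raw path to a fixed number of points by even
index interpolation (transition durations differ, so index alignment is
forced) and average pointwise, with pointwise across-path standard errors.

## Surrogate ground truth

Three Euler-Maruyama Langevin families with known answers exercise the
whole analysis stack without the spiking simulator, in the same trajectory
format and positive units as network rates:

* double well: V = h((x/a)^2 - 1)^2 + k_y y^2 / 2, noise sqrt(2D);
  stationary law exp(-V/D), zero flux, and the 1D mean-exit-time double
  integral T(x0->xt) = (1/D) ∫ e^{V/D} ∫ e^{-V/D} as MFPT reference
  (defaults: a = 10, h = 2, k_y = 1, D = 1 — barrier 2 U-units, escape
  time ~300 s, so a 30,000 s run yields ~100 passages).
* triple well: drift D∇log p for a three-Gaussian mixture p, so p is the
  exact stationary law (wells laid out as SS/DS1/DS2); zero flux.
* linear rotational: dx = (-kI + omega R) x dt + sqrt(2D) dW with
  R = [[0,1],[-1,0]]; Gaussian stationary law with covariance (D/k)I
  (Lyapunov solution) and flux J = omega R x p_ss — divergence-free,
  clockwise for omega > 0.

The surrogates emulate the two-dimensional projected rate dynamics with
state-independent, isotropic noise; they do not reproduce the network's
rate quantization, discreteness of spikes, state-dependent noise, or the
latency structure of decisions.  Passing the surrogate oracles validates
the estimators (landscape, flux, MFPT, path machinery), not the biological
claims; network-facing conclusions rest on the spiking runs themselves.

## Protocol choices that were genuinely open

* Attractor censuses on reduced networks use one long from-rest run per
  seed (tens of seconds) with a fixed initial discard, because the
  reduced-scale circuit switches spontaneously and samples its basins
  ergodically; many short trials instead weight the landscape with each
  trial's undecided transient.  The parameter census workflow additionally
  supports pulsed multi-initial-condition trials.
* sigma's published formula is typographically garbled at the source; the
  relative-L2 reading above is used.  The convergence threshold 0.06% is
  retained.
* The depth-pruning threshold (0.5) and the island mass floor (2%) are
  package choices; no published value exists.
* Index-based (not arc-length) path resampling matches the literal reading
  of splitting trajectories evenly into equal numbers of points.
* Stimulus Poisson spikes share the background's external-AMPA gating
  variable; the current equation names a single external AMPA term.

## Known limitations

* Landscape and flux live on the 2D (r1, r2) projection; the underlying
  dynamics are higher-dimensional, so projected barriers and fluxes
  underestimate their full-dimensional counterparts.
* Reduced-scale topography is not guaranteed to match the full circuit's:
  noise scales with 1/sqrt(N), and basins that are distinct at full size
  can merge (or transient states linger longer) at scale 8.
* MFPT estimates are biased low when a large fraction of observation
  windows are censored; the censoring count is reported and a bias note
  emitted above 10%.
* The box-window rate estimator is the only one offered (no kernel
  smoothing), matching the counting definition the landscape is built on.
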