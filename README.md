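# spikescape

Non-equilibrium landscape, probability-flux and kinetic-path analysis of a
spiking winner-take-all decision circuit.

## What this is for

In the random-dot motion discrimination task, a subject judges the net
direction of a noisy dot field; the standard circuit model of the
underlying cortical computation is a fully connected network of leaky
integrate-and-fire neurons in which two stimulus-selective excitatory
pools (S1, S2) compete through shared feedback inhibition, with slow NMDA
reverberation sustaining the winner.  spikescape simulates that circuit
and then treats its population-rate dynamics as a stochastic system to be
quantified globally:

* **Potential landscape.**  The joint stationary distribution
  P_ss(r1, r2) of the two selective population rates defines a
  dimensionless potential U = −ln P_ss.  Minima of U are the attractors:
  the spontaneous state SS (both pools low), the decision states DS1/DS2
  (one pool high), and the double-up state DU (both high, at strong
  stimulus).
* **Probability flux.**  On a coarse grid of boxes, the net transition
  rate across each face, w_ab = (N_ab − N_ba)/t_total, assembles into a
  per-box flux vector J.  J = 0 is detailed balance; the circuit's
  nonzero curl flux makes forward and backward transition paths between
  decision states irreversible.
* **Barriers and kinetics.**  For a pair of minima, BH_i = U_saddle − U_i
  and RB1 = BH1 − BH2 quantify relative stability; mean first-passage
  times between elliptic attractor regions measure the same stability
  kinetically, and averaged transition paths ψ(t) trace how changes of
  mind traverse the landscape.

A surrogate module generates 2D Langevin trajectories (double well, triple
well, rotational Ornstein–Uhlenbeck) with known stationary law, flux and
mean exit time, so every estimator is validated against closed-form ground
truth without the expensive spiking simulation.

## Worked example

Generate a triple-well surrogate (a stand-in for the tristable decision
landscape with known ground truth), estimate its landscape and kinetics:

```bash
spikescape surrogate --family triple_well --duration 4000 -D 9 --seed 7 --out tw.h5
spikescape landscape --input tw.h5 --rate-threshold 25 --out out_ls
spikescape mfpt --input tw.h5 --rate-threshold 25 --from SS --to DS1
```

which prints (seed 7):

```
wrote 80000 samples to tw.h5
{"n_attractors": 3, "labels": ["SS", "DS1", "DS2"], "converged": true, "sigma_history": []}
{"K": 4, "mfpt_s": 650.8125, "se_s": 255.45866460724454, "n_censored": 0}
```

Three minima — the spontaneous state and the two decision states — and
four observed SS→DS1 passages (the "decision" transition) with a mean
first-passage time of ~651 s of surrogate time.

The spiking circuit itself runs through the same interface, e.g. a
quarter-size network under a zero-coherence stimulus:

```bash
spikescape landscape --scale 4 --mu 58 --seed 1 --out out_net
```

or from Python:

```python
from spikescape import NetworkConfig, StimulusSpec, run_trial, \
    compute_population_rates

raster = run_trial(NetworkConfig(w_plus=1.61, scale=4),
                   StimulusSpec(mu=58, c=0.0), duration=10_000, seed=1)
rates = compute_population_rates(raster)   # 50 ms windows, 5 ms stride
print(raster.mean_rates())
```

Subcommands: `simulate`, `rates`, `landscape`, `flux`, `paths`, `mfpt`,
`ramp` (staircase-stimulus hysteresis), `sweep` (coherence sweep of RB1
and MFPT), `census` (attractor counts over the (w+, mu) plane),
`surrogate`.  See `docs/methods.md` for the model, estimators, defaults
and their rationale.

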