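"""Conductance-based leaky integrate-and-fire simulation of the decision circuit.

The membrane equation C_m dV/dt = -g_L (V - V_L) - I_syn is integrated with a
second-order Runge-Kutta (Heun) scheme at dt = 0.02 ms together with the
synaptic gating dynamics:

    ds_AMPA/dt = -s_AMPA/tau_AMPA            (+1 per presynaptic spike)
    dx/dt      = -x/tau_NMDA_rise            (+1 per presynaptic spike)
    ds_NMDA/dt = -s_NMDA/tau_NMDA_decay + alpha * x * (1 - s_NMDA)
    ds_GABA/dt = -s_GABA/tau_GABA            (+1 per presynaptic spike)

Spike and Poisson increments are discrete jumps applied between RK2 steps
(delta inputs are not smooth, so only the decay/rise terms receive the RK2
treatment).  Spikes are detected at step boundaries; the potential is clamped
to V_reset for the refractory period.  Because weights depend only on the
(source population, target population) pair, recurrent drive is accumulated
as population sums of presynaptic gating variables, making each step O(N).

External drive (2.4 kHz background for every neuron, plus the stimulus rates
mu(1+c) / mu(1-c) for S1 / S2 during the stimulus window) is a superposed
Poisson process feeding one shared external-AMPA gating variable per neuron;
per-step event counts are sampled exactly as Poisson variates.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .params import (NetworkConfig, StimulusSpec, ConnectivityMatrix,
                     build_network, POP_S1, POP_S2, POP_NS, POP_I, POP_NAMES)
from .raster import SpikeRaster

logger = logging.getLogger(__name__)


class SimulationDivergedError(RuntimeError):
    """Raised when V or a gating variable becomes non-finite."""


@dataclass
class NetworkState:
    """Dynamic variables of every neuron at time t (all arrays length N)."""

    V: np.ndarray
    ref_until: np.ndarray     # ms; V clamped to V_reset while t < ref_until
    s_ampa_ext: np.ndarray
    s_ampa: np.ndarray
    x_nmda: np.ndarray
    s_nmda: np.ndarray
    s_gaba: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.V.copy(), self.ref_until.copy(),
                            self.s_ampa_ext.copy(), self.s_ampa.copy(),
                            self.x_nmda.copy(), self.s_nmda.copy(),
                            self.s_gaba.copy(), self.t)


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _run_chunk(n_steps, t0, dt,
               V, ref_until, s_ext, s_ampa, x_nmda, s_nmda, s_gaba,
               gstart, gsize, glam,       # (4,) per-population blocks and
                                          # external rates per ms
               pop, is_exc,               # (N,)
               C_pF, g_L, V_L, V_th, V_reset, tau_ref, I_inj,
               g_ext, g_rec_a, g_nmda, g_gaba,
               W,                         # (3, 4) excitatory weights
               V_E, V_I, inv_tau_a, inv_tau_nd, inv_tau_nr, inv_tau_g,
               alpha, Mg,
               spike_flags):              # (n_steps, N) uint8 out
    N = V.shape[0]
    Vp = np.empty(N)
    se_p = np.empty(N)
    sa_p = np.empty(N)
    x_p = np.empty(N)
    sn_p = np.empty(N)
    sg_p = np.empty(N)
    dV1 = np.empty(N)

    for k in range(n_steps):
        t = t0 + k * dt
        # --- external Poisson jumps --------------------------------------
        # rates are uniform within a population, so the per-step event total
        # of each block is Poisson(n*lam*dt) and events scatter uniformly
        # over the block's neurons (superposition/thinning; exact counts)
        for g in range(4):
            lg = glam[g] * dt * gsize[g]
            if lg > 0.0:
                c = np.random.poisson(lg)
                for _ in range(c):
                    i = gstart[g] + int(np.random.random() * gsize[g])
                    if i >= gstart[g] + gsize[g]:
                        i = gstart[g] + gsize[g] - 1
                    s_ext[i] += 1.0

        # --- stage 1: population sums and derivatives ---------------------
        sumA0 = 0.0; sumA1 = 0.0; sumA2 = 0.0
        sumN0 = 0.0; sumN1 = 0.0; sumN2 = 0.0
        sumG = 0.0
        for i in range(N):
            p = pop[i]
            if p == 0:
                sumA0 += s_ampa[i]; sumN0 += s_nmda[i]
            elif p == 1:
                sumA1 += s_ampa[i]; sumN1 += s_nmda[i]
            elif p == 2:
                sumA2 += s_ampa[i]; sumN2 += s_nmda[i]
            else:
                sumG += s_gaba[i]
        A_t = np.empty(4); N_t = np.empty(4)
        for tgt in range(4):
            A_t[tgt] = W[0, tgt] * sumA0 + W[1, tgt] * sumA1 + W[2, tgt] * sumA2
            N_t[tgt] = W[0, tgt] * sumN0 + W[1, tgt] * sumN1 + W[2, tgt] * sumN2

        for i in range(N):
            refr = t < ref_until[i] - 1e-12
            if refr:
                dV1[i] = 0.0
                Vp[i] = V_reset[i]
            else:
                v = V[i]
                gate = 1.0 / (1.0 + Mg * np.exp(-0.062 * v) / 3.57)
                Isyn = (g_ext[i] * (v - V_E) * s_ext[i]
                        + g_rec_a[i] * (v - V_E) * A_t[pop[i]]
                        + g_nmda[i] * (v - V_E) * gate * N_t[pop[i]]
                        + g_gaba[i] * (v - V_I) * sumG)
                dV1[i] = (-g_L[i] * (v - V_L[i]) - Isyn + I_inj[i]) / C_pF[i]
                Vp[i] = v + dt * dV1[i]
            se_p[i] = s_ext[i] * (1.0 - dt * inv_tau_a)
            sa_p[i] = s_ampa[i] * (1.0 - dt * inv_tau_a)
            x_p[i] = x_nmda[i] * (1.0 - dt * inv_tau_nr)
            dsn = -s_nmda[i] * inv_tau_nd + alpha * x_nmda[i] * (1.0 - s_nmda[i])
            sn_p[i] = s_nmda[i] + dt * dsn
            sg_p[i] = s_gaba[i] * (1.0 - dt * inv_tau_g)

        # --- stage 2: derivatives at the predictor ------------------------
        sumA0 = 0.0; sumA1 = 0.0; sumA2 = 0.0
        sumN0 = 0.0; sumN1 = 0.0; sumN2 = 0.0
        sumG = 0.0
        for i in range(N):
            p = pop[i]
            if p == 0:
                sumA0 += sa_p[i]; sumN0 += sn_p[i]
            elif p == 1:
                sumA1 += sa_p[i]; sumN1 += sn_p[i]
            elif p == 2:
                sumA2 += sa_p[i]; sumN2 += sn_p[i]
            else:
                sumG += sg_p[i]
        for tgt in range(4):
            A_t[tgt] = W[0, tgt] * sumA0 + W[1, tgt] * sumA1 + W[2, tgt] * sumA2
            N_t[tgt] = W[0, tgt] * sumN0 + W[1, tgt] * sumN1 + W[2, tgt] * sumN2

        t_next = t0 + (k + 1) * dt
        for i in range(N):
            refr = t < ref_until[i] - 1e-12
            if not refr:
                v = Vp[i]
                gate = 1.0 / (1.0 + Mg * np.exp(-0.062 * v) / 3.57)
                Isyn = (g_ext[i] * (v - V_E) * se_p[i]
                        + g_rec_a[i] * (v - V_E) * A_t[pop[i]]
                        + g_nmda[i] * (v - V_E) * gate * N_t[pop[i]]
                        + g_gaba[i] * (v - V_I) * sumG)
                dV2 = (-g_L[i] * (v - V_L[i]) - Isyn + I_inj[i]) / C_pF[i]
                V[i] = V[i] + 0.5 * dt * (dV1[i] + dV2)
            else:
                V[i] = V_reset[i]
            # Heun update of gating (decays are linear; NMDA rise nonlinear)
            s_ext[i] = s_ext[i] + 0.5 * dt * (-s_ext[i] * inv_tau_a
                                              - se_p[i] * inv_tau_a)
            s_ampa[i] = s_ampa[i] + 0.5 * dt * (-s_ampa[i] * inv_tau_a
                                                - sa_p[i] * inv_tau_a)
            dsn1 = (-s_nmda[i] * inv_tau_nd
                    + alpha * x_nmda[i] * (1.0 - s_nmda[i]))
            dsn2 = (-sn_p[i] * inv_tau_nd
                    + alpha * x_p[i] * (1.0 - sn_p[i]))
            s_nmda[i] = s_nmda[i] + 0.5 * dt * (dsn1 + dsn2)
            x_nmda[i] = x_nmda[i] + 0.5 * dt * (-x_nmda[i] * inv_tau_nr
                                                - x_p[i] * inv_tau_nr)
            s_gaba[i] = s_gaba[i] + 0.5 * dt * (-s_gaba[i] * inv_tau_g
                                                - sg_p[i] * inv_tau_g)

            # --- threshold crossing at the step boundary ------------------
            if (not refr) and V[i] >= V_th[i]:
                spike_flags[k, i] = 1
                V[i] = V_reset[i]
                ref_until[i] = t_next + tau_ref[i]
                if is_exc[i]:
                    s_ampa[i] += 1.0
                    x_nmda[i] += 1.0
                else:
                    s_gaba[i] += 1.0

        # --- divergence guard --------------------------------------------
        for i in range(N):
            if not (np.isfinite(V[i]) and np.isfinite(s_nmda[i])
                    and np.isfinite(s_ampa[i]) and np.isfinite(s_ext[i])):
                return k, i
    return -1, -1


class Network:
    """A configured circuit: builds per-neuron arrays and runs trials."""

    def __init__(self, config: NetworkConfig,
                 connectivity: Optional[ConnectivityMatrix] = None):
        self.config = config
        self.connectivity = connectivity or build_network(config)
        sizes = config.population_sizes()
        N = config.N_total
        pop = np.empty(N, dtype=np.int8)
        idx = 0
        self.pop_slices: dict[str, slice] = {}
        for p, name in enumerate(POP_NAMES):
            n = sizes[name]
            pop[idx:idx + n] = p
            self.pop_slices[name] = slice(idx, idx + n)
            idx += n
        self.pop = pop
        self.is_exc = pop != POP_I

        nE, nI = config.neuron_E, config.neuron_I
        sE, sI = config.syn_E, config.syn_I

        def per_neuron(val_E, val_I):
            return np.where(self.is_exc, val_E, val_I).astype(float)

        self.C_pF = per_neuron(nE.C_m, nI.C_m) * 1000.0  # nF -> pF so that
        # dV/dt = I[pA]/C[pF] comes out in mV/ms
        self.g_L = per_neuron(nE.g_L, nI.g_L)
        self.V_L = per_neuron(nE.V_L, nI.V_L)
        self.V_th = per_neuron(nE.V_th, nI.V_th)
        self.V_reset = per_neuron(nE.V_reset, nI.V_reset)
        self.tau_ref = per_neuron(nE.tau_ref, nI.tau_ref)
        # scaled recurrent conductances keep the mean drive fixed when the
        # population counts are divided by `scale`
        k = float(config.scale)
        self.g_ext = per_neuron(sE.g_ext_AMPA, sI.g_ext_AMPA)
        self.g_rec_a = per_neuron(sE.g_rec_AMPA, sI.g_rec_AMPA) * k
        self.g_nmda = per_neuron(sE.g_NMDA, sI.g_NMDA) * k
        self.g_gaba = per_neuron(sE.g_GABA, sI.g_GABA) * k
        self.I_inj = np.zeros(N)
        self.syn_shared = sE  # reversal potentials / kinetics are shared

    # -- state -------------------------------------------------------------

    def init_state(self) -> NetworkState:
        N = self.config.N_total
        return NetworkState(V=self.V_L.copy(),
                            ref_until=np.zeros(N),
                            s_ampa_ext=np.zeros(N),
                            s_ampa=np.zeros(N),
                            x_nmda=np.zeros(N),
                            s_nmda=np.zeros(N),
                            s_gaba=np.zeros(N),
                            t=0.0)

    def external_rates(self, stimulus: Optional[StimulusSpec],
                       t: float) -> np.ndarray:
        """Per-neuron external Poisson rate (events/ms) at time t."""
        lam = np.full(self.config.N_total, self.config.v_ext)  # kHz == /ms
        if stimulus is not None and stimulus.t_on <= t < stimulus.t_off:
            lam[self.pop_slices["S1"]] += stimulus.mu1 / 1000.0
            lam[self.pop_slices["S2"]] += stimulus.mu2 / 1000.0
        return lam

    def step(self, state: NetworkState, n_steps: int = 1,
             stimulus: Optional[StimulusSpec] = None,
             lam: Optional[np.ndarray] = None) -> np.ndarray:
        """Advance the state in place by n_steps; returns (n_steps, N) flags.

        ``lam`` overrides the per-neuron external rate (events/ms); it must
        be constant within each population.  Pass an all-zero array to
        integrate the deterministic skeleton.
        """
        cfg = self.config
        syn = self.syn_shared
        if lam is None:
            lam = self.external_rates(stimulus, state.t)
        gstart = np.empty(4, np.int64)
        gsize = np.empty(4, np.int64)
        glam = np.empty(4, float)
        for g, name in enumerate(POP_NAMES):
            sl = self.pop_slices[name]
            gstart[g], gsize[g] = sl.start, sl.stop - sl.start
            block = np.asarray(lam[sl], float)
            if block.size and np.ptp(block) > 1e-12:
                raise ValueError(
                    "external rate must be uniform within each population")
            glam[g] = block[0] if block.size else 0.0
        flags = np.zeros((n_steps, cfg.N_total), dtype=np.uint8)
        bad_step, bad_neuron = _run_chunk(
            n_steps, state.t, cfg.dt,
            state.V, state.ref_until, state.s_ampa_ext, state.s_ampa,
            state.x_nmda, state.s_nmda, state.s_gaba,
            gstart, gsize, glam, self.pop, self.is_exc,
            self.C_pF, self.g_L, self.V_L, self.V_th, self.V_reset,
            self.tau_ref, self.I_inj,
            self.g_ext, self.g_rec_a, self.g_nmda, self.g_gaba,
            self.connectivity.W_exc,
            syn.V_E, syn.V_I, 1.0 / syn.tau_AMPA, 1.0 / syn.tau_NMDA_decay,
            1.0 / syn.tau_NMDA_rise, 1.0 / syn.tau_GABA, syn.alpha, syn.Mg,
            flags)
        if bad_step >= 0:
            raise SimulationDivergedError(
                f"non-finite state at t={state.t + bad_step * cfg.dt:.3f} ms "
                f"(step {bad_step}, neuron {bad_neuron})")
        state.t += n_steps * cfg.dt
        return flags


def run_trial(config: NetworkConfig,
              stimulus: Optional[StimulusSpec] = None,
              duration: float = 2000.0,
              seed: int = 0,
              network: Optional[Network] = None,
              chunk_ms: float = 100.0) -> SpikeRaster:
    """Simulate one trial and return its spike raster.

    Background Poisson drive runs for the whole trial; the stimulus adds
    mu(1+c) / mu(1-c) Hz Poisson trains to S1 / S2 during [t_on, t_off),
    merged into the same external-AMPA channel.  Bit-identical for identical
    (config, stimulus, duration, seed).
    """
    if duration <= 0:
        raise ValueError("duration must be positive (ms)")
    net = network if network is not None else Network(config)
    _seed_numba(np.uint32(seed))
    state = net.init_state()
    n_total = int(round(duration / config.dt))

    # chunk boundaries, split at the stimulus window edges so the external
    # rate is constant within each chunk
    marks = {0, n_total}
    if stimulus is not None:
        for edge in (stimulus.t_on, stimulus.t_off):
            if np.isfinite(edge) and 0 < edge < duration:
                marks.add(int(round(edge / config.dt)))
    steps_per_chunk = max(1, int(round(chunk_ms / config.dt)))
    bounds = sorted(marks)
    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []
    t_start = time.perf_counter()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        k = lo
        while k < hi:
            n = min(steps_per_chunk, hi - k)
            lam = net.external_rates(stimulus, (k + 0.5) * config.dt)
            flags = net.step(state, n, lam=lam)
            st, ids = np.nonzero(flags)
            spike_steps.append((st + k + 1) * config.dt)
            spike_ids.append(ids)
            k += n
    times = np.concatenate(spike_steps) if spike_steps else np.empty(0)
    ids = (np.concatenate(spike_ids) if spike_ids
           else np.empty(0, dtype=np.int64))
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(neuron_ids=ids[order].astype(np.int64),
                         times=times[order],
                         pop_of_neuron=net.pop.copy(), duration=duration)
    wall = time.perf_counter() - t_start
    logger.info("trial done: %.0f ms simulated, %d spikes, %.1f s wall; "
                "mean rates %s", duration, raster.n_spikes, wall,
                {k: round(v, 2) for k, v in raster.mean_rates().items()})
    return raster
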