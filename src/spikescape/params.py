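"""Model parameters for the four-population winner-take-all spiking circuit.

The circuit contains two stimulus-selective excitatory populations (S1, S2),
one non-selective excitatory population (NS) and one population of inhibitory
interneurons (I).  Neurons are leaky integrate-and-fire with conductance-based
AMPA, NMDA and GABA synapses; the network is fully connected with
population-structured dimensionless weights.

Units used throughout: membrane capacitance nF, conductances nS, voltages mV,
times ms, external Poisson rates kHz (per-neuron), stimulus rates Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# Population index convention used by every module in the package.
POP_S1, POP_S2, POP_NS, POP_I = 0, 1, 2, 3
POP_NAMES = ("S1", "S2", "NS", "I")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire single-cell parameters."""

    C_m: float      # membrane capacitance, nF
    g_L: float      # leak conductance, nS
    V_L: float      # leak reversal, mV
    V_th: float     # spike threshold, mV
    V_reset: float  # post-spike reset, mV
    tau_ref: float  # absolute refractory period, ms

    def __post_init__(self) -> None:
        if not (self.V_th > self.V_reset and self.V_th > self.V_L):
            raise ValueError("require V_th > V_reset and V_th > V_L")
        if self.C_m <= 0 or self.g_L <= 0 or self.tau_ref < 0:
            raise ValueError("C_m, g_L must be positive; tau_ref non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms (C_m nF / g_L nS * 1000)."""
        return 1000.0 * self.C_m / self.g_L


#: Pyramidal-cell preset.
EXCITATORY_NEURON = NeuronParams(C_m=0.5, g_L=25.0, V_L=-70.0, V_th=-50.0,
                                 V_reset=-55.0, tau_ref=2.0)
#: Interneuron preset.
INHIBITORY_NEURON = NeuronParams(C_m=0.2, g_L=20.0, V_L=-70.0, V_th=-50.0,
                                 V_reset=-55.0, tau_ref=1.0)


@dataclass(frozen=True)
class SynapseParams:
    """Conductances and kinetics of the synaptic channels onto one cell class."""

    g_ext_AMPA: float   # nS, external (background + stimulus) AMPA
    g_rec_AMPA: float   # nS, recurrent AMPA
    g_NMDA: float       # nS, recurrent NMDA
    g_GABA: float       # nS, recurrent GABA
    V_E: float = 0.0    # mV, excitatory reversal
    V_I: float = -70.0  # mV, inhibitory reversal
    tau_AMPA: float = 2.0          # ms
    tau_NMDA_decay: float = 100.0  # ms
    tau_NMDA_rise: float = 2.0     # ms
    tau_GABA: float = 5.0          # ms
    alpha: float = 0.5             # 1/ms, NMDA rise->saturation coupling
    Mg: float = 1.0                # mM, extracellular magnesium

    def __post_init__(self) -> None:
        for name in ("g_ext_AMPA", "g_rec_AMPA", "g_NMDA", "g_GABA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def nmda_gate(self, V: float) -> float:
        """Voltage-dependent magnesium unblock factor, in (0, 1]."""
        return 1.0 / (1.0 + self.Mg * np.exp(-0.062 * V) / 3.57)


#: Synapses onto pyramidal cells.
SYNAPSES_ONTO_EXCITATORY = SynapseParams(g_ext_AMPA=2.1, g_rec_AMPA=0.05,
                                         g_NMDA=0.165, g_GABA=1.3)
#: Synapses onto interneurons.
SYNAPSES_ONTO_INHIBITORY = SynapseParams(g_ext_AMPA=1.62, g_rec_AMPA=0.04,
                                         g_NMDA=0.13, g_GABA=1.0)


def derive_w_minus(w_plus: float, f: float) -> float:
    """Depressed cross-population weight compensating a potentiated w_plus.

    w_minus = 1 - f (w_plus - 1) / (1 - f), chosen so that the total recurrent
    excitatory drive onto a selective cell in the spontaneous state,
    f*w_plus + (1 - f)*w_minus = 1, does not change with w_plus.

    Only the potentiated regime w_plus >= 1 is meaningful; smaller values are
    rejected.
    """
    if not (0.0 < f < 0.5):
        raise ValueError(f"selective fraction f must lie in (0, 0.5), got {f}")
    if w_plus < 1.0:
        raise ValueError(
            f"w_plus={w_plus} < 1: the compensation rule applies to the "
            "potentiated regime only")
    return 1.0 - f * (w_plus - 1.0) / (1.0 - f)


@dataclass(frozen=True)
class StimulusSpec:
    """Motion stimulus: Poisson drive mu(1+c) to S1 and mu(1-c) to S2 (Hz)."""

    mu: float          # overall stimulus strength, Hz
    c: float = 0.0     # motion coherence, fraction in [-1, 1]
    t_on: float = 0.0       # ms
    t_off: float = np.inf   # ms (np.inf = until end of trial)

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("stimulus strength mu must be >= 0")
        if abs(self.c) > 1:
            raise ValueError("coherence |c| must be <= 1")
        if self.t_off < self.t_on:
            raise ValueError("t_off must be >= t_on")

    @property
    def mu1(self) -> float:
        return self.mu * (1.0 + self.c)

    @property
    def mu2(self) -> float:
        return self.mu * (1.0 - self.c)


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and numerical configuration of the circuit.

    ``scale`` divides every population count by the given integer and
    multiplies the recurrent conductances by the same factor, preserving the
    mean recurrent drive per cell while shrinking the network (finite-size
    fluctuations grow as sqrt(scale)).  scale=1 is the full published circuit.
    """

    w_plus: float = 1.61
    N_E: int = 1600
    N_I: int = 400
    f: float = 0.15
    v_ext: float = 2.4       # kHz background Poisson rate per neuron
    dt: float = 0.02         # ms integration step
    scale: int = 1
    neuron_E: NeuronParams = EXCITATORY_NEURON
    neuron_I: NeuronParams = INHIBITORY_NEURON
    syn_E: SynapseParams = SYNAPSES_ONTO_EXCITATORY
    syn_I: SynapseParams = SYNAPSES_ONTO_INHIBITORY

    def __post_init__(self) -> None:
        if self.w_plus < 1.0:
            raise ValueError("w_plus must be >= 1")
        if not (0.0 < self.f < 0.5):
            raise ValueError("f must lie in (0, 0.5)")
        if self.v_ext < 0 or self.dt <= 0:
            raise ValueError("v_ext >= 0 and dt > 0 required")
        if self.scale < 1 or int(self.scale) != self.scale:
            raise ValueError("scale must be a positive integer")
        # population sizes must come out integral after scaling
        for label, value in (("N_S1", self.f * self.N_E / self.scale),
                             ("N_NS", (1 - 2 * self.f) * self.N_E / self.scale),
                             ("N_I", self.N_I / self.scale)):
            if abs(value - round(value)) > 1e-9 or round(value) < 1:
                raise ValueError(
                    f"population {label} = {value} is not a positive integer "
                    f"after scaling by {self.scale}")

    @property
    def w_minus(self) -> float:
        return derive_w_minus(self.w_plus, self.f)

    @property
    def N_S1(self) -> int:
        return round(self.f * self.N_E / self.scale)

    @property
    def N_S2(self) -> int:
        return self.N_S1

    @property
    def N_NS(self) -> int:
        return round((1 - 2 * self.f) * self.N_E / self.scale)

    @property
    def N_I_scaled(self) -> int:
        return round(self.N_I / self.scale)

    @property
    def N_total(self) -> int:
        return 2 * self.N_S1 + self.N_NS + self.N_I_scaled

    def population_sizes(self) -> dict[str, int]:
        return {"S1": self.N_S1, "S2": self.N_S2, "NS": self.N_NS,
                "I": self.N_I_scaled}

    def with_(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Population-structured dimensionless weights of the fully connected net.

    ``W_exc[src, tgt]`` is the weight of every AMPA/NMDA synapse from a neuron
    in excitatory source population ``src`` (S1, S2, NS) onto a neuron of
    target population ``tgt`` (S1, S2, NS, I).  GABA synapses are unweighted
    (weight 1); inhibition enters through the sign of (V - V_I) in the
    current equation.
    """

    W_exc: np.ndarray          # shape (3, 4), float
    sizes: dict[str, int]

    def weight(self, src: str, tgt: str) -> float:
        if src == "I":
            return 1.0
        return float(self.W_exc[POP_NAMES.index(src), POP_NAMES.index(tgt)])


def build_network(config: NetworkConfig) -> ConnectivityMatrix:
    """Assemble the population weight structure for a configuration.

    Within-S1 and within-S2 synapses carry the potentiated weight w_plus;
    S1<->S2 and NS->S1/S2 carry the compensating depressed weight w_minus;
    every other weight is 1.
    """
    wp, wm = config.w_plus, config.w_minus
    W = np.ones((3, 4))
    W[POP_S1, POP_S1] = wp
    W[POP_S2, POP_S2] = wp
    W[POP_S1, POP_S2] = wm
    W[POP_S2, POP_S1] = wm
    W[POP_NS, POP_S1] = wm
    W[POP_NS, POP_S2] = wm
    return ConnectivityMatrix(W_exc=W, sizes=config.population_sizes())
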