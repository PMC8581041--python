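"""Spike raster container and on-disk formats (HDF5 and two-column CSV)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import h5py

from .params import POP_NAMES


@dataclass
class SpikeRaster:
    """Spike events of one simulated trial.

    Attributes
    ----------
    neuron_ids : int array, index of the spiking neuron per event
    times : float array (ms), non-decreasing event times
    pop_of_neuron : int array of length N, population index (0=S1, 1=S2,
        2=NS, 3=I) of every neuron in the network
    duration : float (ms), simulated span (events lie in (0, duration])
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    pop_of_neuron: np.ndarray
    duration: float

    @property
    def n_neurons(self) -> int:
        return len(self.pop_of_neuron)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def population_neurons(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_of_neuron == POP_NAMES.index(pop))

    def population_spikes(self, pop: str) -> np.ndarray:
        """Spike times (ms) of every neuron in the named population."""
        mask = self.pop_of_neuron[self.neuron_ids] == POP_NAMES.index(pop)
        return self.times[mask]

    def mean_rates(self) -> dict[str, float]:
        """Trial-averaged firing rate per population, spikes/s."""
        out = {}
        for pop in POP_NAMES:
            n = len(self.population_neurons(pop))
            if n == 0:
                continue
            out[pop] = len(self.population_spikes(pop)) / n / (self.duration / 1000.0)
        return out

    def min_isi(self) -> float:
        """Smallest inter-spike interval of any single neuron (ms)."""
        best = np.inf
        order = np.lexsort((self.times, self.neuron_ids))
        ids, ts = self.neuron_ids[order], self.times[order]
        same = ids[1:] == ids[:-1]
        if same.any():
            best = float(np.min(ts[1:][same] - ts[:-1][same]))
        return best

    # ---- persistence -----------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("neuron_id", data=self.neuron_ids.astype(np.int32))
            h5.create_dataset("time_ms", data=self.times.astype(np.float64))
            h5.create_dataset("pop_of_neuron",
                              data=self.pop_of_neuron.astype(np.int8))
            h5.attrs["duration_ms"] = self.duration
            h5.attrs["pop_names"] = ",".join(POP_NAMES)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as h5:
            return cls(neuron_ids=h5["neuron_id"][:].astype(np.int64),
                       times=h5["time_ms"][:],
                       pop_of_neuron=h5["pop_of_neuron"][:].astype(np.int8),
                       duration=float(h5.attrs["duration_ms"]))

    def to_csv(self, path) -> None:
        """Two-column event table plus a per-neuron population table footer.

        Events go to ``path``; neuron membership goes to ``path`` with a
        ``.neurons.csv`` suffix so both are plain CSV.
        """
        pd.DataFrame({"neuron_id": self.neuron_ids,
                      "time_ms": self.times}).to_csv(path, index=False)
        side = str(path) + ".neurons.csv"
        pd.DataFrame({"neuron_id": np.arange(self.n_neurons),
                      "population": [POP_NAMES[p] for p in self.pop_of_neuron],
                      "duration_ms": self.duration}).to_csv(side, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeRaster":
        ev = pd.read_csv(path)
        side = pd.read_csv(str(path) + ".neurons.csv")
        pops = np.array([POP_NAMES.index(p) for p in side["population"]],
                        dtype=np.int8)
        return cls(neuron_ids=ev["neuron_id"].to_numpy(np.int64),
                   times=ev["time_ms"].to_numpy(float),
                   pop_of_neuron=pops,
                   duration=float(side["duration_ms"].iloc[0]))
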