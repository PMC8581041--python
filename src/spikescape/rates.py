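"""Population firing-rate trajectories from spike rasters.

Rates are simple box-window counts: the total number of spikes emitted by a
population inside a sliding window (default 50 ms, sliding by 5 ms), divided
by the population size and the window length.  Window labels are
right-aligned: the sample at time t summarizes the interval (t - window, t].
Partial windows at the trajectory edges are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import h5py

from .params import POP_NAMES
from .raster import SpikeRaster

_COLUMNS = ("r1", "r2", "r_NS", "r_I")
_COL_OF_POP = dict(zip(POP_NAMES, _COLUMNS))


@dataclass
class RateTrajectory:
    """Time series of population-averaged rates in the (r1, r2) plane.

    t is in ms; rates are spikes/s.  r_NS and r_I may be absent (None) for
    surrogate trajectories.
    """

    t: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    r_NS: Optional[np.ndarray] = None
    r_I: Optional[np.ndarray] = None
    window: float = 50.0
    stride: float = 5.0

    def __post_init__(self) -> None:
        if len(self.t) != len(self.r1) or len(self.t) != len(self.r2):
            raise ValueError("t, r1, r2 must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (r1, r2) samples."""
        return np.column_stack([self.r1, self.r2])

    def reversed(self) -> "RateTrajectory":
        """Time-reversed copy (sample order flipped, clock rebuilt forward)."""
        return RateTrajectory(t=self.t[0] + (self.t[-1] - self.t[::-1]),
                              r1=self.r1[::-1].copy(), r2=self.r2[::-1].copy(),
                              r_NS=None if self.r_NS is None else self.r_NS[::-1].copy(),
                              r_I=None if self.r_I is None else self.r_I[::-1].copy(),
                              window=self.window, stride=self.stride)

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "r1": self.r1, "r2": self.r2}
        if self.r_NS is not None:
            data["r_NS"] = self.r_NS
        if self.r_I is not None:
            data["r_I"] = self.r_I
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window: float = 50.0,
                 stride: float = 5.0) -> "RateTrajectory":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(float), r1=df["r1"].to_numpy(float),
                   r2=df["r2"].to_numpy(float),
                   r_NS=df["r_NS"].to_numpy(float) if "r_NS" in df else None,
                   r_I=df["r_I"].to_numpy(float) if "r_I" in df else None,
                   window=window, stride=stride)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("t", data=self.t)
            h5.create_dataset("r1", data=self.r1)
            h5.create_dataset("r2", data=self.r2)
            if self.r_NS is not None:
                h5.create_dataset("r_NS", data=self.r_NS)
            if self.r_I is not None:
                h5.create_dataset("r_I", data=self.r_I)
            h5.attrs["window_ms"] = self.window
            h5.attrs["stride_ms"] = self.stride

    @classmethod
    def from_hdf5(cls, path) -> "RateTrajectory":
        with h5py.File(path, "r") as h5:
            return cls(t=h5["t"][:], r1=h5["r1"][:], r2=h5["r2"][:],
                       r_NS=h5["r_NS"][:] if "r_NS" in h5 else None,
                       r_I=h5["r_I"][:] if "r_I" in h5 else None,
                       window=float(h5.attrs["window_ms"]),
                       stride=float(h5.attrs["stride_ms"]))


def load_trajectory(path) -> RateTrajectory:
    """Load a trajectory from HDF5 (.h5/.hdf5) or CSV by file extension."""
    s = str(path)
    if s.endswith((".h5", ".hdf5")):
        return RateTrajectory.from_hdf5(path)
    return RateTrajectory.from_csv(path)


def _window_counts(times: np.ndarray, t_ends: np.ndarray,
                   window: float) -> np.ndarray:
    """Spike counts in (t - window, t] for each right-aligned window end."""
    times = np.sort(times)
    hi = np.searchsorted(times, t_ends, side="right")
    lo = np.searchsorted(times, t_ends - window, side="right")
    return hi - lo


def compute_population_rates(raster: SpikeRaster, window: float = 50.0,
                             stride: float = 5.0,
                             include_all: bool = True) -> RateTrajectory:
    """Sliding-window population rates from a raster.

    For each window end t in {window, window+stride, ...} <= duration, the
    rate of a population is (spikes of its members in (t-window, t]) /
    (population size * window in seconds).
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    if raster.duration <= 0:
        raise ValueError("raster has zero duration")
    n_windows = int(np.floor((raster.duration - window) / stride)) + 1
    if n_windows < 1:
        raise ValueError("raster shorter than one window")
    t_ends = window + stride * np.arange(n_windows)
    win_s = window / 1000.0

    cols: dict[str, np.ndarray] = {}
    pops = POP_NAMES if include_all else POP_NAMES[:2]
    for pop in pops:
        n = len(raster.population_neurons(pop))
        counts = _window_counts(raster.population_spikes(pop), t_ends, window)
        cols[_COL_OF_POP[pop]] = counts / (n * win_s) if n else np.zeros(n_windows)
    return RateTrajectory(t=t_ends, r1=cols["r1"], r2=cols["r2"],
                          r_NS=cols.get("r_NS"), r_I=cols.get("r_I"),
                          window=window, stride=stride)


def pool_trajectories(trajectories: Sequence[RateTrajectory],
                      discard_ms: float = 0.0) -> np.ndarray:
    """Concatenate (r1, r2) samples across trials for stationary statistics.

    ``discard_ms`` drops the initial transient of each trajectory (measured
    from its first sample time).
    """
    chunks = []
    for traj in trajectories:
        keep = traj.t >= traj.t[0] + discard_ms
        chunks.append(traj.points[keep])
    if not chunks:
        raise ValueError("no trajectories to pool")
    return np.vstack(chunks)
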