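"""Attractor-region kinetics: first-passage times and averaged transition paths.

An attractor region is a small ellipse centered on a landscape minimum.  A
transition path from region B_i to region B_j starts at the last trajectory
point inside B_i before the excursion that reaches B_j and ends at the first
point inside B_j; its duration is a first-passage-time sample, and the mean
over samples is the MFPT.  Because individual transition durations differ,
averaged paths are built by resampling every raw path to a fixed number of
points by even index interpolation and averaging pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import h5py

from .landscape import AttractorSet, Attractor
from .rates import RateTrajectory


class OverlappingRegionsError(ValueError):
    pass


@dataclass(frozen=True)
class AttractorRegion:
    """Elliptic region around a landscape minimum (axes aligned with r1/r2)."""

    label: str
    center: tuple[float, float]    # spikes/s
    semi_axes: tuple[float, float]  # spikes/s

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (n, 2) array (or a single point)."""
        pts = np.atleast_2d(np.asarray(points, float))
        u = (pts[:, 0] - self.center[0]) / self.semi_axes[0]
        v = (pts[:, 1] - self.center[1]) / self.semi_axes[1]
        inside = u * u + v * v <= 1.0
        return inside if pts.shape[0] > 1 else inside[0]


@dataclass
class FPTResult:
    """First-passage samples for an ordered region pair."""

    from_label: str
    to_label: str
    samples: np.ndarray          # seconds, one per completed transition
    n_censored: int = 0          # observation windows ending mid-transition

    @property
    def K(self) -> int:
        return len(self.samples)

    @property
    def mfpt(self) -> float:
        """Mean first-passage time in seconds; NaN when no transitions."""
        return float(np.mean(self.samples)) if self.K else np.nan

    @property
    def se(self) -> float:
        if self.K < 2:
            return np.nan
        return float(np.std(self.samples, ddof=1) / np.sqrt(self.K))


@dataclass
class TransitionPathSet:
    from_label: str
    to_label: str
    paths: list[np.ndarray]              # each (m_k, 3): columns t, r1, r2
    n_points: Optional[int] = None
    mean_path: Optional[np.ndarray] = None      # (n_points, 2)
    pointwise_se: Optional[np.ndarray] = None   # (n_points, 2)

    @property
    def K(self) -> int:
        return len(self.paths)

    def mean_path_to_csv(self, path) -> None:
        if self.mean_path is None:
            raise ValueError("call average_path first")
        np.savetxt(path, self.mean_path, delimiter=",", header="r1,r2",
                   comments="")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["from"] = self.from_label
            h5.attrs["to"] = self.to_label
            grp = h5.create_group("paths")
            for k, p in enumerate(self.paths):
                grp.create_dataset(str(k), data=p)
            if self.mean_path is not None:
                h5.create_dataset("mean_path", data=self.mean_path)
                h5.create_dataset("pointwise_se", data=self.pointwise_se)


def define_regions(attractors: AttractorSet,
                   semi_axes: float | tuple[float, float] | dict = 5.0
                   ) -> list[AttractorRegion]:
    """One elliptic region per labeled attractor.

    `semi_axes` is a radius (circular region), an (a1, a2) pair applied to
    all attractors, or a {label: (a1, a2)} mapping.  Overlapping regions are
    rejected with an instruction to shrink the axes.
    """
    labeled = [m for m in attractors if m.label is not None]
    if not labeled:
        raise ValueError("attractor set has no labeled minima")
    regions = []
    for m in labeled:
        ax = semi_axes[m.label] if isinstance(semi_axes, dict) else semi_axes
        if np.isscalar(ax):
            ax = (float(ax), float(ax))
        regions.append(AttractorRegion(m.label, m.position, tuple(ax)))
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            # conservative test: compare center distance with the sum of the
            # largest semi-axes
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= max(a.semi_axes) + max(b.semi_axes):
                raise OverlappingRegionsError(
                    f"regions {a.label} and {b.label} overlap (center "
                    f"distance {d:.2f}); use smaller semi-axes")
    return regions


def _passage_events(in_src: np.ndarray, in_dst: np.ndarray):
    """(i_armed, i_start, i_end) triples of successive src -> dst passages.

    i_armed is the first sample inside src after the previous passage (the
    escape clock origin), i_start the last sample inside src before the
    excursion that reaches dst, i_end the first sample inside dst.  Returns
    (events, armed_at_end).
    """
    src_idx = np.flatnonzero(in_src)
    dst_idx = np.flatnonzero(in_dst)
    events = []
    cursor = 0  # samples before this index are consumed
    while True:
        k = np.searchsorted(src_idx, cursor)
        if k == len(src_idx):
            return events, False
        i_armed = src_idx[k]
        m = np.searchsorted(dst_idx, i_armed)
        if m == len(dst_idx):
            return events, True
        i_end = dst_idx[m]
        # last src sample before i_end
        i_start = src_idx[np.searchsorted(src_idx, i_end) - 1]
        events.append((int(i_armed), int(i_start), int(i_end)))
        cursor = i_end + 1


def first_passage_times(traj: RateTrajectory, src: AttractorRegion,
                        dst: AttractorRegion) -> FPTResult:
    """First-passage times from `src` to `dst` along one trajectory.

    The clock arms at the first visit to `src`; a sample is the time until
    the first subsequent entry into `dst` (dwell time near `src`, including
    failed excursions, counts — this is the escape time the barrier heights
    predict).  After recording, the clock re-arms at the next visit to
    `src`.  With zero observed transitions the result has K = 0 and an
    undefined (NaN) MFPT — never a fabricated value.
    """
    pts = traj.points
    events, censored = _passage_events(src.contains(pts), dst.contains(pts))
    samples = [(traj.t[i_end] - traj.t[i_armed]) / 1000.0
               for i_armed, _, i_end in events]
    return FPTResult(src.label, dst.label, np.asarray(samples, float),
                     n_censored=int(censored))


def pooled_first_passage_times(trajectories: Sequence[RateTrajectory],
                               src: AttractorRegion,
                               dst: AttractorRegion) -> FPTResult:
    """FPT samples pooled over independent trajectories."""
    all_samples = []
    n_cens = 0
    for traj in trajectories:
        r = first_passage_times(traj, src, dst)
        all_samples.append(r.samples)
        n_cens += r.n_censored
    return FPTResult(src.label, dst.label,
                     np.concatenate(all_samples) if all_samples else
                     np.empty(0), n_censored=n_cens)


def extract_transition_paths(traj: RateTrajectory, src: AttractorRegion,
                             dst: AttractorRegion) -> TransitionPathSet:
    """Raw transition paths (no averaging) from `src` to `dst`.

    Each path runs from the last point inside `src` to the first point
    inside `dst`; excursions that fall back into `src` restart from the new
    exit, so no interior point lies in `dst` before the end.
    """
    pts = traj.points
    events, _ = _passage_events(src.contains(pts), dst.contains(pts))
    paths = []
    for _, i, j in events:
        seg = np.column_stack([traj.t[i:j + 1],
                               traj.r1[i:j + 1], traj.r2[i:j + 1]])
        paths.append(seg)
    return TransitionPathSet(src.label, dst.label, paths)


def average_path(path_set: TransitionPathSet,
                 n_points: int = 100) -> TransitionPathSet:
    """Average transition path by even index-based resampling.

    Every raw path is interpolated at n_points evenly spaced fractional
    sample indices and the K resampled paths are averaged pointwise.  The
    pointwise across-path standard error accompanies the mean.
    """
    if path_set.K == 0:
        raise ValueError("cannot average an empty path set")
    resampled = np.empty((path_set.K, n_points, 2))
    for k, p in enumerate(path_set.paths):
        idx = np.linspace(0.0, len(p) - 1.0, n_points)
        base = np.arange(len(p), dtype=float)
        resampled[k, :, 0] = np.interp(idx, base, p[:, 1])
        resampled[k, :, 1] = np.interp(idx, base, p[:, 2])
    mean = resampled.mean(axis=0)
    if path_set.K > 1:
        se = resampled.std(axis=0, ddof=1) / np.sqrt(path_set.K)
    else:
        se = np.zeros_like(mean)
    return TransitionPathSet(path_set.from_label, path_set.to_label,
                             path_set.paths, n_points=n_points,
                             mean_path=mean, pointwise_se=se)
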