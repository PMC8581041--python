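"""Potential landscape U = -ln P_ss on the (r1, r2) decision plane.

P_ss is the normalized occupancy histogram of the stationary rate trajectory
on a rectangular grid.  The potential is defined only on visited bins;
unvisited bins carry NaN rather than a fabricated finite value, and barrier
paths may not traverse them.

Minima and saddles are found with a watershed-style flood: bins are added in
ascending order of U to a union-find structure over the 8-connected visited
region.  A bin with no previously-added neighbor seeds a basin (a strict
local minimum); when a bin first joins two basins it is the minimax saddle
between them, and the shallower basin's depth (persistence) is the barrier
measured there.  This is exactly equivalent to exhaustive minimax path
search, but deterministic and fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import h5py

from .rates import RateTrajectory

logger = logging.getLogger(__name__)

SamplesLike = Union[np.ndarray, RateTrajectory, Sequence[RateTrajectory]]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


class GridMismatchError(ValueError):
    pass


class MissingAttractorError(KeyError):
    pass


@dataclass
class LandscapeGrid:
    """Binned steady-state probability and potential on the (r1, r2) plane."""

    edges1: np.ndarray   # len n1+1, spikes/s
    edges2: np.ndarray   # len n2+1
    counts: np.ndarray   # (n1, n2)
    P: np.ndarray        # (n1, n2), sums to 1
    U: np.ndarray        # (n1, n2); NaN on unvisited bins
    n_samples: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def visited(self) -> np.ndarray:
        return self.counts > 0

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    def bin_center(self, ij: tuple[int, int]) -> tuple[float, float]:
        return float(self.centers1[ij[0]]), float(self.centers2[ij[1]])

    def same_grid(self, other: "LandscapeGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.edges1, other.edges1)
                and np.allclose(self.edges2, other.edges2))

    def transposed(self) -> "LandscapeGrid":
        """The landscape of the r1<->r2 swapped data."""
        return LandscapeGrid(self.edges2.copy(), self.edges1.copy(),
                             self.counts.T.copy(), self.P.T.copy(),
                             self.U.T.copy(), self.n_samples)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            for name in ("edges1", "edges2", "counts", "P", "U"):
                h5.create_dataset(name, data=getattr(self, name))
            h5.attrs["n_samples"] = self.n_samples

    @classmethod
    def from_hdf5(cls, path) -> "LandscapeGrid":
        with h5py.File(path, "r") as h5:
            return cls(*(h5[name][:] for name in
                         ("edges1", "edges2", "counts", "P", "U")),
                       n_samples=int(h5.attrs["n_samples"]))


@dataclass(frozen=True)
class Attractor:
    position: tuple[float, float]   # (r1, r2) bin center, spikes/s
    U: float                        # potential at the minimum
    bin: tuple[int, int]
    depth: float                    # persistence: lowest escape barrier
    label: Optional[str] = None     # SS / DS1 / DS2 / DU


@dataclass
class AttractorSet:
    minima: list[Attractor]
    grid: LandscapeGrid             # the (possibly smoothed) field searched

    def __len__(self) -> int:
        return len(self.minima)

    def __iter__(self):
        return iter(self.minima)

    def get(self, label: str) -> Attractor:
        for m in self.minima:
            if m.label == label:
                return m
        raise MissingAttractorError(
            f"no attractor labeled {label!r}; present: "
            f"{[m.label for m in self.minima]}")

    @property
    def labels(self) -> list[Optional[str]]:
        return [m.label for m in self.minima]


@dataclass(frozen=True)
class Saddle:
    connected: bool
    U: float                                  # inf when not connected
    position: Optional[tuple[float, float]] = None
    bin: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class BarrierMetrics:
    """Saddle-referenced barrier heights for an ordered pair of attractors.

    BH1 = U_saddle - U(a), BH2 = U_saddle - U(b), RB = BH1 - BH2
    = U(b) - U(a): positive RB means `a` sits in the deeper basin.
    """

    U_a: float
    U_b: float
    U_saddle: float
    saddle_position: Optional[tuple[float, float]]

    @property
    def BH1(self) -> float:
        return self.U_saddle - self.U_a

    @property
    def BH2(self) -> float:
        return self.U_saddle - self.U_b

    @property
    def RB(self) -> float:
        return self.BH1 - self.BH2


# ---------------------------------------------------------------------------


def _collect_samples(samples: SamplesLike) -> np.ndarray:
    if isinstance(samples, RateTrajectory):
        return samples.points
    if isinstance(samples, np.ndarray):
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise ValueError("sample array must have shape (n, 2)")
        return samples
    return np.vstack([_collect_samples(s) for s in samples])


def make_edges(samples: np.ndarray, bins: int = 50,
               domain: Optional[tuple[float, float, float, float]] = None,
               min_width: float = 0.0
               ) -> tuple[np.ndarray, np.ndarray]:
    """Default grid: `bins` bins per axis spanning [0, max + one bin width].

    Population rates computed from spike counts are quantized in steps of
    1/(N_pop * window); ``min_width`` (same units as the rates) caps the bin
    count so bins are never narrower than that quantum, which would shred
    the histogram into disconnected stripes of visited bins.
    """
    if domain is not None:
        lo1, hi1, lo2, hi2 = domain
    else:
        lo1 = lo2 = 0.0
        hi1 = max(float(samples[:, 0].max()), 1e-9)
        hi2 = max(float(samples[:, 1].max()), 1e-9)
        hi1 += hi1 / bins
        hi2 += hi2 / bins
    n1 = n2 = bins
    if min_width > 0:
        n1 = max(2, min(bins, int((hi1 - lo1) / min_width)))
        n2 = max(2, min(bins, int((hi2 - lo2) / min_width)))
    return (np.linspace(lo1, hi1, n1 + 1), np.linspace(lo2, hi2, n2 + 1))


def estimate_pss(samples: SamplesLike, bins: int = 50,
                 domain: Optional[tuple[float, float, float, float]] = None,
                 edges: Optional[tuple[np.ndarray, np.ndarray]] = None
                 ) -> LandscapeGrid:
    """Normalized stationary histogram and potential U = -ln P_ss.

    `samples` may be an (n, 2) array, a RateTrajectory, or a sequence of
    trajectories (pooled by concatenation).  Samples outside the grid are
    clipped to the edge bins and counted, with a logged warning.
    """
    pts = _collect_samples(samples)
    if len(pts) == 0:
        raise ValueError("no samples")
    if edges is None:
        edges = make_edges(pts, bins=bins, domain=domain)
    e1, e2 = np.asarray(edges[0], float), np.asarray(edges[1], float)

    out = ((pts[:, 0] < e1[0]) | (pts[:, 0] > e1[-1])
           | (pts[:, 1] < e2[0]) | (pts[:, 1] > e2[-1]))
    if out.any():
        logger.warning("%d of %d samples outside the grid were clipped "
                       "to edge bins", int(out.sum()), len(pts))
    x = np.clip(pts[:, 0], e1[0], np.nextafter(e1[-1], -np.inf))
    y = np.clip(pts[:, 1], e2[0], np.nextafter(e2[-1], -np.inf))
    counts, _, _ = np.histogram2d(x, y, bins=(e1, e2))
    P = counts / counts.sum()
    with np.errstate(divide="ignore"):
        U = np.where(counts > 0, -np.log(P, where=P > 0,
                                         out=np.full_like(P, np.nan)), np.nan)
    return LandscapeGrid(e1, e2, counts, P, U, n_samples=len(pts))


def convergence_sigma(P_t: Union[LandscapeGrid, np.ndarray],
                      P_t_plus: Union[LandscapeGrid, np.ndarray]) -> float:
    """Relative Euclidean distance between two occupancy distributions.

    sigma = ||P_t_plus - P_t||_2 / ||P_t||_2 over bins; a fraction (multiply
    by 100 to report %).  The two histograms must share one grid.
    """
    if isinstance(P_t, LandscapeGrid) and isinstance(P_t_plus, LandscapeGrid):
        if not P_t.same_grid(P_t_plus):
            raise GridMismatchError("convergence_sigma requires one grid")
        a, b = P_t.P, P_t_plus.P
    else:
        a = P_t.P if isinstance(P_t, LandscapeGrid) else np.asarray(P_t, float)
        b = (P_t_plus.P if isinstance(P_t_plus, LandscapeGrid)
             else np.asarray(P_t_plus, float))
        if a.shape != b.shape:
            raise GridMismatchError("distributions have different shapes")
    # normalize so raw count arrays are accepted (sigma is scale-free)
    a = a / a.sum()
    b = b / b.sum()
    return float(np.linalg.norm(b - a) / np.linalg.norm(a))


def smooth_grid(grid: LandscapeGrid, passes: int = 1) -> LandscapeGrid:
    """3x3 boxcar smoothing of U over visited bins (one pass by default).

    Each visited bin is replaced by the mean of its visited 8-neighborhood
    (including itself); unvisited bins stay NaN.  Smoothing suppresses the
    spurious one-bin minima a finite-sample histogram produces.
    """
    U = grid.U.copy()
    vis = grid.visited
    for _ in range(passes):
        filled = np.where(vis, U, 0.0)
        acc = np.zeros_like(U)
        norm = np.zeros_like(U)
        n1, n2 = U.shape
        for di, dj in _NEIGHBORS8 + [(0, 0)]:
            src_i = slice(max(0, -di), n1 - max(0, di))
            dst_i = slice(max(0, di), n1 - max(0, -di))
            src_j = slice(max(0, -dj), n2 - max(0, dj))
            dst_j = slice(max(0, dj), n2 - max(0, -dj))
            acc[dst_i, dst_j] += filled[src_i, src_j]
            norm[dst_i, dst_j] += vis[src_i, src_j]
        U = np.where(vis & (norm > 0), acc / np.maximum(norm, 1), np.nan)
    out = LandscapeGrid(grid.edges1, grid.edges2, grid.counts, grid.P, U,
                        grid.n_samples)
    return out


def _flood(U: np.ndarray):
    """Watershed flood over visited bins in ascending U.

    Returns (minima, merges): minima is a list of (bin, U) basin seeds;
    merges is a list of (saddle_bin, U_saddle, root_kept, root_dead) events
    in flooding order.  Roots are basin-seed bins.
    """
    n1, n2 = U.shape
    vis = np.isfinite(U)
    order = np.argsort(U[vis], kind="stable")
    bins = np.argwhere(vis)[order]

    parent: dict[tuple[int, int], tuple[int, int]] = {}
    root_min: dict[tuple[int, int], tuple[tuple[int, int], float]] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    minima = []
    merges = []
    added = np.zeros_like(vis)
    for i, j in bins:
        b = (int(i), int(j))
        u = float(U[b])
        roots = set()
        for di, dj in _NEIGHBORS8:
            ni, nj = b[0] + di, b[1] + dj
            if 0 <= ni < n1 and 0 <= nj < n2 and added[ni, nj]:
                roots.add(find((ni, nj)))
        if not roots:
            parent[b] = b
            root_min[b] = (b, u)
            minima.append((b, u))
        else:
            roots = sorted(roots, key=lambda r: (root_min[r][1], r))
            keep = roots[0]
            parent[b] = keep
            for dead in roots[1:]:
                merges.append((b, u, keep, dead, root_min[dead]))
                parent[dead] = keep
        added[b[0], b[1]] = True
    return minima, merges


def _label_minima(minima: list[Attractor], rate_threshold: float,
                  asym_threshold: float) -> list[Attractor]:
    """Assign SS/DS1/DS2/DU by position; each label goes to its deepest
    (lowest-U) candidate so labels stay unique.

    Decision states are defined by winner-loser asymmetry (|r1 - r2| at or
    above `asym_threshold`), matching their semantics in the circuit; the
    symmetric states split into SS (spontaneous, low mean rate) and DU
    (double-up, high mean rate) at `rate_threshold`.
    """
    def category(pos):
        if abs(pos[0] - pos[1]) >= asym_threshold:
            return "DS1" if pos[0] > pos[1] else "DS2"
        return "SS" if 0.5 * (pos[0] + pos[1]) < rate_threshold else "DU"

    best: dict[str, Attractor] = {}
    for m in minima:
        cat = category(m.position)
        if cat not in best or m.U < best[cat].U:
            best[cat] = m
    out = []
    for m in minima:
        cat = category(m.position)
        label = cat if best[cat] is m else None
        out.append(Attractor(m.position, m.U, m.bin, m.depth, label))
    return out


def _component_mass(grid: LandscapeGrid) -> np.ndarray:
    """Probability mass of the 8-connected visited component of each bin."""
    from scipy import ndimage
    structure = np.ones((3, 3), bool)
    labels, n = ndimage.label(grid.visited, structure=structure)
    mass = ndimage.sum_labels(grid.P, labels, index=np.arange(1, n + 1))
    out = np.zeros(grid.shape)
    for k in range(n):
        out[labels == k + 1] = mass[k]
    return out


def find_minima(grid: LandscapeGrid, smooth: int = 1,
                depth_threshold: float = 0.5,
                rate_threshold: float = 10.0,
                asym_threshold: float = 5.0,
                min_component_mass: float = 0.02) -> AttractorSet:
    """Strict local minima of U, pruned by basin depth (persistence).

    `smooth` boxcar passes are applied first (0 disables).  A minimum is kept
    if the lowest saddle separating it from any deeper basin lies at least
    `depth_threshold` (dimensionless U units) above it; the global minimum is
    always kept.  Minima in disconnected visited islands carrying less than
    `min_component_mass` of the total probability are sampling debris and
    are dropped.  Labels: DS1/DS2 when |r1 - r2| >= `asym_threshold`
    (winner-take-all asymmetry), otherwise SS or DU by mean rate against
    `rate_threshold` (both in spikes/s).
    """
    g = smooth_grid(grid, passes=smooth) if smooth else grid
    if not np.isfinite(g.U).any():
        return AttractorSet([], g)
    comp_mass = _component_mass(g)
    seeds, merges = _flood(g.U)
    depth = {b: np.inf for b, _ in seeds}
    for saddle_bin, u_saddle, keep, dead, (dead_min, dead_u) in merges:
        depth[dead_min] = min(depth[dead_min], u_saddle - dead_u)
    minima = []
    for b, u in seeds:
        if depth[b] >= depth_threshold and \
                comp_mass[b] >= min_component_mass:
            minima.append(Attractor(position=g.bin_center(b), U=u, bin=b,
                                    depth=float(depth[b])))
    minima.sort(key=lambda m: m.U)
    return AttractorSet(_label_minima(minima, rate_threshold,
                                      asym_threshold), g)


def find_saddle(grid: LandscapeGrid, a: Union[Attractor, tuple[int, int]],
                b: Union[Attractor, tuple[int, int]]) -> Saddle:
    """Minimax saddle between two bins over 8-connected visited paths.

    The returned U is min over paths of the max U along the path — the value
    at which rising water first connects the two bins.  If the bins lie in
    disconnected visited regions the result has connected=False and U=inf.
    """
    ba = a.bin if isinstance(a, Attractor) else tuple(a)
    bb = b.bin if isinstance(b, Attractor) else tuple(b)
    U = grid.U
    if not (np.isfinite(U[ba]) and np.isfinite(U[bb])):
        raise ValueError("saddle endpoints must be visited bins")
    if ba == bb:
        return Saddle(True, float(U[ba]), grid.bin_center(ba), ba)

    n1, n2 = U.shape
    vis = np.isfinite(U)
    order = np.argsort(U[vis], kind="stable")
    bins = np.argwhere(vis)[order]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    added = np.zeros_like(vis)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bins:
        cur = (int(i), int(j))
        parent[cur] = cur
        for di, dj in _NEIGHBORS8:
            ni, nj = cur[0] + di, cur[1] + dj
            if 0 <= ni < n1 and 0 <= nj < n2 and added[ni, nj]:
                ra, rb = find(cur), find((ni, nj))
                if ra != rb:
                    parent[ra] = rb
        added[cur[0], cur[1]] = True
        if added[ba] and added[bb] and find(ba) == find(bb):
            return Saddle(True, float(U[cur]), grid.bin_center(cur), cur)
    return Saddle(False, np.inf)


def barrier_metrics(grid: LandscapeGrid, attractors: AttractorSet,
                    pair: tuple[str, str]) -> BarrierMetrics:
    """BH/RB between two labeled attractors; `pair` e.g. ("DS1", "DS2").

    Uses the same (smoothed) field the attractors were found on when `grid`
    is the AttractorSet's grid; pass attractors.grid for consistency.
    """
    a = attractors.get(pair[0])
    b = attractors.get(pair[1])
    s = find_saddle(grid, a, b)
    return BarrierMetrics(U_a=a.U, U_b=b.U, U_saddle=s.U,
                          saddle_position=s.position)
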