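"""Non-equilibrium probability flux from steady-state trajectories.

The (r1, r2) plane is divided into N1 x N2 equally sized rectangular boxes
(discrete states).  For every ordered pair of adjacent boxes the net
transition rate is

    w_ab = (N_ab - N_ba) / t_total,

where N_ab counts directed face crossings of the trajectory; when a sampling
step jumps over more than one box the straight segment between the two
sample points is traced and every crossed face is counted, ordered by the
segment's parametric crossing times.  The flux vector at a box averages the
net rates through its two faces per direction,

    J = 1/2 * (w_in + w_out)        (per component),

with rates across the domain boundary taken as zero.  Nonzero J at steady
state marks broken detailed balance; for a gradient (equilibrium) system J
vanishes up to sampling error.

Statistical errors are estimated by splitting the trajectory into contiguous
blocks and taking the across-block dispersion of the per-block flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import h5py
from numba import njit

from .rates import RateTrajectory

SamplesLike = Union[np.ndarray, RateTrajectory]


@dataclass(frozen=True)
class CoarseGrid:
    """Equally sized rectangular boxes covering the analysis domain."""

    edges1: np.ndarray   # len N1+1
    edges2: np.ndarray   # len N2+1

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.edges1) - 1, len(self.edges2) - 1

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])


@dataclass
class TransitionTallies:
    """Directed face-crossing counts. Face (i, j) of N1pos/N1neg separates
    boxes (i, j) and (i+1, j); face (i, j) of N2pos/N2neg separates boxes
    (i, j) and (i, j+1)."""

    N1_pos: np.ndarray   # (N1-1, N2) crossings toward larger r1
    N1_neg: np.ndarray
    N2_pos: np.ndarray   # (N1, N2-1) crossings toward larger r2
    N2_neg: np.ndarray


@dataclass
class FluxField:
    grid: CoarseGrid
    w1: np.ndarray        # (N1-1, N2) net signed rate across r1-faces, 1/s
    w2: np.ndarray        # (N1, N2-1) net signed rate across r2-faces, 1/s
    Jx: np.ndarray        # (N1, N2) flux vector components per box, 1/s
    Jy: np.ndarray
    t_total: float        # s
    tallies: Optional[TransitionTallies] = None
    Jx_se: Optional[np.ndarray] = None   # across-block standard errors
    Jy_se: Optional[np.ndarray] = None

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.Jx, self.Jy)

    @property
    def se_magnitude(self) -> Optional[np.ndarray]:
        if self.Jx_se is None:
            return None
        return np.hypot(self.Jx_se, self.Jy_se)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("edges1", data=self.grid.edges1)
            h5.create_dataset("edges2", data=self.grid.edges2)
            for name in ("w1", "w2", "Jx", "Jy"):
                h5.create_dataset(name, data=getattr(self, name))
            if self.tallies is not None:
                for name in ("N1_pos", "N1_neg", "N2_pos", "N2_neg"):
                    h5.create_dataset(name, data=getattr(self.tallies, name))
            if self.Jx_se is not None:
                h5.create_dataset("Jx_se", data=self.Jx_se)
                h5.create_dataset("Jy_se", data=self.Jy_se)
            h5.attrs["t_total_s"] = self.t_total

    def to_quiver_csv(self, path) -> None:
        """Box centers and flux vectors as a flat CSV for plotting."""
        c1, c2 = np.meshgrid(self.grid.centers1, self.grid.centers2,
                             indexing="ij")
        pd.DataFrame({"r1": c1.ravel(), "r2": c2.ravel(),
                      "Jx": self.Jx.ravel(),
                      "Jy": self.Jy.ravel()}).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def _as_points(samples: SamplesLike) -> np.ndarray:
    pts = samples.points if isinstance(samples, RateTrajectory) else \
        np.asarray(samples, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("need an (n, 2) sample array")
    if len(pts) == 0:
        raise ValueError("empty trajectory")
    return pts


def make_coarse_grid(samples: SamplesLike, N1: int = 20, N2: int = 20,
                     domain: Optional[tuple[float, float, float, float]] = None
                     ) -> CoarseGrid:
    if N1 < 2 or N2 < 2:
        raise ValueError("need at least 2 boxes per direction")
    pts = _as_points(samples)
    if domain is None:
        lo1, hi1 = float(pts[:, 0].min()), float(pts[:, 0].max())
        lo2, hi2 = float(pts[:, 1].min()), float(pts[:, 1].max())
        pad1 = max(hi1 - lo1, 1e-9) * 1e-6
        pad2 = max(hi2 - lo2, 1e-9) * 1e-6
        lo1, hi1, lo2, hi2 = lo1 - pad1, hi1 + pad1, lo2 - pad2, hi2 + pad2
    else:
        lo1, hi1, lo2, hi2 = domain
    return CoarseGrid(np.linspace(lo1, hi1, N1 + 1),
                      np.linspace(lo2, hi2, N2 + 1))


def coarse_grain(samples: SamplesLike, grid: Optional[CoarseGrid] = None,
                 N1: int = 20, N2: int = 20,
                 domain: Optional[tuple[float, float, float, float]] = None
                 ) -> tuple[np.ndarray, np.ndarray, CoarseGrid, np.ndarray]:
    """Per-sample box indices (ix, iy) on the coarse grid.

    Samples outside the domain are clipped to the edge boxes.  Returns
    (ix, iy, grid, clipped_points).
    """
    pts = _as_points(samples)
    if grid is None:
        grid = make_coarse_grid(pts, N1, N2, domain)
    e1, e2 = grid.edges1, grid.edges2
    x = np.clip(pts[:, 0], e1[0], np.nextafter(e1[-1], -np.inf))
    y = np.clip(pts[:, 1], e2[0], np.nextafter(e2[-1], -np.inf))
    ix = np.clip(np.searchsorted(e1, x, side="right") - 1, 0, len(e1) - 2)
    iy = np.clip(np.searchsorted(e2, y, side="right") - 1, 0, len(e2) - 2)
    return ix.astype(np.int64), iy.astype(np.int64), grid, \
        np.column_stack([x, y])


@njit(cache=True)
def _count_crossings(x, y, ix, iy, e1, e2, N1_pos, N1_neg, N2_pos, N2_neg):
    n = x.shape[0]
    for k in range(n - 1):
        ci, cj = ix[k], iy[k]
        ti, tj = ix[k + 1], iy[k + 1]
        if ci == ti and cj == tj:
            continue
        x0, y0 = x[k], y[k]
        dx = x[k + 1] - x0
        dy = y[k + 1] - y0
        guard = 0
        while (ci != ti or cj != tj) and guard < 100000:
            guard += 1
            tx = np.inf
            if ti > ci and dx > 0:
                tx = (e1[ci + 1] - x0) / dx
            elif ti < ci and dx < 0:
                tx = (e1[ci] - x0) / dx
            ty = np.inf
            if tj > cj and dy > 0:
                ty = (e2[cj + 1] - y0) / dy
            elif tj < cj and dy < 0:
                ty = (e2[cj] - y0) / dy
            if tx <= ty:
                if ti > ci:
                    N1_pos[ci, cj] += 1
                    ci += 1
                else:
                    N1_neg[ci - 1, cj] += 1
                    ci -= 1
            else:
                if tj > cj:
                    N2_pos[ci, cj] += 1
                    cj += 1
                else:
                    N2_neg[ci, cj - 1] += 1
                    cj -= 1


def count_transitions(samples: SamplesLike,
                      grid: Optional[CoarseGrid] = None,
                      N1: int = 20, N2: int = 20,
                      domain: Optional[tuple[float, float, float, float]] = None
                      ) -> tuple[TransitionTallies, CoarseGrid]:
    """Directed face-crossing tallies for consecutive sample pairs.

    Pairs in the same box contribute nothing; pairs in different boxes are
    linearly interpolated so every crossed face is counted in order.
    """
    ix, iy, grid, pts = coarse_grain(samples, grid, N1, N2, domain)
    n1, n2 = grid.shape
    tallies = TransitionTallies(
        N1_pos=np.zeros((n1 - 1, n2), dtype=np.int64),
        N1_neg=np.zeros((n1 - 1, n2), dtype=np.int64),
        N2_pos=np.zeros((n1, n2 - 1), dtype=np.int64),
        N2_neg=np.zeros((n1, n2 - 1), dtype=np.int64))
    _count_crossings(pts[:, 0], pts[:, 1], ix, iy,
                     grid.edges1, grid.edges2,
                     tallies.N1_pos, tallies.N1_neg,
                     tallies.N2_pos, tallies.N2_neg)
    return tallies, grid


def flux_field(tallies: TransitionTallies, t_total: float,
               grid: CoarseGrid) -> FluxField:
    """Net face rates w = (N_ab - N_ba)/t_total and per-box flux vectors.

    J at a box averages the net rate through its two faces in each direction;
    faces on the domain boundary contribute zero.
    """
    if t_total <= 0:
        raise ValueError("t_total must be positive (seconds)")
    w1 = (tallies.N1_pos - tallies.N1_neg) / t_total
    w2 = (tallies.N2_pos - tallies.N2_neg) / t_total
    n1, n2 = grid.shape
    w1pad = np.zeros((n1 + 1, n2))
    w1pad[1:-1, :] = w1
    w2pad = np.zeros((n1, n2 + 1))
    w2pad[:, 1:-1] = w2
    Jx = 0.5 * (w1pad[:-1, :] + w1pad[1:, :])
    Jy = 0.5 * (w2pad[:, :-1] + w2pad[:, 1:])
    return FluxField(grid=grid, w1=w1, w2=w2, Jx=Jx, Jy=Jy,
                     t_total=t_total, tallies=tallies)


def estimate_flux(samples: SamplesLike, t_total: float,
                  grid: Optional[CoarseGrid] = None,
                  N1: int = 20, N2: int = 20,
                  domain: Optional[tuple[float, float, float, float]] = None,
                  n_blocks: int = 10) -> FluxField:
    """Flux field with across-block standard errors.

    The trajectory is split into `n_blocks` contiguous blocks; the SE of
    each flux component is the across-block standard deviation divided by
    sqrt(n_blocks).
    """
    pts = _as_points(samples)
    if grid is None:
        grid = make_coarse_grid(pts, N1, N2, domain)
    tallies, _ = count_transitions(pts, grid)
    out = flux_field(tallies, t_total, grid)

    if n_blocks >= 2 and len(pts) >= 2 * n_blocks:
        bounds = np.linspace(0, len(pts), n_blocks + 1).astype(int)
        t_block = t_total / n_blocks
        Jx_blocks, Jy_blocks = [], []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            tb, _ = count_transitions(pts[lo:hi], grid)
            fb = flux_field(tb, t_block, grid)
            Jx_blocks.append(fb.Jx)
            Jy_blocks.append(fb.Jy)
        out.Jx_se = np.std(Jx_blocks, axis=0, ddof=1) / np.sqrt(n_blocks)
        out.Jy_se = np.std(Jy_blocks, axis=0, ddof=1) / np.sqrt(n_blocks)
    return out


def pooled_flux(trajectories, grid: Optional[CoarseGrid] = None,
                N1: int = 20, N2: int = 20,
                domain: Optional[tuple[float, float, float, float]] = None,
                n_blocks: int = 10) -> FluxField:
    """Flux pooled over independent trajectories.

    Crossings are counted per trajectory (never across the seam between two
    pooled trials) and the tallies and observation times are summed.  Block
    standard errors use the trajectories themselves as blocks when there are
    at least `n_blocks` of them, otherwise contiguous blocks of the
    concatenated per-trajectory fluxes.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories")
    pts_all = np.vstack([_as_points(t) for t in trajs])
    if grid is None:
        grid = make_coarse_grid(pts_all, N1, N2, domain)
    n1, n2 = grid.shape
    total = TransitionTallies(
        N1_pos=np.zeros((n1 - 1, n2), dtype=np.int64),
        N1_neg=np.zeros((n1 - 1, n2), dtype=np.int64),
        N2_pos=np.zeros((n1, n2 - 1), dtype=np.int64),
        N2_neg=np.zeros((n1, n2 - 1), dtype=np.int64))
    t_total = 0.0
    per_traj = []
    for tr in trajs:
        tb, _ = count_transitions(tr, grid)
        stride_s = (tr.stride / 1000.0 if isinstance(tr, RateTrajectory)
                    else 1.0)
        dur = len(_as_points(tr)) * stride_s
        for name in ("N1_pos", "N1_neg", "N2_pos", "N2_neg"):
            getattr(total, name)[:] += getattr(tb, name)
        per_traj.append((tb, dur))
        t_total += dur
    out = flux_field(total, t_total, grid)
    if len(per_traj) >= 2:
        Jx_blocks, Jy_blocks = [], []
        for tb, dur in per_traj:
            fb = flux_field(tb, dur, grid)
            Jx_blocks.append(fb.Jx)
            Jy_blocks.append(fb.Jy)
        nb = len(per_traj)
        out.Jx_se = np.std(Jx_blocks, axis=0, ddof=1) / np.sqrt(nb)
        out.Jy_se = np.std(Jy_blocks, axis=0, ddof=1) / np.sqrt(nb)
    return out


def tangential_component(flux: FluxField,
                         center: tuple[float, float]) -> np.ndarray:
    """Signed tangential flux component about `center` per box.

    Positive values mean counterclockwise circulation at that box (J
    projected on the unit vector (-(y-cy), x-cx)/r).
    """
    c1, c2 = np.meshgrid(flux.grid.centers1, flux.grid.centers2,
                         indexing="ij")
    rx, ry = c1 - center[0], c2 - center[1]
    r = np.hypot(rx, ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        tang = (-ry * flux.Jx + rx * flux.Jy) / np.where(r > 0, r, np.nan)
    return tang


def curl_sign_consistency(flux: FluxField, center: tuple[float, float],
                          noise_floor_se: float = 2.0
                          ) -> tuple[float, int, int]:
    """Fraction of above-noise boxes whose rotation sense about `center`
    matches the majority sense.

    Boxes with ||J|| below `noise_floor_se` block standard errors are
    excluded.  Returns (fraction, n_majority, n_above_noise); the circulation
    sign itself is sign(sum of tangential components over included boxes).
    """
    tang = tangential_component(flux, center)
    mask = np.isfinite(tang) & (flux.magnitude > 0)
    if flux.se_magnitude is not None:
        mask &= flux.magnitude > noise_floor_se * flux.se_magnitude
    vals = tang[mask]
    vals = vals[vals != 0]
    if len(vals) == 0:
        return np.nan, 0, 0
    majority_sign = np.sign(np.sum(vals))
    n_major = int(np.sum(np.sign(vals) == majority_sign))
    return n_major / len(vals), n_major, len(vals)


def circulation_sign(flux: FluxField, center: tuple[float, float],
                     noise_floor_se: float = 2.0) -> int:
    """Sign (+1 counterclockwise, -1 clockwise, 0 none) of the net
    circulation of J about `center` over above-noise boxes."""
    tang = tangential_component(flux, center)
    mask = np.isfinite(tang)
    if flux.se_magnitude is not None:
        mask &= flux.magnitude > noise_floor_se * flux.se_magnitude
    total = np.nansum(tang[mask])
    return int(np.sign(total))
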