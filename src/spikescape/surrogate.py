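"""Synthetic 2D Langevin trajectories with known stationary law, flux, MFPT.

Three drift families, each emitted in the same trajectory format as the
network rates (samples offset into a positive, rate-like range) so that the
landscape, flux and transition machinery consumes them unchanged:

* ``double_well`` — gradient drift of V(x, y) = h ((x/a)^2 - 1)^2 + k_y y^2/2
  plus isotropic noise sqrt(2D) dW.  Stationary law exp(-V/D) (detailed
  balance, zero flux); the x-marginal passage problem has the classic 1D
  mean-exit-time double integral as closed-ish form.
* ``triple_well`` — gradient drift D * grad(log p) for a three-component
  isotropic Gaussian mixture p, so the stationary density is exactly that
  mixture (wells laid out like the spontaneous state and the two decision
  states).  Zero flux.
* ``linear_rotational`` — linear drift A x with A = -k I + omega R,
  R = [[0, 1], [-1, 0]].  Gaussian stationary law with covariance (D/k) I
  and a non-vanishing rotational flux J = omega R x p_ss: a known-sign curl
  (clockwise for omega > 0, i.e., negative counterclockwise circulation).

Time is in seconds internally; emitted trajectories carry t in ms to match
the network rate trajectories.  Integration is Euler–Maruyama, deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .rates import RateTrajectory

FAMILIES = ("double_well", "triple_well", "linear_rotational")
_FAM_CODE = {name: i for i, name in enumerate(FAMILIES)}


class UnstableIntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LangevinSpec:
    """Configuration of one surrogate trajectory.

    Drift parameters are in 1/s units, D in (spikes/s)^2 / s, dt and
    duration in seconds.  ``offset`` shifts the dynamical origin into the
    positive quadrant.  ``record_stride`` keeps every n-th Euler step.
    """

    family: str
    D: float = 1.0
    dt: float = 0.01
    duration: float = 1000.0
    seed: int = 0
    offset: tuple[float, float] = (25.0, 25.0)
    record_stride: int = 5
    x0: Optional[tuple[float, float]] = None   # absolute start, rate units
    # double_well parameters
    well_half_separation: float = 10.0   # a: wells at offset_x +/- a
    barrier_height: float = 2.0          # h, units of D when D=1
    k_y: float = 1.0                     # transverse stiffness, 1/s
    # triple_well parameters
    mixture_centers: tuple = ((-10.0, -10.0), (10.0, -10.0), (-10.0, 10.0))
    mixture_sigma: float = 3.0
    # linear_rotational parameters
    k: float = 1.0                       # symmetric decay rate, 1/s
    omega: float = 1.0                   # rotation coefficient, 1/s

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if self.D < 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("need D >= 0, dt > 0, duration > 0")
        if self.family == "linear_rotational" and self.k <= 0:
            raise ValueError("linear_rotational needs k > 0 for stability")

    @property
    def well_positions(self) -> np.ndarray:
        """Absolute (r1, r2) positions of the stationary wells."""
        ox, oy = self.offset
        if self.family == "double_well":
            a = self.well_half_separation
            return np.array([[ox - a, oy], [ox + a, oy]])
        if self.family == "triple_well":
            return np.asarray(self.mixture_centers) + np.array([ox, oy])
        return np.array([[ox, oy]])


@njit(cache=True, fastmath=True)
def _euler(fam, n_steps, rec_stride, dt, sqrt2Ddt, x0, y0,
           p0, p1, p2, p3,          # family parameters
           cx0, cy0, cx1, cy1, cx2, cy2, sig,   # mixture geometry
           out):
    x, y = x0, y0
    nrec = out.shape[0]
    r = 0
    for step in range(n_steps):
        if fam == 0:
            # V = h((x/a)^2-1)^2 + ky y^2/2 ; p0=h, p1=a, p2=ky
            fx = -4.0 * p0 * x * ((x / p1) ** 2 - 1.0) / (p1 * p1)
            fy = -p2 * y
        elif fam == 1:
            # drift = D * grad log(mixture); p0 = D
            s2 = sig * sig
            g0 = np.exp(-((x - cx0) ** 2 + (y - cy0) ** 2) / (2.0 * s2))
            g1 = np.exp(-((x - cx1) ** 2 + (y - cy1) ** 2) / (2.0 * s2))
            g2 = np.exp(-((x - cx2) ** 2 + (y - cy2) ** 2) / (2.0 * s2))
            tot = g0 + g1 + g2 + 1e-300
            gx = (g0 * (cx0 - x) + g1 * (cx1 - x) + g2 * (cx2 - x)) / s2
            gy = (g0 * (cy0 - y) + g1 * (cy1 - y) + g2 * (cy2 - y)) / s2
            fx = p0 * gx / tot
            fy = p0 * gy / tot
        else:
            # A = -k I + omega R, R = [[0,1],[-1,0]]; p0=k, p1=omega
            fx = -p0 * x + p1 * y
            fy = -p1 * x - p0 * y
        x = x + dt * fx + sqrt2Ddt * np.random.normal()
        y = y + dt * fy + sqrt2Ddt * np.random.normal()
        if abs(x) > 1e6 or abs(y) > 1e6:
            return step
        if (step + 1) % rec_stride == 0:
            if r < nrec:
                out[r, 0] = x
                out[r, 1] = y
                r += 1
    return -1


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def simulate_langevin(spec: LangevinSpec) -> RateTrajectory:
    """Euler–Maruyama trajectory of the specified family.

    The output is a RateTrajectory whose (r1, r2) samples live in the same
    positive units as network population rates; t is in ms.  Identical specs
    (including seed) give bit-identical trajectories.
    """
    n_steps = int(round(spec.duration / spec.dt))
    nrec = n_steps // spec.record_stride
    if nrec < 1:
        raise ValueError("duration too short for one recorded sample")
    out = np.empty((nrec, 2))
    ox, oy = spec.offset
    if spec.x0 is not None:
        x0, y0 = spec.x0[0] - ox, spec.x0[1] - oy
    elif spec.family == "double_well":
        x0, y0 = -spec.well_half_separation, 0.0
    elif spec.family == "triple_well":
        x0, y0 = spec.mixture_centers[0]
    else:
        x0, y0 = 0.0, 0.0
    fam = _FAM_CODE[spec.family]
    if fam == 0:
        p = (spec.barrier_height, spec.well_half_separation, spec.k_y, 0.0)
    elif fam == 1:
        p = (spec.D, 0.0, 0.0, 0.0)
    else:
        p = (spec.k, spec.omega, 0.0, 0.0)
    (cx0, cy0), (cx1, cy1), (cx2, cy2) = spec.mixture_centers
    _seed(np.uint32(spec.seed))
    bad = _euler(fam, n_steps, spec.record_stride, spec.dt,
                 np.sqrt(2.0 * spec.D * spec.dt), x0, y0,
                 p[0], p[1], p[2], p[3],
                 cx0, cy0, cx1, cy1, cx2, cy2, spec.mixture_sigma, out)
    if bad >= 0:
        raise UnstableIntegrationError(
            f"trajectory diverged at step {bad}; reduce dt for this drift")
    dt_rec_s = spec.dt * spec.record_stride
    t_ms = 1000.0 * dt_rec_s * np.arange(1, nrec + 1)
    return RateTrajectory(t=t_ms, r1=out[:, 0] + ox, r2=out[:, 1] + oy,
                          window=dt_rec_s * 1000.0, stride=dt_rec_s * 1000.0)


# -- analytic references ----------------------------------------------------


@dataclass
class ReferenceBundle:
    """Ground truth for a surrogate family, in absolute (r1, r2) units."""

    spec: LangevinSpec

    def potential(self, r1, r2) -> np.ndarray:
        """Dimensionless potential -log p_ss at absolute coordinates."""
        x = np.asarray(r1, float) - self.spec.offset[0]
        y = np.asarray(r2, float) - self.spec.offset[1]
        s = self.spec
        if s.family == "double_well":
            V = (s.barrier_height * ((x / s.well_half_separation) ** 2 - 1) ** 2
                 + 0.5 * s.k_y * y * y)
            return V / s.D
        if s.family == "triple_well":
            s2 = s.mixture_sigma ** 2
            dens = sum(np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s2))
                       for cx, cy in s.mixture_centers) / 3.0
            return -np.log(dens / (2 * np.pi * s2))
        var = s.D / s.k
        return (x * x + y * y) / (2 * var)

    def p_ss_on_grid(self, edges1: np.ndarray,
                     edges2: np.ndarray) -> np.ndarray:
        """Stationary probability per bin, normalized over the grid
        (bin-center evaluation with quadrature normalization)."""
        c1 = 0.5 * (edges1[:-1] + edges1[1:])
        c2 = 0.5 * (edges2[:-1] + edges2[1:])
        X, Y = np.meshgrid(c1, c2, indexing="ij")
        dens = np.exp(-self.potential(X, Y))
        return dens / dens.sum()

    @property
    def stationary_covariance(self) -> np.ndarray:
        """Exact covariance for linear_rotational (Lyapunov solution)."""
        s = self.spec
        if s.family != "linear_rotational":
            raise ValueError("covariance reference is for linear_rotational")
        return (s.D / s.k) * np.eye(2)

    def flux(self, r1, r2) -> tuple[np.ndarray, np.ndarray]:
        """Stationary flux vector at absolute coordinates.

        Identically zero for the two gradient families; for
        linear_rotational J = omega * (y, -x) * p_ss(x, y).
        """
        s = self.spec
        x = np.asarray(r1, float) - s.offset[0]
        y = np.asarray(r2, float) - s.offset[1]
        if s.family != "linear_rotational":
            return np.zeros_like(x), np.zeros_like(y)
        var = s.D / s.k
        p = np.exp(-(x * x + y * y) / (2 * var)) / (2 * np.pi * var)
        return s.omega * y * p, -s.omega * x * p

    @property
    def circulation_sign(self) -> int:
        """Sign of the counterclockwise circulation of the reference flux."""
        s = self.spec
        if s.family != "linear_rotational":
            return 0
        return -int(np.sign(s.omega))

    def mfpt_quadrature(self, x_start: float, x_target: float,
                        n_grid: int = 6000) -> float:
        """1D mean exit time (s) for the double-well x-marginal.

        T(x0 -> xt) = (1/D) * int_{x0}^{xt} dy e^{V(y)/D}
                      int_{-inf}^{y} dz e^{-V(z)/D}
        for the overdamped dynamics dx = -V'(x) dt + sqrt(2D) dW with a
        natural reflecting boundary on the left.  Coordinates are absolute
        (r1 units).
        """
        s = self.spec
        if s.family != "double_well":
            raise ValueError("MFPT reference is for double_well")
        a, h, D = s.well_half_separation, s.barrier_height, s.D
        ox = s.offset[0]
        x0, xt = x_start - ox, x_target - ox

        def V(z):
            return h * ((z / a) ** 2 - 1) ** 2

        lo = min(x0, -a) - 6.0 * np.sqrt(D / max(8 * h / a ** 2, 1e-12))
        z = np.linspace(lo, xt, n_grid)
        inner = np.concatenate([[0.0],
                                np.cumsum(0.5 * (np.exp(-V(z[1:]) / D)
                                                 + np.exp(-V(z[:-1]) / D))
                                          * np.diff(z))])
        integrand = np.exp(V(z) / D) * inner
        mask = z >= x0
        zm, im = z[mask], integrand[mask]
        return float(np.trapezoid(im, zm) / D)


def analytic_references(spec: LangevinSpec) -> ReferenceBundle:
    """Ground-truth bundle (stationary law, flux, MFPT) for a spec."""
    return ReferenceBundle(spec)
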