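"""Zero-Reynolds-number flow from regularized Stokeslets over a no-slip wall.

Each cilium node carries a point force spread over a radially symmetric blob

    psi_eps(r) = 15 eps^4 / (8 pi (r^2 + eps^2)^(7/2)),

whose Stokes-equation solution is the regularized Stokeslet

    8 pi mu u(x) = [f (r^2 + 2 eps^2) + (f.b) b] / (r^2 + eps^2)^(3/2),

with b = x - x_c.  The velocity is finite everywhere, including at the
source, and approaches the singular Stokeslet at separations r >> eps.

The no-slip wall at z = 0 is enforced by an image system: an equal and
opposite Stokeslet at the mirror point plus higher-order corrections
(force doublets, a potential dipole, and eps^2 regularization corrections)
whose closed forms were obtained by solving, over a basis of image-centred
rational Stokes fields, the conditions that the total field (i) vanishes
identically on z = 0, (ii) is exactly divergence-free, (iii) reduces to the
classical singular image system as eps -> 0, and (iv) obeys kernel
reciprocity.  The residual forcing of the image terms is O(eps^2) and
concentrated at the image point, outside the flow domain.

Forcing modes:

* ``resistive`` (default): f_i = gamma * v_i, the local drag approximation;
  gamma is a scalar calibrated once per beat configuration
  (:func:`calibrate_gamma`).
* ``mobility``: solve the dense 3M x 3M system sum_j G(x_i, x_j) f_j = v_i
  so the flow interpolates the prescribed node velocities exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ciliaflow._wall_image import image_scalar_factors

try:
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False


@dataclass(frozen=True)
class StokesletSet:
    """Discrete regularized point forces: positions (M, 3), forces (M, 3)."""

    positions: np.ndarray
    forces: np.ndarray
    epsilon: float = 0.1

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        frc = np.atleast_2d(np.asarray(self.forces, dtype=float))
        if pos.shape != frc.shape or pos.shape[1] != 3:
            raise ValueError("positions and forces must both be (M, 3)")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if np.any(pos[:, 2] <= 0):
            raise ValueError("all source points must lie strictly above the wall")
        if not np.all(np.isfinite(frc)):
            raise ValueError("forces must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "forces", frc)


@dataclass(frozen=True)
class FlowParams:
    """Fluid and forcing parameters.

    The package is nondimensional: lengths in um, time in beat cycles,
    mu = 1.  Stokes flow is linear, so mu and the force scale only set a
    common velocity prefactor; trajectories depend on gamma/mu.
    """

    mu: float = 1.0
    forcing_mode: str = "resistive"
    gamma: Optional[float] = None     # None = calibrate per configuration
    wall: bool = True
    epsilon: float = 0.1

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.forcing_mode not in ("resistive", "mobility"):
            raise ValueError("forcing_mode must be 'resistive' or 'mobility'")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def with_gamma(self, gamma: float) -> "FlowParams":
        return replace(self, gamma=float(gamma))


def blob(r, epsilon: float):
    """The force-spreading kernel psi_eps(r) = 15 eps^4/(8 pi (r^2+eps^2)^(7/2))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = 15.0 * epsilon ** 4 / (8.0 * np.pi * (r ** 2 + epsilon ** 2) ** 3.5)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# kernel evaluation (numpy reference implementation)
# ---------------------------------------------------------------------------

def _freespace_pairwise(points: np.ndarray, src_pos: np.ndarray,
                        forces: np.ndarray, eps: float) -> np.ndarray:
    """Sum of free-space regularized Stokeslets (scaled by 8 pi mu)."""
    b = points[:, None, :] - src_pos[None, :, :]          # (K, M, 3)
    r2 = np.einsum("kmi,kmi->km", b, b)
    R3 = (r2 + eps * eps) ** 1.5
    fb = np.einsum("kmi,mi->km", b, forces)
    u = (forces[None, :, :] * (r2 + 2 * eps * eps)[:, :, None]
         + b * fb[:, :, None]) / R3[:, :, None]
    return u.sum(axis=1)


def _image_pairwise(points: np.ndarray, src_pos: np.ndarray,
                    forces: np.ndarray, eps: float) -> np.ndarray:
    """Wall-image correction, summed over sources (scaled by 8 pi mu)."""
    h = src_pos[:, 2]
    img = src_pos.copy()
    img[:, 2] = -h
    b = points[:, None, :] - img[None, :, :]              # (K, M, 3)
    r2 = np.einsum("kmi,kmi->km", b, b)
    e2 = eps * eps
    A = b[:, :, 0] * forces[None, :, 0] + b[:, :, 1] * forces[None, :, 1]
    f3 = forces[:, 2]
    s_fpar, s_f3e3, s_abpar, s_f3bpar, s_ae3 = image_scalar_factors(
        points[:, None, 2], h[None, :], e2, r2)

    u = np.zeros((points.shape[0], src_pos.shape[0], 3))
    u[:, :, 0] += forces[None, :, 0] * s_fpar
    u[:, :, 1] += forces[None, :, 1] * s_fpar
    u[:, :, 2] += f3[None, :] * s_f3e3
    coef_b = A * s_abpar + f3[None, :] * s_f3bpar
    u[:, :, 0] += b[:, :, 0] * coef_b
    u[:, :, 1] += b[:, :, 1] * coef_b
    u[:, :, 2] += A * s_ae3
    return u.sum(axis=1)


def freespace_velocity(points: np.ndarray, src: StokesletSet, mu: float = 1.0) -> np.ndarray:
    """Velocity of the free-space regularized-Stokeslet superposition."""
    if not mu > 0:
        raise ValueError("mu must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = _freespace_pairwise(pts, src.positions, src.forces, src.epsilon)
    u /= 8.0 * np.pi * mu
    return u if np.asarray(points).ndim == 2 else u[0]


def wall_velocity(points: np.ndarray, src: StokesletSet, mu: float = 1.0) -> np.ndarray:
    """Velocity with the no-slip wall at z = 0 enforced by the image system."""
    if not mu > 0:
        raise ValueError("mu must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(pts[:, 2] < 0):
        raise ValueError("evaluation points must satisfy z >= 0")
    u = _freespace_pairwise(pts, src.positions, src.forces, src.epsilon)
    u += _image_pairwise(pts, src.positions, src.forces, src.epsilon)
    u /= 8.0 * np.pi * mu
    return u if np.asarray(points).ndim == 2 else u[0]


def flow_velocity(points: np.ndarray, src: StokesletSet, params: FlowParams) -> np.ndarray:
    """Batched velocity evaluation honoring ``params.wall``.

    Uses the compiled kernel for large batch sizes when numba is available.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(pts[:, 2] < 0):
        raise ValueError("evaluation points must satisfy z >= 0")
    if HAVE_NUMBA and pts.shape[0] * src.positions.shape[0] >= 4096:
        out = np.empty_like(pts)
        _velocity_kernel(pts, src.positions, src.forces, src.epsilon,
                         params.wall, out)
        out /= 8.0 * np.pi * params.mu
    else:
        out = _freespace_pairwise(pts, src.positions, src.forces, src.epsilon)
        if params.wall:
            out += _image_pairwise(pts, src.positions, src.forces, src.epsilon)
        out /= 8.0 * np.pi * params.mu
    return out if np.asarray(points).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# force assembly
# ---------------------------------------------------------------------------

def pair_mobility_matrix(positions: np.ndarray, eps: float, mu: float = 1.0,
                         wall: bool = True) -> np.ndarray:
    """Dense 3M x 3M grand mobility matrix G with u = G f at the nodes."""
    M = positions.shape[0]
    G = np.empty((3 * M, 3 * M))
    unit = np.zeros((M, 3))
    for j in range(M):
        for comp in range(3):
            unit[:] = 0.0
            unit[j, comp] = 1.0
            src = StokesletSet(positions=positions, forces=unit, epsilon=eps)
            u = wall_velocity(positions, src, mu) if wall else \
                freespace_velocity(positions, src, mu)
            G[:, 3 * j + comp] = u.ravel()
    return G


def assemble_forces(node_positions: np.ndarray, node_velocities: np.ndarray,
                    params: FlowParams) -> StokesletSet:
    """Stokeslet strengths realizing the prescribed node velocities.

    Resistive mode: f_i = gamma v_i.  Mobility mode: solve the grand
    mobility system; ill-conditioning is reported with a condition estimate.
    """
    pos = np.atleast_2d(np.asarray(node_positions, dtype=float))
    vel = np.atleast_2d(np.asarray(node_velocities, dtype=float))
    if params.forcing_mode == "resistive":
        gamma = params.gamma if params.gamma is not None else 1.0
        return StokesletSet(positions=pos, forces=gamma * vel,
                            epsilon=params.epsilon)
    G = pair_mobility_matrix(pos, params.epsilon, params.mu, params.wall)
    cond = np.linalg.cond(G)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"mobility system ill-conditioned (cond ~ {cond:.2e}); "
            "nodes may be closer than the blob width")
    f = np.linalg.solve(G, vel.ravel())
    return StokesletSet(positions=pos, forces=f.reshape(-1, 3),
                        epsilon=params.epsilon)


def calibrate_gamma(law=None, fractions=None, epsilon: float = 0.1,
                    mu: float = 1.0, wall: bool = True, t: float = 0.25) -> float:
    """Resistive drag coefficient for one isolated rod at mid-stroke.

    gamma is chosen so the fluid speed evaluated at the tip node equals the
    prescribed tip speed: with unit gamma the tip fluid speed scales
    linearly, so gamma = |v_tip| / |u_tip(gamma=1)|.  The mid-effective
    stroke (phi = pi/2) is the calibration phase.
    """
    from ciliaflow.kinematics import BeatLaw, default_node_fractions, rods_nodes_at

    law = law or BeatLaw()
    if fractions is None:
        fractions = default_node_fractions()
    base = np.zeros((1, 3))
    pos, vel = rods_nodes_at(t, base, np.zeros(1), fractions, law)
    src = StokesletSet(positions=pos, forces=vel, epsilon=epsilon)
    tip = pos[-1][None, :]
    u_tip = wall_velocity(tip, src, mu) if wall else freespace_velocity(tip, src, mu)
    speed_flow = np.linalg.norm(u_tip[0])
    speed_rod = np.linalg.norm(vel[-1])
    if speed_flow == 0:
        raise ValueError("degenerate calibration: zero tip flow")
    return float(speed_rod / speed_flow)


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _velocity_kernel(points, src_pos, forces, eps, wall, out):  # pragma: no cover
        K = points.shape[0]
        M = src_pos.shape[0]
        e2 = eps * eps
        for k in range(K):
            px, py, pz = points[k, 0], points[k, 1], points[k, 2]
            ux = 0.0
            uy = 0.0
            uz = 0.0
            for m in range(M):
                fx, fy, fz = forces[m, 0], forces[m, 1], forces[m, 2]
                bx = px - src_pos[m, 0]
                by = py - src_pos[m, 1]
                bz = pz - src_pos[m, 2]
                r2 = bx * bx + by * by + bz * bz
                R2 = r2 + e2
                inv3 = 1.0 / (R2 * np.sqrt(R2))
                fb = fx * bx + fy * by + fz * bz
                c1 = (r2 + 2.0 * e2) * inv3
                ux += fx * c1 + bx * fb * inv3
                uy += fy * c1 + by * fb * inv3
                uz += fz * c1 + bz * fb * inv3
                if wall:
                    h = src_pos[m, 2]
                    b3 = pz + h
                    r2 = bx * bx + by * by + b3 * b3
                    invR2 = 1.0 / (r2 + e2)
                    invR = np.sqrt(invR2)
                    i3 = invR * invR2
                    i5 = i3 * invR2
                    i7 = i5 * invR2
                    hz = h * pz
                    b3sq = b3 * b3
                    A = fx * bx + fy * by
                    s_fpar = -invR - e2 * i3 + hz * (-3.0 * b3sq * i5
                                                     + 3.75 * e2 * (e2 + b3sq) * i7)
                    s_f3e3 = -invR - (e2 + b3sq) * i3 \
                        + 2.0 * hz * (r2 - 2.0 * e2 - 3.0 * b3sq) * i5
                    s_abpar = -i3 + hz * (3.0 * i5 + 3.75 * e2 * i7)
                    s_f3bpar = (2.0 * h - b3) * i3 - 6.0 * b3 * hz * i5
                    s_ae3 = (2.0 * h - b3) * i3 + 6.0 * b3 * hz * i5
                    cb = A * s_abpar + fz * s_f3bpar
                    ux += fx * s_fpar + bx * cb
                    uy += fy * s_fpar + by * cb
                    uz += fz * s_f3e3 + A * s_ae3
            out[k, 0] = ux
            out[k, 1] = uy
            out[k, 2] = uz
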