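"""Analysis statistics for tracer trajectories and flow fields.

Four quantities summarize a run:

* **Center of mass** of all tracers per snapshot — the scalar measure of
  directional clearance (the physiological direction is -x).
* **Mixing number** ``m``: the geometric mean, over tracers of group 1, of
  the squared distance to the nearest tracer of group 2,

      m = ( prod_i  min_j |z_i - z_j|^2 )^(1/N1).

  m is large while the groups are segregated and decreases toward zero as
  they interpenetrate; it is reported normalized by its initial value.
* **Ripley's K** of the in-plane tracer positions with the complete spatial
  randomness (CSR) reference pi*r^2: values above the reference indicate
  aggregation (tracers trapped in swirls), below indicate dispersion.  The
  first down-crossing radius r0 measures the characteristic swirl size.
* **Cycle-averaged velocity fields** on a horizontal grid with the planar
  vorticity omega_z = dv/dx - du/dy, mapping the mesoscale swirl structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ComSeries:
    """Center-of-mass trajectory: times in cycles, coordinates in um."""

    times: np.ndarray
    xc: np.ndarray
    yc: np.ndarray
    zc: np.ndarray
    xc_sd: Optional[np.ndarray] = None
    yc_sd: Optional[np.ndarray] = None
    zc_sd: Optional[np.ndarray] = None


@dataclass(frozen=True)
class MixingSeries:
    times: np.ndarray
    m: np.ndarray
    m_over_m0: np.ndarray
    exact_zero: bool = False


@dataclass(frozen=True)
class RipleyResult:
    r_grid: np.ndarray
    K: np.ndarray
    csr_reference: np.ndarray
    r0: Optional[float]
    n_points: int
    window_area: float


@dataclass(frozen=True)
class FieldGrid:
    """Cycle-averaged in-plane velocity and vorticity on a horizontal grid."""

    z_plane: float
    x: np.ndarray
    y: np.ndarray
    u_avg: np.ndarray
    v_avg: np.ndarray
    omega_z: np.ndarray


def center_of_mass(times: np.ndarray, positions: np.ndarray) -> ComSeries:
    """Unweighted mean tracer position per snapshot.

    ``positions`` has shape (snapshots, tracers, 3).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[1] < 1:
        raise ValueError("positions must be (snapshots, tracers, 3) with >= 1 tracer")
    com = positions.mean(axis=1)
    return ComSeries(times=np.asarray(times, dtype=float),
                     xc=com[:, 0], yc=com[:, 1], zc=com[:, 2])


def aggregate_com(series: Sequence[ComSeries]) -> ComSeries:
    """Ensemble mean and standard deviation across realizations."""
    if not series:
        raise ValueError("need at least one realization")
    t = series[0].times
    xs = np.stack([s.xc for s in series])
    ys = np.stack([s.yc for s in series])
    zs = np.stack([s.zc for s in series])
    return ComSeries(times=t, xc=xs.mean(0), yc=ys.mean(0), zc=zs.mean(0),
                     xc_sd=xs.std(0), yc_sd=ys.std(0), zc_sd=zs.std(0))


def mixing_number(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Geometric mean over group-A tracers of squared nearest-B distance.

    Computed in log space to avoid under/overflow of the N1-fold product.
    A coincident pair makes the product exactly zero; 0.0 is returned in
    that case.  Distances are full 3-vector distances.  Note the statistic
    is asymmetric in (A, B); it is computed exactly as defined, with A the
    first group.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    d, _ = cKDTree(b).query(a, k=1)
    if np.any(d == 0.0):
        return 0.0
    return float(np.exp(2.0 * np.mean(np.log(d))))


def mixing_series(times: np.ndarray, positions: np.ndarray,
                  labels: np.ndarray, group_a, group_b) -> MixingSeries:
    """Mixing number per snapshot for two labelled tracer groups."""
    labels = np.asarray(labels)
    sel_a = labels == group_a
    sel_b = labels == group_b
    m = np.array([mixing_number(snap[sel_a], snap[sel_b]) for snap in positions])
    m0 = m[0]
    norm = m / m0 if m0 > 0 else np.full_like(m, np.nan)
    return MixingSeries(times=np.asarray(times, dtype=float), m=m,
                        m_over_m0=norm, exact_zero=bool(np.any(m == 0.0)))


def ripley_k(points: np.ndarray, window: tuple, r_grid: np.ndarray,
             correction: str = "none") -> RipleyResult:
    """Ripley's K of a 2-D point pattern in a rectangular window.

    K(r) = A / (n (n-1)) * #{ordered pairs i != j with d_ij <= r}, with A
    the window area.  ``window`` is (xmin, xmax, ymin, ymax); points outside
    it are discarded.  ``correction`` is "none" (default) or "translation"
    (pairs weighted by the reciprocal overlap fraction of the translated
    window, removing edge bias).

    The crossing radius r0 is the first radius at which K - pi r^2 changes
    sign from + to - after an initial exceedance, located by linear
    interpolation; None when K never exceeds the CSR reference.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    xmin, xmax, ymin, ymax = window
    inside = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
              & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
    pts = pts[inside]
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two points inside the window")
    area = (xmax - xmin) * (ymax - ymin)
    r_grid = np.asarray(r_grid, dtype=float)

    tree = cKDTree(pts)
    if correction == "none":
        # cumulative ordered-pair counts within each radius
        counts = np.array([2 * len(tree.query_pairs(r)) for r in r_grid], dtype=float)
        K = area * counts / (n * (n - 1))
    elif correction == "translation":
        Lx, Ly = xmax - xmin, ymax - ymin
        pairs = sorted(tree.query_pairs(float(r_grid.max()))) if r_grid.size else []
        if pairs:
            idx = np.asarray(pairs)
            dxy = np.abs(pts[idx[:, 0]] - pts[idx[:, 1]])
            d = np.hypot(dxy[:, 0], dxy[:, 1])
            # weight = reciprocal overlap fraction of the window translated by the pair offset
            w = (Lx * Ly) / ((Lx - dxy[:, 0]) * (Ly - dxy[:, 1]))
            K = np.array([2.0 * w[d <= r].sum() for r in r_grid]) * area / (n * (n - 1))
        else:
            K = np.zeros_like(r_grid)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    csr = np.pi * r_grid ** 2
    r0 = _first_downcrossing(r_grid, K - csr)
    return RipleyResult(r_grid=r_grid, K=K, csr_reference=csr, r0=r0,
                        n_points=n, window_area=area)


def _first_downcrossing(r: np.ndarray, diff: np.ndarray) -> Optional[float]:
    """First +to- sign change of ``diff`` after an initial exceedance."""
    exceeded = False
    for i in range(len(r) - 1):
        if diff[i] > 0:
            exceeded = True
        if exceeded and diff[i] > 0 and diff[i + 1] <= 0:
            # linear interpolation of the zero
            t = diff[i] / (diff[i] - diff[i + 1])
            return float(r[i] + t * (r[i + 1] - r[i]))
    return None


def vorticity_z(x: np.ndarray, y: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Planar vorticity dv/dx - du/dy by central differences (one-sided at edges).

    ``u``, ``v`` are sampled on the grid with shape (len(y), len(x)) in
    meshgrid 'xy' layout.
    """
    dvdx = np.gradient(v, x, axis=1)
    dudy = np.gradient(u, y, axis=0)
    return dvdx - dudy


def cycle_averaged_field(system, z_plane: float, x: np.ndarray, y: np.ndarray,
                         phases_per_cycle: int = 64) -> FieldGrid:
    """Arithmetic mean of the flow over equispaced phases of one beat cycle.

    ``system`` must expose ``velocity_at(points, t)`` (see
    :class:`ciliaflow.transport.CiliaSystem`).  The average is a periodic
    trapezoid rule, spectrally accurate in ``phases_per_cycle``.
    """
    if z_plane <= 0:
        raise ValueError("z_plane must be above the wall")
    X, Y = np.meshgrid(x, y)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z_plane))])
    acc = np.zeros((pts.shape[0], 3))
    for k in range(phases_per_cycle):
        t = k / phases_per_cycle
        acc += system.velocity_at(pts, t)
    acc /= phases_per_cycle
    u = acc[:, 0].reshape(X.shape)
    v = acc[:, 1].reshape(X.shape)
    om = vorticity_z(x, y, u, v)
    return FieldGrid(z_plane=float(z_plane), x=np.asarray(x, dtype=float),
                     y=np.asarray(y, dtype=float), u_avg=u, v_avg=v, omega_z=om)
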