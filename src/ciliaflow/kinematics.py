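"""Prescribed rigid-rod cilium kinematics.

A cilium is idealized as a rigid rod anchored on the wall plane z = 0 that
rotates counterclockwise about the vertical axis through its base.  The
azimuthal phase advances linearly, ``phi(t) = phi0 + omega*t``; the polar
angle ``theta`` (measured from the (x, y)-plane) and the rod length ``L``
are prescribed functions of phase.  During the forward (effective) stroke,
``phi in [0, pi]``, the rod is fully extended; during the recovery stroke it
shortens following a cubic law, mimicking the bent return sweep of a real
cilium.  With counterclockwise rotation the effective stroke sweeps through
the -x half-plane, so the net pumping direction is -x.

The canonical time unit throughout the package is one beat cycle, so the
default angular velocity is 2*pi per cycle.  Wall-clock seconds for a beat
frequency ``f`` Hz are ``cycles / f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

TWO_PI = 2.0 * np.pi

#: Recovery-stroke cubic coefficients (c3, c2, c1, c0), phase in radians,
#: length in micrometres.
RECOVERY_COEFFS = (-0.3235, 5.2009, -26.6650, 49.4710)

THETA_SHAPES = ("sine", "cosine", "triangle")


@dataclass(frozen=True)
class BeatLaw:
    """Parameters of the prescribed beat.

    Attributes
    ----------
    omega : float
        Angular velocity in rad per time unit.  The package convention is
        time in beat cycles, hence the default ``2*pi``.
    theta_min, theta_max : float
        Range of the polar angle in radians (default [0.8, 2.4]).
    L_fwd : float
        Rod length during the forward stroke, micrometres (default 7).
    recovery_coeffs : tuple
        Cubic coefficients (c3, c2, c1, c0) of the recovery-stroke length
        law, evaluated on phi in (pi, 2*pi), result in micrometres.
    theta_shape : str
        Interpolation rule for theta(phi): "sine" (smooth, default; theta
        peaks at mid-effective stroke and is lowest at mid-recovery),
        "cosine" (theta_min at phi = 0, theta_max at phi = pi) or
        "triangle" (piecewise linear between the same endpoints as
        "cosine").
    freq_hz : float
        Beat frequency used only to convert cycles to seconds in reports.
    """

    omega: float = TWO_PI
    theta_min: float = 0.8
    theta_max: float = 2.4
    L_fwd: float = 7.0
    recovery_coeffs: Tuple[float, float, float, float] = RECOVERY_COEFFS
    theta_shape: str = "sine"
    freq_hz: float = 18.0

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if not (0 < self.theta_min < self.theta_max < np.pi):
            raise ValueError("need 0 < theta_min < theta_max < pi")
        if not self.L_fwd > 0:
            raise ValueError("L_fwd must be positive")
        if self.theta_shape not in THETA_SHAPES:
            raise ValueError(f"unknown theta_shape {self.theta_shape!r}")
        phi = np.linspace(np.pi, TWO_PI, 512, endpoint=False)
        L = np.polyval(self.recovery_coeffs, phi)
        if L.min() <= 0 or L.max() > self.L_fwd + 0.01:
            raise ValueError("recovery cubic leaves (0, L_fwd + 0.01]")

    @property
    def period(self) -> float:
        return TWO_PI / self.omega


def default_node_fractions(n: int = 15) -> np.ndarray:
    """Uniform Lagrangian fractions i/n, i = 1..n (tip included, base omitted)."""
    if n < 1:
        raise ValueError("need at least one node")
    return np.arange(1, n + 1, dtype=float) / n


@dataclass(frozen=True)
class RodConfig:
    """A single rod: base position on the wall and its phase offset.

    ``node_fractions`` are the fixed Lagrangian fractions sigma_i in (0, 1]
    at which Stokeslet nodes ride; the physical arclength of node i is
    sigma_i * L(phi), so nodes follow the rod as it shortens.
    """

    base: np.ndarray
    phase_offset: float = 0.0
    node_fractions: np.ndarray = field(default_factory=default_node_fractions)

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float).reshape(3)
        object.__setattr__(self, "base", base)
        if base[2] != 0.0:
            raise ValueError("rod base must sit on the wall plane z = 0")
        frac = np.asarray(self.node_fractions, dtype=float)
        if frac.ndim != 1 or frac.size == 0:
            raise ValueError("node_fractions must be a non-empty 1-D array")
        if np.any(np.diff(frac) <= 0) or not (0 < frac[0]) or frac[-1] != 1.0:
            raise ValueError("node_fractions must be strictly increasing in (0, 1] with last = 1")
        object.__setattr__(self, "node_fractions", frac)


@dataclass(frozen=True)
class RodPose:
    """Node positions and analytic node velocities of one rod at one instant."""

    time: float
    phase: float
    node_positions: np.ndarray
    node_velocities: np.ndarray


def phase_at(t, phi0: float, omega: float):
    """Instantaneous phase ``(phi0 + omega*t) mod 2*pi``, in [0, 2*pi)."""
    if not omega > 0:
        raise ValueError("omega must be positive")
    phi = np.mod(phi0 + omega * np.asarray(t, dtype=float), TWO_PI)
    # np.mod of a tiny negative argument rounds to the modulus itself
    phi = np.where(phi >= TWO_PI, 0.0, phi)
    return phi if phi.ndim else float(phi)


def _check_phase(phi: np.ndarray) -> None:
    if np.any(phi < 0) or np.any(phi >= TWO_PI):
        raise ValueError("phase must lie in [0, 2*pi); wrap with phase_at first")


def _wrap_blend(law: BeatLaw):
    """Linear blend pinning the recovery branch to L_fwd at both ends.

    The recovery cubic evaluates to L_fwd only approximately at the stroke
    switches (within ~1e-3 um at phi = pi, ~9e-3 um at phi = 2*pi).  An
    unblended branch would make the rod *position* jump at the cycle wrap,
    which breaks time-integration convergence, so the linear interpolant of
    the two endpoint mismatches is subtracted; the adjustment is below 0.01
    um everywhere.
    """
    a = np.polyval(law.recovery_coeffs, np.pi) - law.L_fwd
    b = np.polyval(law.recovery_coeffs, TWO_PI) - law.L_fwd
    slope = (b - a) / np.pi
    return a, slope


def rod_length(phi, law: BeatLaw = BeatLaw()):
    """Rod length L(phi): L_fwd on the forward stroke, recovery cubic after.

    The recovery branch is the prescribed cubic minus the linear blend that
    makes L exactly continuous at both stroke switches (see ``_wrap_blend``).
    """
    phi = np.asarray(phi, dtype=float)
    _check_phase(phi)
    a, slope = _wrap_blend(law)
    rec = np.polyval(law.recovery_coeffs, phi) - (a + slope * (phi - np.pi))
    L = np.where(phi <= np.pi, law.L_fwd, rec)
    return L if L.ndim else float(L)


def rod_length_dphi(phi, law: BeatLaw = BeatLaw()):
    """One-sided derivative dL/dphi of the active stroke branch.

    dL/dphi is discontinuous at the stroke switches phi in {0, pi}; the
    derivative of the branch currently in force is returned there.
    """
    phi = np.asarray(phi, dtype=float)
    _check_phase(phi)
    _, slope = _wrap_blend(law)
    dcoeffs = np.polyder(np.asarray(law.recovery_coeffs))
    dL = np.where(phi <= np.pi, 0.0, np.polyval(dcoeffs, phi) - slope)
    return dL if dL.ndim else float(dL)


def polar_angle(phi, law: BeatLaw = BeatLaw()):
    """Polar angle theta(phi) and its phase derivative.

    The beat is constrained to theta in [theta_min, theta_max]; the
    interpolation between the endpoints is a modelling choice:

    - "sine" (default): theta = theta_mid + (span/2)*sin(phi), smooth and
      2*pi-periodic; theta peaks at phi = pi/2 (mid-effective stroke, rod
      leaning past vertical) and bottoms at phi = 3*pi/2 (mid-recovery, rod
      sweeping low over the surface).  This alignment makes the effective
      stroke pump fluid toward -x at cilium-tip heights while the recovery
      backflow stays close to the wall.
    - "cosine": theta = theta_min + (span/2)*(1 - cos phi), hitting
      theta_min at phi = 0 and theta_max at phi = pi.
    - "triangle": piecewise-linear tent over [0, 2*pi], same endpoints as
      "cosine".
    """
    phi = np.asarray(phi, dtype=float)
    _check_phase(phi)
    span = law.theta_max - law.theta_min
    if law.theta_shape == "sine":
        mid = 0.5 * (law.theta_min + law.theta_max)
        theta = mid + 0.5 * span * np.sin(phi)
        dtheta = 0.5 * span * np.cos(phi)
    elif law.theta_shape == "cosine":
        theta = law.theta_min + 0.5 * span * (1.0 - np.cos(phi))
        dtheta = 0.5 * span * np.sin(phi)
    else:  # triangle
        up = phi <= np.pi
        theta = np.where(up, law.theta_min + span * phi / np.pi,
                         law.theta_max - span * (phi - np.pi) / np.pi)
        dtheta = np.where(up, span / np.pi, -span / np.pi)
    if theta.ndim:
        return theta, dtheta
    return float(theta), float(dtheta)


def _pose_arrays(phi: np.ndarray, fractions: np.ndarray, law: BeatLaw):
    """Unit direction/velocity pieces for phases ``phi`` (any shape).

    Returns (e, de_dphi, L, dL_dphi) with e of shape phi.shape + (3,).
    """
    theta, dtheta = polar_angle(phi, law)
    L = rod_length(phi, law)
    dL = rod_length_dphi(phi, law)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    e = np.stack([ct * cp, ct * sp, st], axis=-1)
    de = np.stack([-st * dtheta * cp - ct * sp,
                   -st * dtheta * sp + ct * cp,
                   ct * dtheta], axis=-1)
    return e, de, np.asarray(L), np.asarray(dL)


def rod_pose(t: float, rod: RodConfig, law: BeatLaw = BeatLaw()) -> RodPose:
    """Node positions and analytic velocities of ``rod`` at time ``t``.

    Node i sits at ``base + sigma_i * L(phi) * e(phi)`` with e the unit rod
    direction; its velocity is the exact chain-rule derivative
    ``omega * sigma_i * (dL/dphi * e + L * de/dphi)``, including the
    shortening term along the rod axis.
    """
    phi = float(phase_at(t, rod.phase_offset, law.omega))
    e, de, L, dL = _pose_arrays(np.asarray(phi), rod.node_fractions * 0.0 + 1.0, law)
    s = rod.node_fractions[:, None]
    pos = rod.base[None, :] + s * (float(L) * e)[None, :]
    vel = law.omega * s * (float(dL) * e + float(L) * de)[None, :]
    return RodPose(time=float(t), phase=phi, node_positions=pos, node_velocities=vel)


def rods_nodes_at(t: float, bases: np.ndarray, phase_offsets: np.ndarray,
                  fractions: np.ndarray, law: BeatLaw):
    """Vectorized node kinematics for many rods sharing one fraction set.

    Parameters
    ----------
    bases : (n, 3) array of rod base positions (z = 0).
    phase_offsets : (n,) array of phase lags phi0.
    fractions : (m,) Lagrangian node fractions.

    Returns
    -------
    positions, velocities : (n*m, 3) arrays, rod-major ordering.
    """
    phi = phase_at(t, np.asarray(phase_offsets, dtype=float), law.omega)
    e, de, L, dL = _pose_arrays(phi, fractions, law)
    s = np.asarray(fractions, dtype=float)
    # (n, m, 3): base + s_j * L_i * e_i
    pos = bases[:, None, :] + s[None, :, None] * (L[:, None, None] * e[:, None, :])
    vel = law.omega * s[None, :, None] * (dL[:, None, None] * e[:, None, :]
                                          + L[:, None, None] * de[:, None, :])
    return pos.reshape(-1, 3), vel.reshape(-1, 3)


def cycles_to_seconds(cycles, freq_hz: float = 18.0) -> np.ndarray:
    """Convert beat-cycle counts to seconds at the given beat frequency."""
    return np.asarray(cycles, dtype=float) / freq_hz
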