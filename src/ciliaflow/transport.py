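"""Passive tracer seeding and advection through the cilia-driven flow.

Tracers are massless: they move with the local fluid velocity,
``dx/dt = u(x, t)``, integrated with classical RK4 (default) or forward
Euler.  The flow is evaluated from the instantaneous rod kinematics at each
substage time, so the phase advances consistently within a step.  Tracers
may leave the tissue patch laterally (open boundaries); the wall-corrected
flow vanishes at z = 0, so tracers cannot cross the wall except by
integration error, which is clamped at a -1e-6 um tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ciliaflow.kinematics import BeatLaw, RodConfig, rods_nodes_at
from ciliaflow.geometry import rods_to_arrays
from ciliaflow.stokes import FlowParams, StokesletSet, flow_velocity, calibrate_gamma

#: tracers dipping below -Z_TOLERANCE trigger a numerics warning and clamp
Z_TOLERANCE = 1e-6

LABELING_RULES = ("none", "x_quartile", "z_half", "z_band")


@dataclass
class TracerSet:
    """Massless tracers with immutable group labels.

    ``labels`` are small integers; ``label_names`` maps them to the
    human-readable group names of the chosen labeling rule.
    """

    positions: np.ndarray
    initial_positions: np.ndarray
    labels: np.ndarray
    label_names: tuple

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (P, 3)")
        if np.any(self.positions[:, 2] < 0):
            raise ValueError("tracers must start in the half-space z >= 0")


@dataclass(frozen=True)
class IntegratorSpec:
    scheme: str = "rk4"
    steps_per_cycle: int = 100
    duration_cycles: int = 100
    sample_every: int = 1

    def __post_init__(self):
        if self.scheme not in ("rk4", "euler"):
            raise ValueError("scheme must be 'rk4' or 'euler'")
        if self.scheme == "rk4" and self.steps_per_cycle < 20:
            raise ValueError("rk4 accuracy contract needs steps_per_cycle >= 20")
        if self.steps_per_cycle < 1 or self.duration_cycles < 0 or self.sample_every < 1:
            raise ValueError("invalid integrator settings")


@dataclass(frozen=True)
class TrajectoryRecord:
    """Sampled tracer trajectories: cycles, positions (S, P, 3), labels."""

    cycles: np.ndarray
    positions: np.ndarray
    labels: np.ndarray
    label_names: tuple

    def com(self):
        from ciliaflow.metrics import center_of_mass
        return center_of_mass(self.cycles, self.positions)


class CiliaSystem:
    """A set of beating rods plus flow parameters; evaluates u(x, t).

    In resistive forcing mode each Stokeslet carries force gamma times the
    prescribed node velocity.  When ``flow.gamma`` is not set, a one-time
    calibration chooses gamma so that the fluid speed at the tip of an
    isolated mid-stroke rod matches the prescribed tip speed.
    """

    def __init__(self, rods: Sequence[RodConfig], law: Optional[BeatLaw] = None,
                 flow: Optional[FlowParams] = None):
        self.law = law or BeatLaw()
        self.flow = flow or FlowParams()
        self.rods = list(rods)
        self.bases, self.phase_offsets, self.fractions = rods_to_arrays(self.rods)
        if self.flow.forcing_mode == "resistive" and self.flow.gamma is None:
            gamma = calibrate_gamma(self.law, self.fractions,
                                    epsilon=self.flow.epsilon, mu=self.flow.mu,
                                    wall=self.flow.wall)
            self.flow = self.flow.with_gamma(gamma)

    def stokeslets_at(self, t: float) -> StokesletSet:
        from ciliaflow.stokes import assemble_forces
        pos, vel = rods_nodes_at(t, self.bases, self.phase_offsets,
                                 self.fractions, self.law)
        return assemble_forces(pos, vel, self.flow)

    def velocity_at(self, points: np.ndarray, t: float) -> np.ndarray:
        src = self.stokeslets_at(t)
        return flow_velocity(points, src, self.flow)


def seed_tracers(region, spacing: Optional[float] = None,
                 count: Optional[int] = None, labeling: str = "none") -> TracerSet:
    """Seed a regular lattice of tracers in an axis-aligned box.

    ``region`` is (xmin, xmax, ymin, ymax, zmin, zmax) in um.  Either a
    lattice ``spacing`` or an approximate total ``count`` must be given;
    with ``count``, the spacing is chosen for an isotropic lattice of about
    that many points.

    Labeling rules:

    - "x_quartile": four equal-width color bands by initial x (groups 0-3),
    - "z_half": bottom/top half by initial z (0 = bottom, 1 = top),
    - "z_band": three equal-height bands by initial z (0, 1, 2),
    - "none": all tracers in group 0.
    """
    xmin, xmax, ymin, ymax, zmin, zmax = (float(v) for v in region)
    if zmin < 0:
        raise ValueError("region must lie in the half-space z >= 0")
    ext = np.array([xmax - xmin, ymax - ymin, zmax - zmin])
    if np.any(ext < 0) or np.all(ext == 0):
        raise ValueError("empty region")
    if labeling not in LABELING_RULES:
        raise ValueError(f"unknown labeling rule {labeling!r}")
    if spacing is None:
        if count is None:
            raise ValueError("give either spacing or count")
        # isotropic lattice over the nonzero extents with ~count points
        nz = ext[ext > 0]
        spacing = float((np.prod(nz) / count) ** (1.0 / len(nz)))
    axes = []
    for lo, hi in ((xmin, xmax), (ymin, ymax), (zmin, zmax)):
        n = max(1, int(np.floor((hi - lo) / spacing)) + 1)
        # center the lattice in the box
        width = (n - 1) * spacing
        start = lo + ((hi - lo) - width) / 2.0
        axes.append(start + spacing * np.arange(n))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    if labeling == "x_quartile":
        edges = xmin + np.array([0.25, 0.5, 0.75]) * (xmax - xmin)
        labels = np.searchsorted(edges, pos[:, 0], side="right")
        names = ("black", "blue", "green", "red")
    elif labeling == "z_half":
        zmid = 0.5 * (zmin + zmax)
        labels = (pos[:, 2] >= zmid).astype(int)
        names = ("bottom", "top")
    elif labeling == "z_band":
        edges = zmin + np.array([1.0, 2.0]) / 3.0 * (zmax - zmin)
        labels = np.searchsorted(edges, pos[:, 2], side="right")
        names = ("low", "mid", "high")
    else:
        labels = np.zeros(len(pos), dtype=int)
        names = ("all",)
    return TracerSet(positions=pos.copy(), initial_positions=pos.copy(),
                     labels=labels.astype(int), label_names=names)


def advect(tracers: TracerSet, system: CiliaSystem,
           integrator: IntegratorSpec) -> TrajectoryRecord:
    """Advect tracers through the system flow; sample every few cycles.

    Deterministic: the trajectory depends only on the system configuration
    and the integrator settings.  The stokeslet configuration is assembled
    once per distinct substage time and shared across tracers.
    """
    dt = 1.0 / integrator.steps_per_cycle
    x = tracers.positions.copy()
    n_steps = integrator.duration_cycles * integrator.steps_per_cycle
    sample_stride = integrator.sample_every * integrator.steps_per_cycle

    snaps = [x.copy()]
    cycles = [0.0]
    warned = False

    # cache the flow evaluation per substage time within a step
    def u_at(pts, t):
        return system.velocity_at(pts, t)

    # endpoint stages are nudged into the step interior so that, when a step
    # boundary coincides with a stroke switch (phase 0 or pi), the one-sided
    # branch of the length law matching this step's interval is used;
    # the nudge itself perturbs smooth steps at the 1e-12 level only
    t_eps = 1e-9 * dt

    for step in range(n_steps):
        t = step * dt
        if integrator.scheme == "euler":
            x = x + dt * u_at(x, t + t_eps)
        else:
            k1 = u_at(x, t + t_eps)
            k2 = u_at(x + 0.5 * dt * k1, t + 0.5 * dt)
            k3 = u_at(x + 0.5 * dt * k2, t + 0.5 * dt)
            k4 = u_at(x + dt * k3, t + dt - t_eps)
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        zmin = x[:, 2].min()
        if zmin < 0:
            if zmin < -Z_TOLERANCE and not warned:
                warnings.warn(f"tracer crossed the wall by {-zmin:.2e} um; clamping to z=0",
                              RuntimeWarning)
                warned = True
            np.clip(x[:, 2], 0.0, None, out=x[:, 2])
        if (step + 1) % sample_stride == 0:
            snaps.append(x.copy())
            cycles.append((step + 1) * dt)

    tracers.positions = x
    return TrajectoryRecord(cycles=np.asarray(cycles),
                            positions=np.stack(snaps),
                            labels=tracers.labels.copy(),
                            label_names=tracers.label_names)
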