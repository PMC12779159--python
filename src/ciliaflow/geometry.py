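"""Tissue geometries: cilium base layouts and metachronal phase assignment.

Three scenario families are supported:

* a single 3x3 cluster of cilia with intra-cluster spacing D = 4 um
  (nominal footprint 8 um x 8 um, the bounding box of the 9 bases);
* a linear array of three such clusters along the x-axis with variable
  center-to-center spacing Dc in [3D, 12D];
* a random tissue patch: clusters placed uniformly at random, without
  overlap, inside a square patch (default 100 um x 100 um) at a target
  ciliary density nu = n * A_cluster / (Lx * Ly).

Spacing conventions.  Dc is center-to-center.  Each cluster's *effective*
footprint is taken as 12 um x 12 um (three 4-um cells per side), under which
Dc = 3D places clusters exactly edge-to-edge, forming one continuous lattice
of 4-um-spaced cilia.  For density bookkeeping, A_cluster stays the nominal
8 x 8 = 64 um^2 box that contains the cilia bases, and random patches use
the nominal footprint for the overlap and boundary rules (minimum center
separation 8 um in the Chebyshev metric): the tightest random packings then
match the tightest array spacing, and densities up to the physiological
maximum (~0.6) remain placeable by rejection sampling.

Metachrony: each 3x3 cluster is organized into three columns by base x;
column k (increasing x) receives phase offset k*phi0 while cilia within a
column stay synchronous.  phi0 > 0 is antiplectic (wave travels opposite to
the effective stroke, which points in -x), phi0 < 0 symplectic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from ciliaflow.kinematics import RodConfig, default_node_fractions

#: Intra-cluster rod spacing, micrometres.
D_SPACING = 4.0
#: Nominal cluster footprint area used for density bookkeeping, um^2.
A_CLUSTER = 64.0
#: Nominal cluster footprint side (bounding box of the 9 bases), um.
NOMINAL_SIDE = 8.0
#: Effective footprint side (three 4-um cells per side), um; used to
#: interpret array spacing (Dc = 3D is edge-to-edge).
EFFECTIVE_SIDE = 12.0


@dataclass(frozen=True)
class ClusterSpec:
    """A 3x3 cluster of cilia centred at ``center`` (2-vector, um)."""

    center: tuple = (0.0, 0.0)
    intra_spacing: float = D_SPACING

    def __post_init__(self) -> None:
        if not self.intra_spacing > 0:
            raise ValueError("intra_spacing must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))


@dataclass(frozen=True)
class ArraySpec:
    """Three clusters collinear on the x-axis, consecutive separation ``spacing_Dc``."""

    spacing_Dc: float
    intra_spacing: float = D_SPACING
    n_clusters: int = 3

    def __post_init__(self) -> None:
        if self.n_clusters != 3:
            raise ValueError("the array scenario uses exactly three clusters")
        if self.spacing_Dc < 3 * self.intra_spacing:
            raise ValueError("spacing_Dc below 3D: clusters would interpenetrate")


@dataclass(frozen=True)
class PatchSpec:
    """Random tissue patch of non-overlapping clusters at density ``density``."""

    density: float
    Lx: float = 100.0
    Ly: float = 100.0
    seed: int = 0
    min_separation: float = NOMINAL_SIDE
    intra_spacing: float = D_SPACING
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if not (0 <= self.density <= 0.7):
            raise ValueError("density must lie in [0, 0.7]")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("patch dimensions must be positive")


@dataclass(frozen=True)
class MetachronySpec:
    """Per-column phase increment phi0 applied along x within each cluster."""

    phase_increment: float = 0.0


class PatchPlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested clusters."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} clusters within the attempt budget")


def build_cluster(spec: ClusterSpec, node_fractions: np.ndarray | None = None) -> List[RodConfig]:
    """The 9 rods of one cluster: a regular 3x3 lattice, phase offsets 0.

    Bases sit at center + {-D, 0, +D} x {-D, 0, +D}; rods are emitted
    column-major in x so consecutive triples share a column.
    """
    if node_fractions is None:
        node_fractions = default_node_fractions()
    D = spec.intra_spacing
    cx, cy = spec.center
    rods = []
    for dx in (-D, 0.0, D):
        for dy in (-D, 0.0, D):
            rods.append(RodConfig(base=np.array([cx + dx, cy + dy, 0.0]),
                                  phase_offset=0.0,
                                  node_fractions=node_fractions))
    return rods


def build_array(spec: ArraySpec, node_fractions: np.ndarray | None = None) -> List[RodConfig]:
    """27 rods: three clusters centred at x = -Dc, 0, +Dc on the x-axis."""
    rods: List[RodConfig] = []
    for cx in (-spec.spacing_Dc, 0.0, spec.spacing_Dc):
        rods.extend(build_cluster(ClusterSpec(center=(cx, 0.0),
                                              intra_spacing=spec.intra_spacing),
                                  node_fractions))
    return rods


def sample_patch(spec: PatchSpec) -> List[ClusterSpec]:
    """Place ``round(nu*Lx*Ly/A_cluster)`` non-overlapping clusters uniformly.

    Cluster centers are drawn uniformly over the admissible region (nominal
    8x8 footprints fully inside the patch); a candidate is rejected when its
    center comes within ``min_separation`` (Chebyshev distance, i.e. square
    footprints would overlap) of an accepted one.  Reproducible from
    ``spec.seed``.
    """
    n_target = int(round(spec.density * spec.Lx * spec.Ly / A_CLUSTER))
    rng = np.random.default_rng(spec.seed)
    half = NOMINAL_SIDE / 2.0
    lox, hix = -spec.Lx / 2 + half, spec.Lx / 2 - half
    loy, hiy = -spec.Ly / 2 + half, spec.Ly / 2 - half
    centers: List[np.ndarray] = []
    attempts = 0
    while len(centers) < n_target and attempts < spec.max_attempts:
        attempts += 1
        cand = rng.uniform((lox, loy), (hix, hiy))
        ok = True
        for c in centers:
            if max(abs(cand[0] - c[0]), abs(cand[1] - c[1])) < spec.min_separation:
                ok = False
                break
        if ok:
            centers.append(cand)
    if len(centers) < n_target:
        raise PatchPlacementError(n_target, len(centers))
    return [ClusterSpec(center=(c[0], c[1]), intra_spacing=spec.intra_spacing)
            for c in centers]


def build_patch(spec: PatchSpec, node_fractions: np.ndarray | None = None) -> List[RodConfig]:
    """All rods of a random patch realization (9 per sampled cluster)."""
    rods: List[RodConfig] = []
    for cluster in sample_patch(spec):
        rods.extend(build_cluster(cluster, node_fractions))
    return rods


def assign_phases(rods: Sequence[RodConfig], spec: MetachronySpec) -> List[RodConfig]:
    """Set per-rod phase offsets to k*phi0 by column index within each cluster.

    Rods are grouped into clusters of 9 (the construction order of
    ``build_cluster``); within each cluster the three distinct base-x values
    define columns k = 0, 1, 2 in increasing x.  Idempotent and independent
    of rod order within a cluster.
    """
    phi0 = spec.phase_increment
    out: List[RodConfig] = []
    if len(rods) % 9 != 0:
        raise ValueError("rods must come in whole 3x3 clusters")
    for start in range(0, len(rods), 9):
        cluster = rods[start:start + 9]
        xs = np.array([r.base[0] for r in cluster])
        cols = np.unique(np.round(xs, 9))
        if cols.size != 3:
            raise ValueError("cluster does not have three distinct columns")
        for r in cluster:
            k = int(np.searchsorted(cols, round(r.base[0], 9)))
            out.append(replace(r, phase_offset=k * phi0))
    return out


def rods_to_arrays(rods: Sequence[RodConfig]):
    """Stack rod bases and phase offsets; all rods must share node fractions."""
    bases = np.array([r.base for r in rods])
    offsets = np.array([r.phase_offset for r in rods])
    frac = rods[0].node_fractions
    for r in rods:
        if r.node_fractions.shape != frac.shape or np.any(r.node_fractions != frac):
            raise ValueError("all rods must share one node-fraction set")
    return bases, offsets, frac
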