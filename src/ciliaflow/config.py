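"""Scenario configuration, orchestration and persistence.

A scenario is described by a nested, YAML-serializable mapping with blocks
for geometry, beat kinematics, flow, metachrony, tracers, integration and
seeds.  Three scenario kinds are provided:

- ``single_cluster``: one 3x3 cluster at the origin;
- ``three_clusters``: a linear array of three clusters with spacing Dc;
- ``tissue_patch``: randomly placed clusters at a target ciliary density.

Unknown keys are rejected; every run artifact embeds the fully resolved
configuration so results are reproducible from the artifact alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ciliaflow.kinematics import BeatLaw, default_node_fractions, cycles_to_seconds
from ciliaflow.geometry import (ArraySpec, ClusterSpec, MetachronySpec, PatchSpec,
                                D_SPACING, assign_phases, build_array, build_cluster,
                                build_patch)
from ciliaflow.stokes import FlowParams
from ciliaflow.transport import (CiliaSystem, IntegratorSpec, TrajectoryRecord,
                                 advect, seed_tracers)
from ciliaflow.metrics import mixing_series, ripley_k

SCENARIO_KINDS = ("single_cluster", "three_clusters", "tissue_patch")


def _from_mapping(cls, data: dict, block: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {block!r} block: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class GeometryBlock:
    Dc: float = 5 * D_SPACING          # three_clusters: center-to-center spacing, um
    density: float = 0.1               # tissue_patch: ciliary density nu
    Lx: float = 100.0
    Ly: float = 100.0
    nodes_per_rod: int = 15


@dataclass(frozen=True)
class TracerBlock:
    region: Optional[tuple] = None     # (xmin,xmax,ymin,ymax,zmin,zmax); None = scenario default
    count: int = 0                     # 0 = scenario default
    labeling: str = "x_quartile"


@dataclass(frozen=True)
class ScenarioConfig:
    kind: str = "single_cluster"
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    beat: BeatLaw = field(default_factory=BeatLaw)
    flow: FlowParams = field(default_factory=FlowParams)
    metachrony: MetachronySpec = field(default_factory=MetachronySpec)
    tracers: TracerBlock = field(default_factory=TracerBlock)
    integrator: IntegratorSpec = field(default_factory=IntegratorSpec)
    seeds: tuple = (0,)

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")

    # ---- serialization ----
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        d["beat"]["recovery_coeffs"] = list(self.beat.recovery_coeffs)
        if d["tracers"]["region"] is not None:
            d["tracers"]["region"] = list(d["tracers"]["region"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kw = {}
        if "kind" in data:
            kw["kind"] = data["kind"]
        if "geometry" in data:
            kw["geometry"] = _from_mapping(GeometryBlock, data["geometry"], "geometry")
        if "beat" in data:
            b = dict(data["beat"])
            if "recovery_coeffs" in b:
                b["recovery_coeffs"] = tuple(b["recovery_coeffs"])
            kw["beat"] = _from_mapping(BeatLaw, b, "beat")
        if "flow" in data:
            kw["flow"] = _from_mapping(FlowParams, data["flow"], "flow")
        if "metachrony" in data:
            kw["metachrony"] = _from_mapping(MetachronySpec, data["metachrony"], "metachrony")
        if "tracers" in data:
            tr = dict(data["tracers"])
            if tr.get("region") is not None:
                tr["region"] = tuple(tr["region"])
            kw["tracers"] = _from_mapping(TracerBlock, tr, "tracers")
        if "integrator" in data:
            kw["integrator"] = _from_mapping(IntegratorSpec, data["integrator"], "integrator")
        if "seeds" in data:
            kw["seeds"] = tuple(int(s) for s in data["seeds"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---- scenario construction ------------------------------------------------

def build_rods(config: ScenarioConfig, seed: int = 0):
    """Rod configurations (with metachronal phases applied) for a scenario."""
    frac = default_node_fractions(config.geometry.nodes_per_rod)
    if config.kind == "single_cluster":
        rods = build_cluster(ClusterSpec(center=(0.0, 0.0)), frac)
    elif config.kind == "three_clusters":
        rods = build_array(ArraySpec(spacing_Dc=config.geometry.Dc), frac)
    else:
        spec = PatchSpec(density=config.geometry.density, Lx=config.geometry.Lx,
                         Ly=config.geometry.Ly, seed=seed)
        rods = build_patch(spec, frac)
    return assign_phases(rods, config.metachrony)


def default_tracer_setup(config: ScenarioConfig):
    """Scenario-default seeding region, count and labeling."""
    kind = config.kind
    if kind == "single_cluster":
        region = (-10.0, 10.0, -10.0, 10.0, 1.0, 9.0)
        count = 500
    elif kind == "three_clusters":
        half = config.geometry.Dc + 12.0
        region = (-half, half, -10.0, 10.0, 5.0, 9.0)
        count = 1000
    else:
        region = (-50.0, 50.0, -50.0, 50.0, 5.0, 9.0)
        count = 2000
    tb = config.tracers
    return (tb.region or region, tb.count or count, tb.labeling)


@dataclass(frozen=True)
class RunArtifact:
    config: ScenarioConfig
    seed: int
    record: TrajectoryRecord
    gamma: float


def run_scenario(config: ScenarioConfig, seed: Optional[int] = None) -> RunArtifact:
    """Build the scenario, advect tracers, and return the trajectory record."""
    seed = config.seeds[0] if seed is None else int(seed)
    rods = build_rods(config, seed=seed)
    system = CiliaSystem(rods, law=config.beat, flow=config.flow)
    region, count, labeling = default_tracer_setup(config)
    tracers = seed_tracers(region, count=count, labeling=labeling)
    record = advect(tracers, system, config.integrator)
    return RunArtifact(config=config, seed=seed, record=record,
                       gamma=system.flow.gamma if system.flow.gamma is not None else 0.0)


SWEEP_PARAMETERS = ("Dc", "phi0", "nu")


def _with_parameter(config: ScenarioConfig, parameter: str, value: float) -> ScenarioConfig:
    if parameter == "Dc":
        if config.kind != "three_clusters":
            raise ValueError("Dc sweeps require the three_clusters scenario")
        geom = dataclasses.replace(config.geometry, Dc=float(value))
        return dataclasses.replace(config, geometry=geom)
    if parameter == "phi0":
        return dataclasses.replace(config, metachrony=MetachronySpec(phase_increment=float(value)))
    if parameter == "nu":
        if config.kind != "tissue_patch":
            raise ValueError("nu sweeps require the tissue_patch scenario")
        geom = dataclasses.replace(config.geometry, density=float(value))
        return dataclasses.replace(config, geometry=geom)
    raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {SWEEP_PARAMETERS}")


def sweep(config: ScenarioConfig, parameter: str, values: Sequence[float],
          ensemble: bool = False):
    """One run per value; comparison table of final CoM, m/m0 and r0.

    With ``ensemble=True`` every seed in ``config.seeds`` is run per value
    and the table reports mean and standard deviation across seeds.
    """
    rows = []
    artifacts = []
    seeds = config.seeds if ensemble else config.seeds[:1]
    for value in values:
        cfg = _with_parameter(config, parameter, value)
        per_seed = []
        for seed in seeds:
            art = run_scenario(cfg, seed=seed)
            artifacts.append(art)
            per_seed.append(_summarize(art))
        df = pd.DataFrame(per_seed)
        row = {parameter: value}
        for col in df.columns:
            row[col] = df[col].mean()
            if ensemble and len(seeds) > 1:
                row[col + "_sd"] = df[col].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows), artifacts


def _summarize(art: RunArtifact) -> dict:
    rec = art.record
    com = rec.com()
    out = {
        "dx": float(com.xc[-1] - com.xc[0]),
        "dy": float(com.yc[-1] - com.yc[0]),
        "dz": float(com.zc[-1] - com.zc[0]),
    }
    if len(rec.label_names) >= 2 and (rec.labels == 0).any() and (rec.labels == 1).any():
        ms = mixing_series(rec.cycles, rec.positions, rec.labels, 0, 1)
        out["m_over_m0"] = float(ms.m_over_m0[-1])
    final = rec.positions[-1]
    layer = np.abs(final[:, 2] - 7.0) <= 1.0
    if layer.sum() >= 10:
        res = ripley_k(final[layer, :2], (-100, 100, -100, 100),
                       np.linspace(0.5, 60, 120))
        out["r0"] = res.r0 if res.r0 is not None else np.nan
    else:
        out["r0"] = np.nan
    return out


# ---- persistence ----------------------------------------------------------

def save_run(art: RunArtifact, path) -> None:
    """Persist a run to HDF5: trajectories plus the resolved configuration."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["config_json"] = json.dumps(art.config.to_dict())
        fh.attrs["seed"] = art.seed
        fh.attrs["gamma"] = art.gamma
        import ciliaflow
        fh.attrs["version"] = ciliaflow.__version__
        rec = art.record
        fh.create_dataset("cycles", data=rec.cycles)
        fh.create_dataset("seconds_18hz", data=cycles_to_seconds(rec.cycles, 18.0))
        fh.create_dataset("seconds_36hz", data=cycles_to_seconds(rec.cycles, 36.0))
        fh.create_dataset("positions", data=rec.positions)
        fh.create_dataset("labels", data=rec.labels)
        fh.attrs["label_names"] = json.dumps(list(rec.label_names))


def load_run(path) -> RunArtifact:
    import h5py

    with h5py.File(path, "r") as fh:
        config = ScenarioConfig.from_dict(json.loads(fh.attrs["config_json"]))
        record = TrajectoryRecord(
            cycles=fh["cycles"][:],
            positions=fh["positions"][:],
            labels=fh["labels"][:],
            label_names=tuple(json.loads(fh.attrs["label_names"])),
        )
        return RunArtifact(config=config, seed=int(fh.attrs["seed"]),
                           record=record, gamma=float(fh.attrs["gamma"]))


def trajectory_to_csv(record: TrajectoryRecord, path) -> None:
    """Tidy CSV: one row per (snapshot, tracer)."""
    S, P, _ = record.positions.shape
    snap = np.repeat(np.arange(S), P)
    frame = pd.DataFrame({
        "cycle": np.repeat(record.cycles, P),
        "tracer_id": np.tile(np.arange(P), S),
        "label": np.tile(record.labels, S),
        "x": record.positions[:, :, 0].ravel(),
        "y": record.positions[:, :, 1].ravel(),
        "z": record.positions[:, :, 2].ravel(),
    })
    frame.to_csv(path, index=False)


def geometry_to_csv(config: ScenarioConfig, path, seed: int = 0) -> None:
    """Cluster/rod base table: cluster_id, rod_id, x, y, phase_offset."""
    rods = build_rods(config, seed=seed)
    rows = []
    for i, rod in enumerate(rods):
        rows.append({"cluster_id": i // 9, "rod_id": i,
                     "x": rod.base[0], "y": rod.base[1],
                     "phase_offset": rod.phase_offset})
    pd.DataFrame(rows).to_csv(path, index=False)
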