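"""Simulation orchestrator: configuration, scheduling, scenarios, metrics.

One simulation couples three layers on a shared 3D lattice: tumor-cell
agents, the endothelial vessel network, and the oxygen/VEGF continuum
fields. Every run starts from a single founder tumor cell at the grid
center (plus, optionally, a parent vessel along one grid edge) and advances
in discrete steps with a fixed phase order:

1. perfusion            — vessels deposit oxygen
2. tumor metabolism     — live cells consume oxygen, hypoxic cells secrete VEGF
3. field transport      — diffusion + decay on both fields
4. agent ticks          — tumor cells (ascending id), then endothelial
                          activation, then tip cells (ascending id, move
                          then branch); tips spawned by this step's
                          activation or branching migrate from the next step
5. division             — queued divisions applied ascending parent id
6. observation          — metrics row and stream emission

A single seeded random generator is consumed in exactly this order, so a
(config, seed) pair reproduces a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import tumor as tmod
from . import vessels as vmod
from .fields import FieldParams, ScalarField, diffuse_decay_step, total_mass
from .statechart import ChartDef
from .tumor import TumorCell, TumorParams, tumor_chart
from .vessels import (
    OCC_FREE,
    OCC_NECROTIC,
    OCC_TUMOR,
    OCC_VESSEL,
    AngioParams,
    EndothelialCell,
    VesselNetwork,
    endothelial_chart,
)

__all__ = [
    "SimConfig",
    "SimState",
    "RunResult",
    "ConfigError",
    "InvariantError",
    "init_scenario",
    "step",
    "run",
    "asphericity",
    "kill_object",
    "create_object",
    "query_object",
]

TYPE_TUMOR = "tumor_cell"
TYPE_ENDOTHELIAL = "endothelial_cell"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class InvariantError(RuntimeError):
    """A joint state invariant was violated during a run."""


@dataclass
class SimConfig:
    dims: tuple[int, int, int] = (40, 40, 40)
    spacing: float = 1.0
    n_steps: int = 500
    seed: int = 0
    baseline_o2: float = 4.0
    vessels_enabled: bool = True
    vessel_axis: int = 0
    vessel_offset: tuple[int, int] = (0, 0)
    snapshot_every: int = 10
    record_path: str | None = None
    kill_mode: str = "remove"        # or "necrotic": kill marks instead of removing
    tumor: TumorParams = dc_field(default_factory=TumorParams)
    angio: AngioParams = dc_field(default_factory=AngioParams)
    fields: FieldParams = dc_field(default_factory=FieldParams)

    def validate(self) -> None:
        try:
            if len(self.dims) != 3 or min(self.dims) < 3:
                raise ConfigError(f"dims must be three values >= 3, got {self.dims}")
            if self.spacing <= 0:
                raise ConfigError("spacing must be positive")
            if self.n_steps < 0:
                raise ConfigError("n_steps must be >= 0")
            if self.snapshot_every < 1:
                raise ConfigError("snapshot_every must be >= 1")
            if self.baseline_o2 < 0:
                raise ConfigError("baseline_o2 must be >= 0")
            if self.kill_mode not in ("remove", "necrotic"):
                raise ConfigError(f"unknown kill_mode '{self.kill_mode}'")
            if self.vessel_axis not in (0, 1, 2):
                raise ConfigError("vessel_axis must be 0, 1 or 2")
            self.tumor.validate()
            self.angio.validate()
            self.fields.validate(self.spacing)
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        d["vessel_offset"] = list(self.vessel_offset)
        return d

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "SimConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("tumor", TumorParams), ("angio", AngioParams), ("fields", FieldParams)):
            if key in doc and isinstance(doc[key], Mapping):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                bad = set(doc[key]) - sub_known
                if bad:
                    raise ConfigError(f"unknown keys in '{key}': {sorted(bad)}")
                doc[key] = sub(**doc[key])
        if "dims" in doc:
            doc["dims"] = tuple(int(x) for x in doc["dims"])
        if "vessel_offset" in doc:
            doc["vessel_offset"] = tuple(int(x) for x in doc["vessel_offset"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise ConfigError(f"config file '{path}' is not a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Content hash of the configuration (recording header field)."""
        d = self.to_dict()
        d.pop("record_path", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SimState:
    step: int
    cells: dict[int, TumorCell]
    network: VesselNetwork
    o2: ScalarField
    vegf: ScalarField
    occupancy: np.ndarray
    rng: np.random.Generator
    next_id: int
    founder_voxel: tuple[int, int, int]
    tumor_chart: ChartDef
    endo_chart: ChartDef

    def live_cells(self) -> list[TumorCell]:
        return [c for c in self.cells.values() if c.alive]


@dataclass
class RunResult:
    metrics: pd.DataFrame
    state: SimState
    recording: "Any | None" = None   # protocol.RunRecording when recording was on


def init_scenario(config: SimConfig) -> SimState:
    """Initial state: one founder tumor cell at the grid center, a parent
    vessel along one grid edge iff vessels are enabled, uniform baseline
    oxygen and zero VEGF."""
    config.validate()
    dims = config.dims
    fp = config.fields
    o2 = ScalarField.uniform(dims, config.baseline_o2, spacing=config.spacing,
                             D=fp.D_O2, k_decay=fp.k_decay_O2)
    vegf = ScalarField.uniform(dims, 0.0, spacing=config.spacing,
                               D=fp.D_V, k_decay=fp.k_decay_V)
    occupancy = np.zeros(dims, dtype=np.int8)
    t_chart = tumor_chart()
    e_chart = endothelial_chart()
    founder_voxel = (dims[0] // 2, dims[1] // 2, dims[2] // 2)
    founder = tmod.new_cell(0, founder_voxel, t_chart, parent=None)
    occupancy[founder_voxel] = OCC_TUMOR
    cells = {0: founder}
    next_id = 1
    network = VesselNetwork()
    if config.vessels_enabled:
        network, next_id = vmod.init_parent_vessel(
            dims, config.vessel_axis, config.vessel_offset, e_chart, occupancy,
            id_start=next_id)
    return SimState(step=0, cells=cells, network=network, o2=o2, vegf=vegf,
                    occupancy=occupancy, rng=np.random.default_rng(config.seed),
                    next_id=next_id, founder_voxel=founder_voxel,
                    tumor_chart=t_chart, endo_chart=e_chart)


def step(state: SimState, config: SimConfig) -> SimState:
    """Advance the coupled system by one step (fixed phase order, in place)."""
    dt = config.fields.dt

    # (1) perfusion
    vmod.perfuse(state.network, state.o2, config.angio, dt)

    # (2) tumor metabolism
    tmod.apply_metabolism(state.cells, state.o2, state.vegf, config.tumor, dt)

    # (3) transport (per-species sub-stepping; see FieldParams)
    for _ in range(config.fields.substeps_O2):
        diffuse_decay_step(state.o2, dt / config.fields.substeps_O2)
    for _ in range(config.fields.substeps_V):
        diffuse_decay_step(state.vegf, dt / config.fields.substeps_V)

    # (4) agent ticks (readings gathered in one vectorized pass)
    divide_queue: list[int] = []
    nfree = tmod.free_neighbor_counts(state.occupancy)
    o2v = state.o2.values
    for cid in sorted(state.cells):
        cell = state.cells[cid]
        if not cell.alive:
            continue
        readings = (float(o2v[cell.voxel]), int(nfree[cell.voxel]))
        _, intents = tmod.tick_tumor_fast(cell, readings, config.tumor)
        if not cell.alive:
            state.occupancy[cell.voxel] = OCC_NECROTIC
        for kind, who in intents:
            if kind == "divide":
                divide_queue.append(who)
    if config.vessels_enabled and state.network.cells:
        pre_activation_id = state.next_id
        state.next_id = vmod.activate(state.network, state.vegf, config.angio,
                                      state.occupancy, state.next_id)
        # tips spawned by this step's activation or branching start next step
        for tip_id in [t for t in state.network.tips() if t < pre_activation_id]:
            state.next_id = vmod.tip_step(state.network, tip_id, state.vegf,
                                          config.angio, state.rng,
                                          state.occupancy, state.next_id)
            state.next_id = vmod.branch_step(state.network, tip_id, state.vegf,
                                             config.angio, state.rng,
                                             state.occupancy, state.next_id,
                                             state.step + 1)

    # (5) queued divisions, ascending parent id
    for pid in sorted(divide_queue):
        parent = state.cells[pid]
        if not parent.alive:
            continue
        daughter = tmod.apply_divide(parent, state.occupancy, state.rng,
                                     state.next_id, state.tumor_chart)
        if daughter is not None:
            state.cells[daughter.id] = daughter
            state.next_id += 1

    state.step += 1
    _check_cheap_invariants(state)
    return state


def _check_cheap_invariants(state: SimState) -> None:
    occ = state.occupancy
    n_occ = int(np.count_nonzero(occ))
    n_agents = len(state.cells) + len(state.network.cells)
    if n_occ != n_agents:
        raise InvariantError(
            f"step {state.step}: occupancy count {n_occ} != agent count {n_agents} "
            f"(tumor {len(state.cells)}, endothelial {len(state.network.cells)})")


def check_state(state: SimState) -> list[str]:
    """Full joint-invariant check (used by tests; step() runs a cheap subset)."""
    out: list[str] = []
    seen: dict[tuple[int, int, int], str] = {}
    for cid in sorted(state.cells):
        c = state.cells[cid]
        key = c.voxel
        if key in seen:
            out.append(f"voxel {key} holds both {seen[key]} and tumor {cid}")
        seen[key] = f"tumor {cid}"
        expected = OCC_TUMOR if c.alive else OCC_NECROTIC
        if state.occupancy[key] != expected:
            out.append(f"tumor {cid}: occupancy code {state.occupancy[key]} != {expected}")
        # lineage terminates at the founder
        cur, hops = c, 0
        while cur.parent is not None:
            if cur.parent not in state.cells:
                out.append(f"tumor {cid}: missing ancestor {cur.parent}")
                break
            cur = state.cells[cur.parent]
            hops += 1
            if hops > len(state.cells):
                out.append(f"tumor {cid}: lineage cycle")
                break
    for cid in sorted(state.network.cells):
        c = state.network.cells[cid]
        if c.voxel in seen:
            out.append(f"voxel {c.voxel} holds both {seen[c.voxel]} and endothelial {cid}")
        seen[c.voxel] = f"endothelial {cid}"
        if state.occupancy[c.voxel] != OCC_VESSEL:
            out.append(f"endothelial {cid}: occupancy code is not vessel")
    out.extend(vmod.check_network(state.network))
    return out


# ---------------------------------------------------------------------------
# observation

def asphericity(positions: Iterable) -> float:
    """Shape anisotropy of a point cloud from the gyration tensor.

    With eigenvalues l1 >= l2 >= l3 of the gyration tensor,
    A = (l1 - (l2 + l3)/2) / (l1 + l2 + l3): 0 for an isotropic cloud,
    1/4 for a flat disc, 1 for a line. Fewer than two distinct points leave
    the tensor degenerate and raise ValueError.
    """
    pts = np.asarray(list(positions), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("asphericity needs >= 2 points in 3D")
    centered = pts - pts.mean(axis=0)
    gyr = centered.T @ centered / pts.shape[0]
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    tot = float(lam.sum())
    if tot <= 0.0:
        raise ValueError("asphericity undefined for coincident points")
    return float((lam[0] - 0.5 * (lam[1] + lam[2])) / tot)


def _radial_stats(state: SimState) -> tuple[float, float, float]:
    """(max live radius, mean live radius, mean necrotic radius) from the founder."""
    f = np.array(state.founder_voxel, dtype=float)
    live = [c.voxel for c in state.cells.values() if c.alive]
    nec = [c.voxel for c in state.cells.values() if not c.alive]
    r_live = np.linalg.norm(np.asarray(live, dtype=float) - f, axis=1) if live else np.array([])
    r_nec = np.linalg.norm(np.asarray(nec, dtype=float) - f, axis=1) if nec else np.array([])
    radius = float(r_live.max()) if live else 0.0
    return (radius,
            float(r_live.mean()) if live else float("nan"),
            float(r_nec.mean()) if nec else float("nan"))


def mean_dist_to_vessel(state: SimState) -> float:
    """Mean distance from live tumor cells to their nearest vessel voxel."""
    live = [c.voxel for c in state.cells.values() if c.alive]
    vessels = [e.voxel for e in state.network.cells.values()]
    if not live or not vessels:
        return float("nan")
    tree = cKDTree(np.asarray(vessels, dtype=float))
    d, _ = tree.query(np.asarray(live, dtype=float))
    return float(np.mean(d))


METRICS_COLUMNS = [
    "step", "proliferating", "quiescent", "hypoxic", "necrotic", "live",
    "endothelial", "sprouts", "branch_events", "radius", "asphericity",
    "mean_r_live", "mean_r_necrotic", "mean_dist_to_vessel",
    "total_o2", "total_vegf",
]


def metrics_row(state: SimState) -> dict[str, float]:
    counts = {tmod.S_PROLIFERATING: 0, tmod.S_QUIESCENT: 0,
              tmod.S_HYPOXIC: 0, tmod.S_NECROTIC: 0}
    for c in state.cells.values():
        counts[c.state] += 1
    live_pos = [c.voxel for c in state.cells.values() if c.alive]
    try:
        asph = asphericity(live_pos)
    except ValueError:
        asph = float("nan")
    radius, mean_r_live, mean_r_nec = _radial_stats(state)
    return {
        "step": state.step,
        "proliferating": counts[tmod.S_PROLIFERATING],
        "quiescent": counts[tmod.S_QUIESCENT],
        "hypoxic": counts[tmod.S_HYPOXIC],
        "necrotic": counts[tmod.S_NECROTIC],
        "live": counts[tmod.S_PROLIFERATING] + counts[tmod.S_QUIESCENT] + counts[tmod.S_HYPOXIC],
        "endothelial": len(state.network.cells),
        "sprouts": state.network.n_sprouts,
        "branch_events": len(state.network.branch_events),
        "radius": radius,
        "asphericity": asph,
        "mean_r_live": mean_r_live,
        "mean_r_necrotic": mean_r_nec,
        "mean_dist_to_vessel": mean_dist_to_vessel(state),
        "total_o2": total_mass(state.o2),
        "total_vegf": total_mass(state.vegf),
    }


def run(config: SimConfig, commands: "Mapping[int, list] | None" = None) -> RunResult:
    """Run a configured simulation to completion.

    Returns the metrics table (one row at step 0, every ``snapshot_every``
    steps, and at the final step), the final state, and — when
    ``config.record_path`` is set — the recorded message stream, also written
    to that path. ``commands`` optionally maps a step index to decoded
    inbound commands applied before that step executes.
    """
    from . import protocol  # local import: protocol depends on sim types

    config.validate()
    state = init_scenario(config)
    recorder = None
    if config.record_path is not None:
        recorder = protocol.StreamRecorder(config)
        recorder.emit_step(state)
    rows = [metrics_row(state)]
    for s in range(config.n_steps):
        if commands and s in commands:
            for cmd in commands[s]:
                protocol.apply_command(state, config, cmd)
        step(state, config)
        if recorder is not None:
            recorder.emit_step(state)
        if state.step % config.snapshot_every == 0 or state.step == config.n_steps:
            rows.append(metrics_row(state))
    # drop a duplicated final row when n_steps lands on a snapshot boundary
    metrics = pd.DataFrame(rows, columns=METRICS_COLUMNS).drop_duplicates("step")
    metrics = metrics.reset_index(drop=True)
    recording = None
    if recorder is not None:
        recording = recorder.finish()
        recording.save(config.record_path)
    return RunResult(metrics=metrics, state=state, recording=recording)


# ---------------------------------------------------------------------------
# interactive object commands (create / kill / query)

class CommandRejected(ValueError):
    """An inbound command could not be applied; the state is unchanged."""


def kill_object(state: SimState, config: SimConfig, obj_id: int | None = None,
                obj_type: str | None = None) -> int:
    """Kill one object, by id or at random over a type; returns the victim id.

    Tumor cells are removed or marked necrotic according to
    ``config.kill_mode``; for endothelial cells only tips can be killed
    (stalk removal would sever the vessel forest). Random draws consume the
    simulation rng, so they are reproducible.
    """
    if obj_id is None:
        if obj_type == TYPE_TUMOR:
            pool = sorted(cid for cid, c in state.cells.items() if c.alive)
        elif obj_type == TYPE_ENDOTHELIAL:
            pool = state.network.tips()
        else:
            raise CommandRejected(f"cannot kill at random over type '{obj_type}'")
        if not pool:
            raise CommandRejected(f"no killable object of type '{obj_type}'")
        obj_id = pool[int(state.rng.integers(len(pool)))]
    if obj_id in state.cells:
        cell = state.cells[obj_id]
        if config.kill_mode == "necrotic" and cell.alive:
            ctx = {"o2": 0.0, "free": 0, "hypoxia_count": config.tumor.n_nec,
                   "T_div": config.tumor.T_div, "T_hyp": config.tumor.T_hyp,
                   "n_nec": config.tumor.n_nec}
            from .statechart import dispatch
            # two ticks: the first drops the cell into Hypoxic (inner-first
            # priority), the second fires the outer necrosis transition
            cell.chart, _ = dispatch(cell.chart, "tick", ctx)
            cell.chart, _ = dispatch(cell.chart, "tick", ctx)
            state.occupancy[cell.voxel] = OCC_NECROTIC
        else:
            state.occupancy[cell.voxel] = OCC_FREE
            del state.cells[obj_id]
        return obj_id
    if obj_id in state.network.cells:
        cell = state.network.cells[obj_id]
        if cell.role != vmod.ROLE_TIP:
            raise CommandRejected(f"endothelial cell {obj_id} is not a tip")
        state.occupancy[cell.voxel] = OCC_FREE
        del state.network.cells[obj_id]
        return obj_id
    raise CommandRejected(f"unknown object id {obj_id}")


def create_object(state: SimState, config: SimConfig, obj_type: str, voxel) -> int:
    """Insert a new agent at a free voxel in its chart's initial configuration."""
    voxel = tuple(int(x) for x in voxel)
    dims = state.occupancy.shape
    if not all(0 <= voxel[a] < dims[a] for a in range(3)):
        raise CommandRejected(f"voxel {voxel} outside grid {dims}")
    if state.occupancy[voxel] != OCC_FREE:
        raise CommandRejected(f"voxel {voxel} is occupied")
    if obj_type == TYPE_TUMOR:
        cell = tmod.new_cell(state.next_id, voxel, state.tumor_chart, parent=None)
        state.cells[cell.id] = cell
        state.occupancy[voxel] = OCC_TUMOR
    elif obj_type == TYPE_ENDOTHELIAL:
        from .statechart import enter_initial
        ec = EndothelialCell(id=state.next_id, voxel=voxel, role=vmod.ROLE_TIP,
                             chart=enter_initial(state.endo_chart), pred=None,
                             sprout_id=state.network.n_sprouts)
        # a free-standing endothelial cell starts its own root chain
        state.network.cells[ec.id] = ec
        state.network.root_cells.append(ec.id)
        state.network.n_sprouts += 1
        state.occupancy[voxel] = OCC_VESSEL
    else:
        raise CommandRejected(f"unknown object type '{obj_type}'")
    state.next_id += 1
    return state.next_id - 1


def query_object(state: SimState, obj_id: int) -> dict[str, Any]:
    """Read-only info record for one object (the click-and-select surface)."""
    if obj_id in state.cells:
        c = state.cells[obj_id]
        kind, statetag, parent = TYPE_TUMOR, c.state, c.parent
        voxel = c.voxel
    elif obj_id in state.network.cells:
        e = state.network.cells[obj_id]
        kind, statetag, parent = TYPE_ENDOTHELIAL, e.state, e.pred
        voxel = e.voxel
    else:
        raise CommandRejected(f"unknown object id {obj_id}")
    return {
        "id": obj_id, "type": kind, "position": voxel, "state": statetag,
        "parent": parent,
        "local_o2": float(state.o2.values[voxel]),
        "local_vegf": float(state.vegf.values[voxel]),
    }


def scene_snapshot(state: SimState) -> dict[int, tuple[str, tuple[int, int, int], str, int | None]]:
    """id -> (type, voxel, state tag, pred/parent) for stream diffing."""
    out: dict[int, tuple[str, tuple[int, int, int], str, int | None]] = {}
    for cid, c in state.cells.items():
        out[cid] = (TYPE_TUMOR, c.voxel, c.state, None)
    for cid, e in state.network.cells.items():
        out[cid] = (TYPE_ENDOTHELIAL, e.voxel, e.state, e.pred)
    return out
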