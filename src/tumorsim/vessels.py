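"""Endothelial-cell agents and the vessel network.

Angiogenesis is modeled as sprouting from a pre-existing parent vessel: a
straight chain of quiescent endothelial cells laid along one grid edge.
When tumor-secreted VEGF at a parent-vessel cell reaches the activation
threshold ``T_V``, that cell spawns a migrating *tip* cell; the tip performs
a biased random walk up the VEGF gradient (exploration probability ``eps``),
leaving a *stalk* cell behind at each move so the sprout elongates as a
chain of individual endothelial cells. Tips may branch with probability
proportional to local VEGF, which concentrates branch points where VEGF is
high — i.e. near the tumor. Every endothelial cell releases oxygen at its
voxel (perfusion); there is no anastomosis and no vessel regression.

The vessel graph is a forest over predecessor links rooted in the parent
vessel; tube rendering connects each cell to its predecessor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ScalarField
from .statechart import ChartDef, ChartInstance, build_chart, dispatch, enter_initial
from .tumor import NEIGHBOR_OFFSETS

__all__ = [
    "AngioParams",
    "EndothelialCell",
    "VesselNetwork",
    "endothelial_chart",
    "init_parent_vessel",
    "activate",
    "tip_step",
    "branch_step",
    "perfuse",
]

ROLE_STALK = "stalk"
ROLE_TIP = "tip"

E_INACTIVE = "Inactive"
E_ACTIVATED = "Activated"
E_MIGRATING = "Migrating"
E_ELONGATING = "Elongating"

# occupancy codes shared across the simulation lattice
OCC_FREE = 0
OCC_TUMOR = 1
OCC_NECROTIC = 2
OCC_VESSEL = 3


@dataclass
class AngioParams:
    """Endothelial parameters (relative units).

    T_V        VEGF threshold activating a parent-vessel cell
    p_move     per-step tip migration probability
    eps        exploration probability (random step instead of up-gradient)
    beta       branching coefficient: per-step tip branch probability
               p = min(1, beta * local VEGF)
    s_O2       oxygen delivered per endothelial cell per step (perfusion)
    allow_branching  scenario switch: False restricts sprouts to elongation
    """

    T_V: float = 0.002
    p_move: float = 0.8
    eps: float = 0.1
    beta: float = 0.05
    s_O2: float = 0.2
    allow_branching: bool = True

    def validate(self) -> None:
        for name in ("p_move", "eps"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.T_V < 0 or self.beta < 0 or self.s_O2 < 0:
            raise ValueError("T_V, beta and s_O2 must be >= 0")


_ENDO_CHART_DOC = {
    "states": {
        "id": "root", "kind": "compound", "initial": E_INACTIVE,
        "children": [E_INACTIVE, E_ACTIVATED, E_MIGRATING, E_ELONGATING],
    },
    "transitions": [
        {"id": "e01", "source": E_INACTIVE, "target": E_ACTIVATED,
         "trigger": "activate", "guard": "vegf_above"},
        {"id": "e02", "source": E_INACTIVE, "target": E_MIGRATING, "trigger": "become_tip"},
        {"id": "e03", "source": E_INACTIVE, "target": E_ELONGATING, "trigger": "become_stalk"},
        {"id": "e04", "source": E_MIGRATING, "target": E_ELONGATING, "trigger": "become_stalk"},
    ],
}

_ENDO_GUARDS = {"vegf_above": lambda c: c["vegf"] >= c["T_V"]}


def endothelial_chart() -> ChartDef:
    """Default endothelial statechart (reconstruction; the published chart is
    only shown as a figure)."""
    return build_chart(_ENDO_CHART_DOC, guards=_ENDO_GUARDS)


@dataclass
class EndothelialCell:
    id: int
    voxel: tuple[int, int, int]
    role: str                       # stalk | tip
    chart: ChartInstance
    pred: int | None = None         # predecessor along the vessel (None = root cell)
    sprout_id: int = -1             # -1 marks the parent vessel itself

    @property
    def state(self) -> str:
        for s in (E_INACTIVE, E_ACTIVATED, E_MIGRATING, E_ELONGATING):
            if s in self.chart.configuration:
                return s
        raise RuntimeError(f"endothelial cell {self.id}: no leaf state active")


@dataclass
class VesselNetwork:
    cells: dict[int, EndothelialCell] = field(default_factory=dict)
    root_cells: list[int] = field(default_factory=list)
    branch_events: list[tuple[int, tuple[int, int, int], float]] = field(default_factory=list)
    n_sprouts: int = 0
    n_activations: int = 0

    def sprout_cells(self) -> list[EndothelialCell]:
        return [c for c in self.cells.values() if c.sprout_id >= 0]

    def tips(self) -> list[int]:
        return sorted(cid for cid, c in self.cells.items() if c.role == ROLE_TIP)


def init_parent_vessel(dims, axis: int, offset: tuple[int, int],
                       chart_def: ChartDef, occupancy: np.ndarray,
                       id_start: int = 0,
                       network: VesselNetwork | None = None) -> tuple[VesselNetwork, int]:
    """Lay a straight parent vessel spanning the grid along one axis.

    ``offset`` fixes the two transverse coordinates. Cells are stalk role,
    pred-linked in order along the line. Returns the network and the next
    free id. A second call with the same network adds a disjoint parent
    vessel (a second root chain).
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    other = [a for a in range(3) if a != axis]
    for a, off in zip(other, offset):
        if not (0 <= off < dims[a]):
            raise ValueError(f"vessel offset {offset} outside grid {tuple(dims)}")
    net = network if network is not None else VesselNetwork()
    prev: int | None = None
    cid = id_start
    for pos in range(dims[axis]):
        voxel = [0, 0, 0]
        voxel[axis] = pos
        voxel[other[0]] = offset[0]
        voxel[other[1]] = offset[1]
        v = (voxel[0], voxel[1], voxel[2])
        cell = EndothelialCell(id=cid, voxel=v, role=ROLE_STALK,
                               chart=enter_initial(chart_def), pred=prev, sprout_id=-1)
        net.cells[cid] = cell
        net.root_cells.append(cid)
        occupancy[v] = OCC_VESSEL
        prev = cid
        cid += 1
    return net, cid


def _free_neighbors(voxel, occupancy: np.ndarray) -> list[tuple[int, int, int]]:
    nx, ny, nz = occupancy.shape
    i, j, k = voxel
    out = []
    for di, dj, dk in NEIGHBOR_OFFSETS:
        a, b, c = i + di, j + dj, k + dk
        if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and occupancy[a, b, c] == OCC_FREE:
            out.append((a, b, c))
    return out


def _argmax_vegf(candidates, vegf: ScalarField) -> tuple[int, int, int]:
    """Highest-VEGF candidate; ties resolve to the lowest voxel index
    (candidates arrive in lexicographic order and strict > keeps the first)."""
    best = candidates[0]
    best_v = vegf.values[best]
    for c in candidates[1:]:
        v = vegf.values[c]
        if v > best_v:
            best, best_v = c, v
    return best


def activate(net: VesselNetwork, vegf: ScalarField, params: AngioParams,
             occupancy: np.ndarray, next_id: int) -> int:
    """Threshold activation of parent-vessel cells, ascending id.

    An inactive root cell whose local VEGF >= T_V transitions to Activated
    and spawns one tip in its free face-neighbor voxel of maximal VEGF
    (no free neighbor: the activation happens but no tip is spawned).
    Each activation starts a new sprout. Returns the next free id.
    """
    for cid in list(net.root_cells):
        cell = net.cells[cid]
        if E_INACTIVE not in cell.chart.configuration:
            continue
        local = float(vegf.values[cell.voxel])
        if local < params.T_V:
            continue
        inst, _ = dispatch(cell.chart, "activate", {"vegf": local, "T_V": params.T_V})
        cell.chart = inst
        net.n_activations += 1
        free = _free_neighbors(cell.voxel, occupancy)
        if not free:
            continue
        spawn = _argmax_vegf(free, vegf)
        chart_def = cell.chart.chart
        tip_inst, _ = dispatch(enter_initial(chart_def), "become_tip", {})
        tip = EndothelialCell(id=next_id, voxel=spawn, role=ROLE_TIP,
                              chart=tip_inst, pred=cid, sprout_id=net.n_sprouts)
        net.n_sprouts += 1
        net.cells[next_id] = tip
        occupancy[spawn] = OCC_VESSEL
        next_id += 1
    return next_id


def tip_step(net: VesselNetwork, tip_id: int, vegf: ScalarField, params: AngioParams,
             rng: np.random.Generator, occupancy: np.ndarray, next_id: int) -> int:
    """One migration attempt for one tip; returns the next free id.

    With probability p_move the tip moves — up the VEGF gradient (argmax over
    free face-neighbors) with probability 1-eps, to a uniformly random free
    neighbor otherwise — and a new stalk cell fills the vacated voxel,
    pred-linked behind the tip (elongation). A boxed-in tip stalls.
    """
    cell = net.cells[tip_id]
    if cell.role != ROLE_TIP:
        raise ValueError(f"cell {tip_id} is not a tip")
    if rng.random() >= params.p_move:
        return next_id
    free = _free_neighbors(cell.voxel, occupancy)
    if not free:
        return next_id
    if params.eps > 0.0 and rng.random() < params.eps:
        dest = free[int(rng.integers(len(free)))]
    else:
        dest = _argmax_vegf(free, vegf)
    old_voxel = cell.voxel
    chart_def = cell.chart.chart
    stalk_inst, _ = dispatch(enter_initial(chart_def), "become_stalk", {})
    stalk = EndothelialCell(id=next_id, voxel=old_voxel, role=ROLE_STALK,
                            chart=stalk_inst, pred=cell.pred, sprout_id=cell.sprout_id)
    net.cells[next_id] = stalk
    cell.pred = next_id
    cell.voxel = dest
    occupancy[dest] = OCC_VESSEL  # old voxel stays OCC_VESSEL (stalk fills it)
    return next_id + 1


def branch_step(net: VesselNetwork, tip_id: int, vegf: ScalarField, params: AngioParams,
                rng: np.random.Generator, occupancy: np.ndarray, next_id: int,
                step: int) -> int:
    """One branching attempt for one tip; returns the next free id.

    No-op unless branching is allowed. With probability min(1, beta * local
    VEGF) the tip spawns a second tip in a free face-neighbor distinct from
    the tip's presumptive next move (the up-gradient argmax), chosen
    uniformly; the event (step, voxel, local VEGF) is recorded. The new tip
    starts a new sprout and is pred-linked to the stalk behind the branching
    tip, keeping tips successor-free.
    """
    if not params.allow_branching:
        return next_id
    cell = net.cells[tip_id]
    if cell.role != ROLE_TIP:
        raise ValueError(f"cell {tip_id} is not a tip")
    local = float(vegf.values[cell.voxel])
    p = min(1.0, params.beta * local)
    if p <= 0.0 or rng.random() >= p:
        return next_id
    free = _free_neighbors(cell.voxel, occupancy)
    if not free:
        return next_id
    heading = _argmax_vegf(free, vegf)
    candidates = [v for v in free if v != heading]
    if not candidates:
        return next_id
    spawn = candidates[int(rng.integers(len(candidates)))]
    chart_def = cell.chart.chart
    tip_inst, _ = dispatch(enter_initial(chart_def), "become_tip", {})
    branch = EndothelialCell(id=next_id, voxel=spawn, role=ROLE_TIP,
                             chart=tip_inst, pred=cell.pred, sprout_id=net.n_sprouts)
    net.n_sprouts += 1
    net.cells[next_id] = branch
    occupancy[spawn] = OCC_VESSEL
    net.branch_events.append((step, cell.voxel, local))
    return next_id + 1


def perfuse(net: VesselNetwork, o2: ScalarField, params: AngioParams, dt: float) -> None:
    """Oxygen delivery: every endothelial cell deposits s_O2*dt.

    Endothelial voxels are pairwise distinct, so the deposits are applied as
    one vectorized scatter (equivalent to per-cell deposits in any order).
    """
    if params.s_O2 <= 0.0 or not net.cells:
        return
    voxels = np.asarray([net.cells[cid].voxel for cid in sorted(net.cells)], dtype=np.intp)
    o2.values[tuple(voxels.T)] += params.s_O2 * dt


def check_network(net: VesselNetwork) -> list[str]:
    """Structural violations of the vessel forest (empty when consistent)."""
    out: list[str] = []
    seen_voxels: dict[tuple[int, int, int], int] = {}
    for cid in sorted(net.cells):
        c = net.cells[cid]
        if c.voxel in seen_voxels:
            out.append(f"cells {seen_voxels[c.voxel]} and {cid} share voxel {c.voxel}")
        seen_voxels[c.voxel] = cid
        # pred chain must terminate at a root cell
        cur, hops = c, 0
        while cur.pred is not None:
            if cur.pred not in net.cells:
                out.append(f"cell {cid}: dangling pred {cur.pred}")
                break
            cur = net.cells[cur.pred]
            hops += 1
            if hops > len(net.cells):
                out.append(f"cell {cid}: pred cycle")
                break
        else:
            if cur.id not in net.root_cells:
                out.append(f"cell {cid}: pred chain ends off the parent vessel")
    succ: set[int] = {c.pred for c in net.cells.values() if c.pred is not None}
    for cid in net.tips():
        if cid in succ:
            out.append(f"tip {cid} has a successor")
    return out
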