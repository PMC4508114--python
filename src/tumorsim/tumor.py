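"""Tumor-cell agents.

Each tumor cell occupies one lattice voxel and is driven by a small
hierarchical statechart: an ``Alive`` super-state with ``Proliferating``,
``Quiescent`` and ``Hypoxic`` sub-states, and an absorbing ``Necrotic``
state. Two oxygen thresholds structure the colony the way avascular tumors
layer in vitro: above ``T_div`` a cell with a free face-neighbor cycles
toward division; between ``T_hyp`` and ``T_div`` (or when crowded) it idles;
below ``T_hyp`` it is hypoxic, secretes VEGF, and after ``n_nec`` consecutive
hypoxic steps dies irreversibly. Hypoxia is reversible before that point, so
a tumor reached by new vasculature in time can recover.

The default chart is a reconstruction: the published model shows its charts
only as figures, so the topology here is the minimal one producing the
documented layering (proliferating rim, quiescent band, necrotic core).
Tumor cells do not migrate; growth is purely by division into free
face-neighbor voxels (contact inhibition on a one-cell-per-voxel lattice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ScalarField
from .statechart import ChartDef, ChartInstance, build_chart, dispatch, enter_initial

__all__ = [
    "TumorParams",
    "TumorCell",
    "tumor_chart",
    "sense",
    "tick_tumor",
    "apply_divide",
    "apply_metabolism",
    "S_PROLIFERATING",
    "S_QUIESCENT",
    "S_HYPOXIC",
    "S_NECROTIC",
    "S_ALIVE",
]

S_ALIVE = "Alive"
S_PROLIFERATING = "Proliferating"
S_QUIESCENT = "Quiescent"
S_HYPOXIC = "Hypoxic"
S_NECROTIC = "Necrotic"

# face-neighbor offsets in fixed lexicographic order (determinism)
NEIGHBOR_OFFSETS = ((-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0))


@dataclass
class TumorParams:
    """Tumor-cell parameters (relative units; see docs/methods.md).

    T_div    oxygen threshold for proliferation
    T_hyp    oxygen threshold below which the cell is hypoxic (< T_div)
    n_cyc    cell-cycle length in simulation steps
    n_nec    consecutive hypoxic steps before irreversible necrosis
    k_O2     oxygen consumed per live cell per step
    s_V      VEGF secreted per hypoxic cell per step
    """

    T_div: float = 0.30
    T_hyp: float = 0.15
    n_cyc: int = 6
    n_nec: int = 100
    k_O2: float = 0.05
    s_V: float = 1.0

    def validate(self) -> None:
        if not (0 <= self.T_hyp < self.T_div):
            raise ValueError(f"need 0 <= T_hyp < T_div, got T_hyp={self.T_hyp}, T_div={self.T_div}")
        if self.n_cyc < 1 or self.n_nec < 1:
            raise ValueError("n_cyc and n_nec must be >= 1")
        if self.k_O2 < 0 or self.s_V < 0:
            raise ValueError("k_O2 and s_V must be >= 0")


_TUMOR_CHART_DOC = {
    "states": {
        "id": "root", "kind": "compound", "initial": S_ALIVE,
        "children": [
            {"id": S_ALIVE, "kind": "compound", "initial": S_PROLIFERATING,
             "children": [S_PROLIFERATING, S_QUIESCENT, S_HYPOXIC]},
            {"id": S_NECROTIC},
        ],
    },
    "transitions": [
        {"id": "t01", "source": S_PROLIFERATING, "target": S_QUIESCENT,
         "trigger": "tick", "guard": "quiescent_cond"},
        {"id": "t02", "source": S_PROLIFERATING, "target": S_HYPOXIC,
         "trigger": "tick", "guard": "hypoxic_cond"},
        {"id": "t03", "source": S_QUIESCENT, "target": S_PROLIFERATING,
         "trigger": "tick", "guard": "can_proliferate"},
        {"id": "t04", "source": S_QUIESCENT, "target": S_HYPOXIC,
         "trigger": "tick", "guard": "hypoxic_cond"},
        {"id": "t05", "source": S_HYPOXIC, "target": S_PROLIFERATING,
         "trigger": "tick", "guard": "can_proliferate"},
        {"id": "t06", "source": S_HYPOXIC, "target": S_QUIESCENT,
         "trigger": "tick", "guard": "quiescent_cond"},
        # outer transition: inner-first priority cannot pre-empt it because no
        # inner transition is enabled while the cell is below T_hyp
        {"id": "t10", "source": S_ALIVE, "target": S_NECROTIC,
         "trigger": "tick", "guard": "necrosis_due"},
    ],
}

_TUMOR_GUARDS = {
    "can_proliferate": lambda c: c["o2"] >= c["T_div"] and c["free"] > 0,
    "quiescent_cond": lambda c: (c["T_hyp"] <= c["o2"] < c["T_div"])
    or (c["o2"] >= c["T_div"] and c["free"] == 0),
    "hypoxic_cond": lambda c: c["o2"] < c["T_hyp"],
    "necrosis_due": lambda c: c["hypoxia_count"] >= c["n_nec"],
}


def tumor_chart() -> ChartDef:
    """Default tumor statechart (reconstruction, see module docstring)."""
    return build_chart(_TUMOR_CHART_DOC, guards=_TUMOR_GUARDS)


@dataclass
class TumorCell:
    id: int
    voxel: tuple[int, int, int]
    chart: ChartInstance
    cycle_count: int = 0     # steps since last division
    hypoxia_count: int = 0   # consecutive hypoxic steps
    parent: int | None = None

    @property
    def state(self) -> str:
        for s in (S_PROLIFERATING, S_QUIESCENT, S_HYPOXIC, S_NECROTIC):
            if s in self.chart.configuration:
                return s
        raise RuntimeError(f"cell {self.id}: no leaf state active")

    @property
    def alive(self) -> bool:
        return S_NECROTIC not in self.chart.configuration


def new_cell(cell_id: int, voxel, chart_def: ChartDef, parent: int | None = None) -> TumorCell:
    return TumorCell(id=cell_id, voxel=tuple(int(x) for x in voxel),
                     chart=enter_initial(chart_def), parent=parent)


def free_neighbors(voxel, occupancy: np.ndarray) -> list[tuple[int, int, int]]:
    """Unoccupied in-grid face-neighbor voxels, in fixed lexicographic order."""
    nx, ny, nz = occupancy.shape
    i, j, k = voxel
    out = []
    for di, dj, dk in NEIGHBOR_OFFSETS:
        a, b, c = i + di, j + dj, k + dk
        if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and occupancy[a, b, c] == 0:
            out.append((a, b, c))
    return out


def sense(cell: TumorCell, o2: ScalarField, occupancy: np.ndarray) -> tuple[float, int]:
    """Local readings: oxygen at the cell's voxel, count of free face-neighbors."""
    i, j, k = cell.voxel
    return float(o2.values[i, j, k]), len(free_neighbors(cell.voxel, occupancy))


def tick_tumor(cell: TumorCell, readings: tuple[float, int],
               params: TumorParams) -> tuple[TumorCell, list[tuple[str, int]]]:
    """Advance one cell by one step; returns the cell and emitted intents.

    Intents are ``("divide", cell_id)`` tuples; VEGF secretion and oxygen
    consumption are handled by the metabolism phase from the cell's state.
    Necrosis is absorbing: a necrotic cell's tick is a no-op.
    """
    if not cell.alive:
        return cell, []
    o2, free = readings
    hyp = cell.hypoxia_count + 1 if o2 < params.T_hyp else 0
    ctx = {"o2": o2, "free": free, "hypoxia_count": hyp,
           "T_div": params.T_div, "T_hyp": params.T_hyp, "n_nec": params.n_nec}
    inst, _actions = dispatch(cell.chart, "tick", ctx)
    cell.chart = inst
    cell.hypoxia_count = 0 if S_NECROTIC in inst.configuration else hyp

    intents: list[tuple[str, int]] = []
    if S_PROLIFERATING in inst.configuration:
        cell.cycle_count += 1
        if cell.cycle_count >= params.n_cyc:
            intents.append(("divide", cell.id))
            cell.cycle_count = 0
    return cell, intents


def tick_tumor_fast(cell: TumorCell, readings: tuple[float, int],
                    params: TumorParams) -> tuple[TumorCell, list[tuple[str, int]]]:
    """Semantically identical to :func:`tick_tumor`, skipping dispatch when
    no transition can fire.

    The tumor chart's tick transitions are guarded exactly by the oxygen /
    crowding / counter conditions evaluated here, so when the implied target
    sub-state equals the current one and necrosis is not due, dispatch would
    be a no-op and only the counters advance. Any other case falls back to
    the full statechart path.
    """
    if not cell.alive:
        return cell, []
    o2, free = readings
    hypoxic = o2 < params.T_hyp
    hyp = cell.hypoxia_count + 1 if hypoxic else 0
    if hypoxic:
        target = S_HYPOXIC
    elif o2 >= params.T_div and free > 0:
        target = S_PROLIFERATING
    else:
        target = S_QUIESCENT
    if target not in cell.chart.configuration or (hypoxic and hyp >= params.n_nec):
        return tick_tumor(cell, readings, params)
    cell.hypoxia_count = hyp
    intents: list[tuple[str, int]] = []
    if target == S_PROLIFERATING:
        cell.cycle_count += 1
        if cell.cycle_count >= params.n_cyc:
            intents.append(("divide", cell.id))
            cell.cycle_count = 0
    return cell, intents


def free_neighbor_counts(occupancy: np.ndarray) -> np.ndarray:
    """Per-voxel count of free in-grid face-neighbors (vectorized sense)."""
    f = np.pad(occupancy == 0, 1, constant_values=False)
    return (f[:-2, 1:-1, 1:-1].astype(np.int8) + f[2:, 1:-1, 1:-1]
            + f[1:-1, :-2, 1:-1] + f[1:-1, 2:, 1:-1]
            + f[1:-1, 1:-1, :-2] + f[1:-1, 1:-1, 2:])


def apply_divide(cell: TumorCell, occupancy: np.ndarray, rng: np.random.Generator,
                 daughter_id: int, chart_def: ChartDef) -> TumorCell | None:
    """Place a daughter in a uniformly chosen free face-neighbor voxel.

    Returns None (division dropped) if no free neighbor remains when the
    queued division is applied.
    """
    free = free_neighbors(cell.voxel, occupancy)
    if not free:
        return None
    choice = free[int(rng.integers(len(free)))]
    daughter = new_cell(daughter_id, choice, chart_def, parent=cell.id)
    occupancy[choice] = 1
    return daughter


def apply_metabolism(cells: dict[int, TumorCell], o2: ScalarField, vegf: ScalarField,
                     params: TumorParams, dt: float) -> None:
    """Per-cell oxygen consumption and hypoxic VEGF secretion, ascending id.

    Live (non-necrotic) cells consume k_O2*dt oxygen at their voxel; hypoxic
    cells additionally deposit s_V*dt VEGF. Necrotic cells are inert.
    Because each cell owns its voxel the per-cell updates touch disjoint
    entries and are applied as one vectorized gather/scatter.
    """
    live = []
    hypoxic = []
    for cid in sorted(cells):
        cell = cells[cid]
        cfg = cell.chart.configuration
        if S_NECROTIC in cfg:
            continue
        live.append(cell.voxel)
        if S_HYPOXIC in cfg:
            hypoxic.append(cell.voxel)
    if live:
        idx = tuple(np.asarray(live, dtype=np.intp).T)
        o2.values[idx] = np.maximum(o2.values[idx] - params.k_O2 * dt, 0.0)
    if hypoxic and params.s_V > 0:
        idx = tuple(np.asarray(hypoxic, dtype=np.intp).T)
        vegf.values[idx] += params.s_V * dt
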