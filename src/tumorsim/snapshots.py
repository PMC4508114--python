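"""Plain-text snapshot exports.

Field snapshots as (x, y, z, value) CSV or as the coarse cube-histogram
grid; agent snapshots as the same tuples the interactive query surface
exposes. All outputs are deterministic (sorted ids, fixed column order).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fields import ScalarField, cube_histogram
from .sim import SimState

__all__ = [
    "field_frame",
    "write_field_csv",
    "write_cube_histogram_csv",
    "cell_frame",
    "write_cell_csv",
    "vessel_frame",
    "write_vessel_csv",
    "branch_event_frame",
    "write_branch_events_csv",
]


def field_frame(field: ScalarField, include_zeros: bool = False) -> pd.DataFrame:
    """Voxel table x, y, z, value (zero voxels skipped unless requested)."""
    v = field.values
    if include_zeros:
        idx = np.indices(v.shape).reshape(3, -1)
        vals = v.ravel()
    else:
        nz = np.nonzero(v)
        idx = np.stack(nz)
        vals = v[nz]
    return pd.DataFrame({"x": idx[0], "y": idx[1], "z": idx[2], "value": vals})


def write_field_csv(field: ScalarField, path: str, include_zeros: bool = False) -> None:
    field_frame(field, include_zeros).to_csv(path, index=False)


def write_cube_histogram_csv(field: ScalarField, block: int, path: str) -> None:
    """Coarse block-sum grid as (bx, by, bz, total) rows."""
    h = cube_histogram(field, block)
    idx = np.indices(h.shape).reshape(3, -1)
    pd.DataFrame({"bx": idx[0], "by": idx[1], "bz": idx[2],
                  "total": h.ravel()}).to_csv(path, index=False)


def cell_frame(state: SimState) -> pd.DataFrame:
    """Tumor-cell snapshot: id, type, x, y, z, state, parent."""
    rows = []
    for cid in sorted(state.cells):
        c = state.cells[cid]
        rows.append({"id": cid, "type": "tumor_cell",
                     "x": c.voxel[0], "y": c.voxel[1], "z": c.voxel[2],
                     "state": c.state, "parent": c.parent})
    return pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "state", "parent"])


def write_cell_csv(state: SimState, path: str) -> None:
    cell_frame(state).to_csv(path, index=False)


def vessel_frame(state: SimState) -> pd.DataFrame:
    """Endothelial snapshot: id, x, y, z, role, pred, sprout_id."""
    rows = []
    for cid in sorted(state.network.cells):
        e = state.network.cells[cid]
        rows.append({"id": cid, "x": e.voxel[0], "y": e.voxel[1], "z": e.voxel[2],
                     "role": e.role, "pred": e.pred, "sprout_id": e.sprout_id})
    return pd.DataFrame(rows, columns=["id", "x", "y", "z", "role", "pred", "sprout_id"])


def write_vessel_csv(state: SimState, path: str) -> None:
    vessel_frame(state).to_csv(path, index=False)


def branch_event_frame(state: SimState) -> pd.DataFrame:
    """Branch-event log: step, x, y, z, vegf at the branching tip."""
    rows = [{"step": s, "x": v[0], "y": v[1], "z": v[2], "vegf": val}
            for s, v, val in state.network.branch_events]
    return pd.DataFrame(rows, columns=["step", "x", "y", "z", "vegf"])


def write_branch_events_csv(state: SimState, path: str) -> None:
    branch_event_frame(state).to_csv(path, index=False)
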