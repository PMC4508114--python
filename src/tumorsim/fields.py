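"""Oxygen and VEGF concentration fields on a 3D lattice.

Each molecular species is a continuum ``ScalarField``: non-negative
concentrations on a regular grid, advanced by an explicit forward-Euler
6-point Laplacian with zero-flux (reflecting) boundaries plus first-order
decay. All quantities are in relative units; the lattice spacing equals one
cell diameter so agents and fields share a grid.

Field operations mutate ``values`` in place and return the field, numpy
style; callers needing a snapshot copy the array first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalarField",
    "FieldParams",
    "STABILITY_LIMIT",
    "FieldError",
    "add_source",
    "diffuse_decay_step",
    "consume",
    "gradient_at",
    "radial_profile",
    "cube_histogram",
    "total_mass",
]

STABILITY_LIMIT = 1.0 / 6.0


class FieldError(ValueError):
    """Bad field configuration or out-of-range voxel access."""


@dataclass
class FieldParams:
    """Transport parameters for the two molecular fields (relative units).

    Each species advances by ``substeps_*`` explicit sub-steps of length
    ``dt/substeps`` per simulation step, so a species may diffuse faster than
    the agent timescale while every sub-step still satisfies the stability
    bound D*(dt/substeps)/h^2 <= 1/6 (enforced at configuration load). VEGF,
    a small signaling molecule, defaults to a faster timescale than the
    metabolically limited oxygen field.
    """

    D_O2: float = 0.15
    D_V: float = 1.2
    k_decay_O2: float = 0.012
    k_decay_V: float = 0.01
    substeps_O2: int = 1
    substeps_V: int = 8
    dt: float = 1.0

    def validate(self, spacing: float = 1.0) -> None:
        for name in ("D_O2", "D_V", "k_decay_O2", "k_decay_V"):
            if getattr(self, name) < 0:
                raise FieldError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise FieldError("dt must be positive")
        if self.substeps_O2 < 1 or self.substeps_V < 1:
            raise FieldError("substeps must be >= 1")
        for name, nsub in (("D_O2", self.substeps_O2), ("D_V", self.substeps_V)):
            lam = getattr(self, name) * (self.dt / nsub) / spacing**2
            if lam > STABILITY_LIMIT + 1e-12:
                raise FieldError(
                    f"stability bound violated for {name}: D*(dt/substeps)/h^2 "
                    f"= {lam:.6g} > 1/6")
        for name, nsub in (("k_decay_O2", self.substeps_O2), ("k_decay_V", self.substeps_V)):
            if getattr(self, name) * self.dt / nsub > 1.0:
                raise FieldError(f"decay step too large for {name}")


@dataclass
class ScalarField:
    values: np.ndarray            # float64, shape (nx, ny, nz), >= 0
    spacing: float = 1.0          # h, relative units (one cell diameter)
    D: float = 0.0                # diffusion coefficient
    k_decay: float = 0.0          # first-order decay rate

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 3:
            raise FieldError(f"field dims must be 3D and >= (3,3,3), got {self.values.shape}")
        if self.spacing <= 0:
            raise FieldError("spacing must be positive")
        if self.D < 0 or self.k_decay < 0:
            raise FieldError("D and k_decay must be >= 0")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise FieldError("field values must be finite and non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @classmethod
    def uniform(cls, dims, value: float = 0.0, spacing: float = 1.0,
                D: float = 0.0, k_decay: float = 0.0) -> "ScalarField":
        return cls(np.full(dims, float(value)), spacing=spacing, D=D, k_decay=k_decay)

    def check_stability(self, dt: float) -> None:
        lam = self.D * dt / self.spacing**2
        if lam > STABILITY_LIMIT + 1e-12:
            raise FieldError(
                f"diffusion unstable: D*dt/h^2 = {lam:.6g} exceeds 1/6")

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.spacing, self.D, self.k_decay)


def _check_voxel(f: ScalarField, voxel) -> tuple[int, int, int]:
    i, j, k = (int(voxel[0]), int(voxel[1]), int(voxel[2]))
    nx, ny, nz = f.dims
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise FieldError(f"voxel {voxel} outside grid {f.dims}")
    return i, j, k


def add_source(f: ScalarField, voxel, amount: float) -> ScalarField:
    """Deposit `amount` at one voxel (e.g. VEGF secretion, vessel oxygen)."""
    if amount < 0:
        raise FieldError("source amount must be >= 0")
    i, j, k = _check_voxel(f, voxel)
    f.values[i, j, k] += amount
    return f


def consume(f: ScalarField, voxel, rate: float, dt: float) -> ScalarField:
    """Remove rate*dt at one voxel, silently clamping at zero."""
    if rate < 0:
        raise FieldError("consumption rate must be >= 0")
    i, j, k = _check_voxel(f, voxel)
    v = f.values[i, j, k] - rate * dt
    f.values[i, j, k] = v if v > 0.0 else 0.0
    return f


def diffuse_decay_step(f: ScalarField, dt: float) -> ScalarField:
    """One explicit diffusion + decay step.

    6-neighbor Laplacian with reflecting boundaries (a missing neighbor
    contributes no flux), then multiplicative decay ``values * (1 - k*dt)``.
    Requires the stability bound D*dt/h^2 <= 1/6, under which the update is a
    convex combination of old values and hence preserves non-negativity; with
    zero decay, total mass is conserved to round-off.
    """
    f.check_stability(dt)
    lam = f.D * dt / f.spacing**2
    v = f.values
    if lam > 0.0:
        p = np.pad(v, 1, mode="edge")
        lap = (p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
               + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
               + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
               - 6.0 * v)
        v = v + lam * lap
    if f.k_decay > 0.0:
        factor = 1.0 - f.k_decay * dt
        if factor < 0.0:
            raise FieldError("decay step too large: k_decay*dt > 1")
        v = v * factor
    np.copyto(f.values, v)
    return f


def gradient_at(f: ScalarField, voxel) -> np.ndarray:
    """Finite-difference gradient at one voxel (concentration per spacing).

    Central differences in the interior, one-sided at boundary faces.
    """
    i, j, k = _check_voxel(f, voxel)
    v, h = f.values, f.spacing
    out = np.empty(3)
    for axis, idx, n in ((0, i, v.shape[0]), (1, j, v.shape[1]), (2, k, v.shape[2])):
        lo = [i, j, k]
        hi = [i, j, k]
        if idx == 0:
            hi[axis] = idx + 1
            out[axis] = (v[tuple(hi)] - v[tuple(lo)]) / h
        elif idx == n - 1:
            lo[axis] = idx - 1
            out[axis] = (v[tuple(hi)] - v[tuple(lo)]) / h
        else:
            lo[axis] = idx - 1
            hi[axis] = idx + 1
            out[axis] = (v[tuple(hi)] - v[tuple(lo)]) / (2.0 * h)
    return out


def total_mass(f: ScalarField) -> float:
    return float(f.values.sum())


def radial_profile(f: ScalarField, center, n_bins: int) -> list[tuple[int, float]]:
    """Total amount per spherical shell around `center` (real coordinates).

    Voxel centers sit at (i+0.5)*h. Distances are binned into ``n_bins``
    equal-width shells spanning [0, max distance]; the shell totals partition
    the field's total mass.
    """
    if n_bins < 1:
        raise FieldError("n_bins must be >= 1")
    nx, ny, nz = f.dims
    h = f.spacing
    cx, cy, cz = (float(center[0]), float(center[1]), float(center[2]))
    xs = (np.arange(nx) + 0.5) * h - cx
    ys = (np.arange(ny) + 0.5) * h - cy
    zs = (np.arange(nz) + 0.5) * h - cz
    r = np.sqrt(xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2)
    rmax = float(r.max())
    if rmax == 0.0:
        idx = np.zeros(r.shape, dtype=np.intp)
    else:
        idx = np.minimum((r / rmax * n_bins).astype(np.intp), n_bins - 1)
    sums = np.bincount(idx.ravel(), weights=f.values.ravel(), minlength=n_bins)
    return [(b, float(sums[b])) for b in range(n_bins)]


def cube_histogram(f: ScalarField, block: int) -> np.ndarray:
    """Coarse grid of block^3 cube sums (ragged edge cubes allowed)."""
    if block < 1:
        raise FieldError("block must be >= 1")
    out = f.values
    for axis in range(3):
        edges = np.arange(0, out.shape[axis], block)
        out = np.add.reduceat(out, edges, axis=axis)
    return out
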