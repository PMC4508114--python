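"""Shipped scenario presets.

Each preset returns a fully validated :class:`~tumorsim.sim.SimConfig`.
The four named scenarios mirror the study conditions the simulator is built
to reproduce:

* ``no_angio``     — no vessels at all: the avascular tumor grows, exhausts
                     its oxygen, and dies back (peak-then-decline).
* ``low_vegf`` / ``high_vegf`` — identical except for the hypoxic VEGF
                     secretion rate; compared at the same step, the high-dose
                     run has recruited far more endothelial cells.
* ``no_branch``    — sprouts may only elongate, never branch; the tumor
                     grows toward the sparse vessels ("hugging" morphology,
                     higher asphericity) instead of spherically.
* ``turning_point_die`` / ``turning_point_recover`` — identical except for
                     the per-cell vessel oxygen delivery ``angio.s_O2``; one
                     run goes extinct, the other is rescued by the arriving
                     vasculature.

Default parameter values are this package's own calibration (relative
units); see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

from .sim import SimConfig
from .vessels import AngioParams

__all__ = [
    "baseline",
    "no_angio",
    "low_vegf",
    "high_vegf",
    "no_branch",
    "branch_control",
    "turning_point_die",
    "turning_point_recover",
    "PRESETS",
]

# matched comparison steps: the VEGF-dose contrast is read at an early step
# while vessels are still being recruited; the branching-morphology contrast
# at a late step, after growth has become vessel-limited
DOSE_STEPS = 320
MORPHOLOGY_STEPS = 500
S_V_LOW = 0.2
S_V_HIGH = 2.0


def baseline(seed: int = 0, n_steps: int = MORPHOLOGY_STEPS) -> SimConfig:
    cfg = SimConfig(seed=seed, n_steps=n_steps)
    cfg.validate()
    return cfg


def no_angio(seed: int = 0, n_steps: int = 500) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.vessels_enabled = False
    return cfg


def low_vegf(seed: int = 0, n_steps: int = DOSE_STEPS) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.tumor.s_V = S_V_LOW
    return cfg


def high_vegf(seed: int = 0, n_steps: int = DOSE_STEPS) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.tumor.s_V = S_V_HIGH
    return cfg


def no_branch(seed: int = 0, n_steps: int = MORPHOLOGY_STEPS) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.angio.allow_branching = False
    return cfg


def branch_control(seed: int = 0, n_steps: int = MORPHOLOGY_STEPS) -> SimConfig:
    """Branching-enabled control matched to :func:`no_branch`."""
    return baseline(seed, n_steps)


def turning_point_die(seed: int = 0, n_steps: int = 500) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.angio.s_O2 = 0.0
    return cfg


def turning_point_recover(seed: int = 0, n_steps: int = 500) -> SimConfig:
    cfg = baseline(seed, n_steps)
    cfg.angio.s_O2 = AngioParams().s_O2  # the default delivery rate, made explicit
    return cfg


PRESETS = {
    "baseline": baseline,
    "no-angio": no_angio,
    "low-vegf": low_vegf,
    "high-vegf": high_vegf,
    "no-branch": no_branch,
    "branch-control": branch_control,
    "turning-die": turning_point_die,
    "turning-recover": turning_point_recover,
}
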