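"""Scenario batteries: the emergent-behavior checks run over many seeds.

Each battery runs one of the shipped scenario contrasts across a list of
seeds and reduces every run to the quantities the contrast is about (peak
and final population, endothelial counts at a matched step, asphericity,
distance to the vasculature, necrotic/live radial structure, branch-event
VEGF enrichment). Tests and the reproduction script both consume these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import presets
from .sim import RunResult, run

__all__ = [
    "avascular_collapse",
    "vegf_dose_pair",
    "branching_morphology_pair",
    "turning_point_pair",
    "RECOVERY_THRESHOLD",
]

# a run "recovers" when its final living population is at least this large;
# collapsed runs end at zero, rescued ones at thousands, so the threshold
# sits far from both
RECOVERY_THRESHOLD = 1000


@dataclass
class CollapseResult:
    seed: int
    peak: int
    peak_step: int
    final: int
    declined: bool   # peak strictly before the final step and final below peak


def avascular_collapse(seeds: Iterable[int], n_steps: int = 500) -> list[CollapseResult]:
    """No-angiogenesis runs: the tumor must peak and then die back."""
    out = []
    for s in seeds:
        m = run(presets.no_angio(seed=s, n_steps=n_steps)).metrics
        live = m["live"].to_numpy()
        i = int(live.argmax())
        out.append(CollapseResult(
            seed=s, peak=int(live[i]), peak_step=int(m["step"].iloc[i]),
            final=int(live[-1]),
            declined=bool(i < len(live) - 1 and live[-1] < live[i])))
    return out


@dataclass
class DoseResult:
    seed: int
    ec_low: int
    ec_high: int
    high_exceeds_low: bool
    # necrotic-core structure, read from the vascular-delayed (low-dose) run
    mean_r_necrotic: float
    mean_r_live: float
    core_inside: bool
    # branch-location enrichment, read from the well-vascularized (high) run
    mean_branch_vegf: float
    mean_vessel_vegf: float
    branches_enriched: bool


def _branch_enrichment(result: RunResult) -> tuple[float, float]:
    state = result.state
    events = state.network.branch_events
    if not events or not state.network.cells:
        return float("nan"), float("nan")
    b = float(np.mean([v for _, _, v in events]))
    voxels = np.asarray([c.voxel for c in state.network.cells.values()])
    v = float(state.vegf.values[tuple(voxels.T)].mean())
    return b, v


def vegf_dose_pair(seeds: Iterable[int], n_steps: int = presets.DOSE_STEPS) -> list[DoseResult]:
    """Low vs high hypoxic VEGF secretion, compared at the same step."""
    out = []
    for s in seeds:
        lo = run(presets.low_vegf(seed=s, n_steps=n_steps))
        hi = run(presets.high_vegf(seed=s, n_steps=n_steps))
        ec_low = int(lo.metrics["endothelial"].iloc[-1])
        ec_high = int(hi.metrics["endothelial"].iloc[-1])
        r_nec = float(lo.metrics["mean_r_necrotic"].iloc[-1])
        r_live = float(lo.metrics["mean_r_live"].iloc[-1])
        b_vegf, v_vegf = _branch_enrichment(hi)
        out.append(DoseResult(
            seed=s, ec_low=ec_low, ec_high=ec_high,
            high_exceeds_low=ec_high > ec_low,
            mean_r_necrotic=r_nec, mean_r_live=r_live,
            core_inside=bool(np.isfinite(r_nec) and np.isfinite(r_live) and r_nec < r_live),
            mean_branch_vegf=b_vegf, mean_vessel_vegf=v_vegf,
            branches_enriched=bool(np.isfinite(b_vegf) and b_vegf > v_vegf)))
    return out


@dataclass
class MorphologyResult:
    seed: int
    asph_no_branch: float
    asph_control: float
    more_aspherical: bool
    dist_no_branch: float
    dist_control: float
    closer_to_vessels: bool


def branching_morphology_pair(seeds: Iterable[int],
                              n_steps: int = presets.MORPHOLOGY_STEPS) -> list[MorphologyResult]:
    """Branching-disabled sprouts vs the branching control ("hugging" shape)."""
    out = []
    for s in seeds:
        nb = run(presets.no_branch(seed=s, n_steps=n_steps)).metrics.iloc[-1]
        ctl = run(presets.branch_control(seed=s, n_steps=n_steps)).metrics.iloc[-1]
        out.append(MorphologyResult(
            seed=s,
            asph_no_branch=float(nb["asphericity"]),
            asph_control=float(ctl["asphericity"]),
            more_aspherical=bool(nb["asphericity"] > ctl["asphericity"]),
            dist_no_branch=float(nb["mean_dist_to_vessel"]),
            dist_control=float(ctl["mean_dist_to_vessel"]),
            closer_to_vessels=bool(nb["mean_dist_to_vessel"] < ctl["mean_dist_to_vessel"])))
    return out


@dataclass
class TurningPointResult:
    seed: int
    final_without_perfusion: int
    final_with_perfusion: int
    extinct: bool
    recovered: bool


def turning_point_pair(seed: int, n_steps: int = 500) -> TurningPointResult:
    """Two configs differing only in per-cell vessel oxygen delivery.

    Without perfusion the tumor must go extinct; with it, the arriving
    vasculature must rescue a large living population.
    """
    die = run(presets.turning_point_die(seed=seed, n_steps=n_steps)).metrics
    rec = run(presets.turning_point_recover(seed=seed, n_steps=n_steps)).metrics
    f_die = int(die["live"].iloc[-1])
    f_rec = int(rec["live"].iloc[-1])
    return TurningPointResult(
        seed=seed, final_without_perfusion=f_die, final_with_perfusion=f_rec,
        extinct=f_die == 0, recovered=f_rec >= RECOVERY_THRESHOLD)
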