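# Methods

`tumorsim` is a deterministic, seedable 3D agent-based model of early solid
tumor growth and sprouting angiogenesis, coupled to continuum oxygen and
VEGF fields on a shared lattice, with hierarchical statecharts as the
behavioral formalism for every agent. This note records the model, its
assumptions, the parameter choices, and what the shipped scenario batteries
do and do not demonstrate.

## Model structure

**Lattice.** Space is a regular grid (default 40×40×40) with spacing equal
to one cell diameter, so at most one agent occupies a voxel. All quantities
are in relative units: parameters are meaningful relative to each other, not
in physical units, and the model supports qualitative rather than
quantitative comparison with experiments.

**Statecharts.** Agent behavior is expressed as statecharts — state trees
with nested (compound) and concurrent (orthogonal) states — executed by a
small engine (`statechart.py`) in the UML/Rhapsody semantics family:
run-to-completion dispatch, inner-first transition priority, ties broken on
the lowest transition id for determinism. Guards and actions are named hooks
resolved by the embedding module, which keeps the engine domain-agnostic.
Timed behavior uses counters advanced by one `tick` per simulation step;
there are no wall-clock timers, so runs are reproducible. History states,
entry/exit actions and event parameters are not implemented. The shipped
tumor and endothelial charts are reconstructions: the original charts were
published only as figures, so we use the minimal topologies that produce the
documented behaviors, and flag them as such in the module docstrings.

**Tumor cells** (`tumor.py`) occupy one voxel each and carry the chart
`root{ Alive{ Proliferating*, Quiescent, Hypoxic }, Necrotic }`. Two oxygen
thresholds create the classic avascular layering: at local O₂ ≥ `T_div`
with a free face-neighbor a cell cycles and divides every `n_cyc` steps into
a uniformly chosen free neighbor (contact inhibition — no migration and no
pushing); between `T_hyp` and `T_div`, or when crowded, it idles with its
cycle frozen; below `T_hyp` it is hypoxic, secretes VEGF at rate `s_V`, and
after `n_nec` *consecutive* hypoxic steps transitions irreversibly to
Necrotic (inert, but still occupying its voxel). Hypoxia is reversible
before `n_nec`; this is what makes the die-or-recover turning point
possible. The split into two thresholds, and keeping necrotic cells in
place, are design choices: they are the minimal structure yielding a
proliferating rim, quiescent band and necrotic core.

**Vasculature** (`vessels.py`). A parent vessel — a pred-linked chain of
quiescent endothelial cells — lies along one grid edge. A root cell whose
local VEGF reaches `T_V` activates once and spawns a migrating *tip* cell
into its highest-VEGF free neighbor. Tips perform a biased random walk:
each step, with probability `p_move`, they move to the highest-VEGF free
face-neighbor (probability `1−eps`) or a uniformly random free neighbor
(`eps`), leaving a *stalk* cell behind so the sprout elongates as a chain of
individual cells. With branching enabled a tip also branches with
probability `min(1, beta·V_local)`, spawning a second tip; branch events
record `(step, voxel, V_local)`. The VEGF-proportional branching rule is
the simplest mechanism that makes branching concentrate near the tumor
emerge rather than being scripted. Every endothelial cell deposits `s_O2`
oxygen per step at its voxel from birth (perfusion); there is no
anastomosis, no vessel regression, no flow model. The vessel graph is a
forest over pred links; a branch tip is pred-linked to the stalk behind the
branching tip so that tips never acquire successors.

**Fields** (`fields.py`). Oxygen and VEGF are continuum fields advanced by
an explicit forward-Euler 6-point Laplacian with zero-flux boundaries and
multiplicative first-order decay `v·(1−k·dt)`. The stability bound
`D·dt_sub/h² ≤ 1/6` is enforced at configuration load; under it the update
is a convex combination, so non-negativity is automatic and mass is
conserved to round-off when decay is zero. Each species may take several
sub-steps per simulation step (`substeps_O2`, `substeps_V`): VEGF, a small
signaling molecule, diffuses on a faster timescale (default 8 sub-steps,
effective D = 1.2) than the agent dynamics, while oxygen transport stays
slow (D = 0.15) so that consumption and perfusion produce steep local
gradients. Molecules are fields, not particles; viewers display them as
radial-shell or cube-histogram density summaries.

**Scheduling** (`sim.py`). Each step executes a fixed phase order —
perfusion, tumor metabolism, field transport, agent ticks (tumor ascending
id, then endothelial activation, then tips ascending id, move then branch),
queued divisions ascending parent id, then observation. One global seeded
generator is consumed in exactly this order, which makes runs bit-for-bit
reproducible (the determinism contract covers metrics tables and recorded
streams). Tips spawned by this step's activation or branching first migrate
on the following step.

## Parameters

Defaults (all relative units):

| parameter | value | meaning |
|---|---|---|
| `baseline_o2` | 4.0 | initial uniform oxygen reservoir |
| `fields.D_O2`, `k_decay_O2` | 0.15, 0.012 | oxygen transport; decay length ≈ 3.5 voxels |
| `fields.D_V`, `k_decay_V` (8 sub-steps) | 1.2, 0.01 | VEGF transport; decay length ≈ 11 voxels |
| `tumor.T_div`, `T_hyp` | 0.30, 0.15 | proliferation / hypoxia thresholds |
| `tumor.n_cyc`, `n_nec` | 6, 100 | cycle length; hypoxia tolerance (steps) |
| `tumor.k_O2`, `s_V` | 0.05, 1.0 | consumption; hypoxic VEGF secretion |
| `angio.T_V` | 0.002 | activation threshold at the parent vessel |
| `angio.p_move`, `eps`, `beta` | 0.8, 0.1, 0.05 | tip motility, exploration, branching |
| `angio.s_O2` | 0.2 | oxygen delivered per endothelial cell per step |

The source model's exact parameter values were not published with it, so
these defaults are this package's own calibration, chosen once so that the
documented qualitative behaviors emerge and then frozen. The regime can be
understood from two screening lengths. An isolated perfused vessel line
with `s_O2 = 0.2` sustains O₂ ≈ 0.3 at distance 1 (just proliferative),
≈ 0.2 at distance 2 (quiescent) and hypoxic levels beyond — so a lone
vessel supports only a thin sheath of tumor, which is what produces the
"hugging" morphology when branching is disabled, whereas overlapping halos
of a branched plexus support wider, rounder growth. The initial reservoir
(4.0, decaying with k = 0.012) sustains a free-floating avascular colony for
roughly 200–270 steps, long enough for it to reach ~10⁴ cells, turn hypoxic
in the interior, and recruit vessels before the rim's `n_nec` budget runs
out; without vessels it collapses to extinction well before step 500.

## Scenario batteries

The four shipped contrasts (`scenarios.py`, presets in `presets.py`):

* **Avascular collapse** (`no-angio`, 500 steps): no vessels; the living
  population peaks (~10⁴ around step 180) and declines to extinction.
* **VEGF dose** (`low-vegf` vs `high-vegf`, matched at step 320): hypoxic
  secretion 0.2 vs 2.0; higher secretion activates the parent vessel sooner
  and recruits strictly more endothelial cells at the same step. The
  low-dose (vascular-delayed) runs are also where the necrotic core is
  measured: mean founder-distance of necrotic cells < that of living cells.
  The high-dose runs provide the branch-location statistic: mean VEGF at
  branch events exceeds mean VEGF over all vessel voxels.
* **Branching morphology** (`no-branch` vs its control, 500 steps):
  elongation-only sprouts leave a more aspherical tumor (gyration-tensor
  asphericity) that sits closer to the vasculature than the branching
  control, whose plexus feeds a compact rounder mass.
* **Turning point** (`turning-die` vs `turning-recover`): identical except
  `angio.s_O2` (0 vs 0.2); one run ends extinct, the other ends with a
  large rescued population. "Recovered" is operationalized as a final
  living population of at least 1,000 cells — collapsed runs end at zero
  and rescued ones in the thousands, so the threshold separates the regimes
  by orders of magnitude.

Batteries use 10 consecutive seeds and majority criteria (≥ 9/10, or ≥ 8/10
for the morphology pair) because individual runs are stochastic. Problem
sizes (40³ grid, 320–500 steps, 10 seeds) are the package's reference
configuration; they keep a full battery within minutes on one core.

## What the scenarios do and do not show

These are emergent-behavior demonstrations inside a deliberately minimal
model: one nutrient species, no cell mechanics or migration, no immune
compartment, no vessel flow, lumen, maturation or pruning, no extracellular
matrix, and branching driven by local VEGF alone. Passing batteries show
that the coupled mechanisms (threshold metabolism, reversible hypoxia with
a necrosis clock, VEGF-gated sprouting, chemotactic tips, perfusion) are
sufficient to reproduce the documented qualitative phenomena; they say
nothing quantitative about real tumor growth curves, and the relative units
are not mapped to hours or micrometers.

## Numerical and design notes

* Explicit (not implicit) diffusion keeps every update local, testable by
  hand stencils, and exactly mass-conserving with reflecting boundaries.
* Tie-breaks are all deterministic: highest-VEGF neighbor ties resolve to
  the lexicographically lowest voxel; equal-priority statechart transitions
  to the lowest transition id.
* `tick_tumor_fast` skips statechart dispatch when no transition can fire
  (the implied target sub-state equals the current one and necrosis is not
  due); a property test asserts trajectory-identity with the full
  statechart path. Metabolism and perfusion scatter per-agent amounts with
  vectorized updates; since each agent owns its voxel, this is exactly the
  per-agent loop.
* The asphericity of a point cloud is `(λ₁ − (λ₂+λ₃)/2)/(λ₁+λ₂+λ₃)` from
  the gyration tensor's eigenvalues: 0 for isotropy, 1/4 for a flat disc,
  1 for a line; it is undefined (raises) for fewer than two distinct points.
* Degenerate inputs: a division with no free neighbor at application time
  is dropped; a boxed-in tip stalls; killing is restricted to tumor cells
  and vessel tips (removing a stalk would sever the forest).
* The wire protocol (see `docs/protocol.md`) is a versioned schema of this
  package's own design: per-step object diffs plus statistics as
  newline-delimited XML documents, byte-stable so that equal seeds yield
  byte-identical recordings.

## Known limitations

Tumors and vessels block each other on the lattice; a dense vessel plexus
can therefore wall in a small tumor and freeze it — visible in the
branching control arm, where late-run populations plateau. Vessel growth
never terminates (tips keep migrating on residual VEGF), so endothelial
counts grow throughout a run; this is harmless for the shipped step counts
but means very long runs fill the grid with vasculature. Both are
consequences of the minimal rule set rather than numerical artifacts.
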