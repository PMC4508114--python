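"""Hierarchical statechart execution engine.

Implements the state-machine formalism used to drive every agent in the
simulator: nested (compound) states, concurrent (orthogonal) regions, and
run-to-completion event dispatch with inner-first transition priority, in the
UML/Rhapsody semantics family.

The engine is deliberately domain-agnostic: guards and actions are *names*;
guard predicates are resolved against a registry supplied by the embedding
module and evaluated on the dispatch context (a plain mapping owned by the
agent). Timed behavior is expressed with counters advanced by an explicit
``tick`` event, never wall-clock timers, so that runs are reproducible.

Not implemented (out of scope): history states, entry/exit actions on states,
deferred events, do-activities, event parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "StateNode",
    "TransitionDef",
    "ChartDef",
    "ChartInstance",
    "ChartError",
    "GuardError",
    "validate_chart",
    "build_chart",
    "load_chart",
    "enter_initial",
    "dispatch",
    "is_in",
]

BASIC = "basic"
COMPOUND = "compound"
ORTHOGONAL = "orthogonal"
_KINDS = (BASIC, COMPOUND, ORTHOGONAL)


class ChartError(ValueError):
    """A structurally invalid chart was used where a valid one is required."""


class GuardError(RuntimeError):
    """A transition guard could not be resolved or raised during evaluation."""


@dataclass(frozen=True)
class StateNode:
    """One node of the state tree.

    kind is one of ``basic`` (leaf), ``compound`` (XOR children, one active at
    a time, with a default ``initial`` child) or ``orthogonal`` (AND children:
    every region active simultaneously; each region must be compound).
    """

    id: str
    kind: str = BASIC
    children: tuple[str, ...] = ()
    initial: str | None = None
    parent: str | None = None


@dataclass(frozen=True)
class TransitionDef:
    id: str
    source: str
    target: str
    trigger: str
    guard: str | None = None
    actions: tuple[str, ...] = ()


class ChartDef:
    """A validated statechart: a state tree plus its transitions.

    Construction precomputes the lookup tables dispatch needs (ancestor
    chains, subtree sets, depth, transitions indexed by trigger in priority
    order) so that per-event dispatch touches only small tuples.
    """

    def __init__(
        self,
        nodes: Mapping[str, StateNode],
        root: str,
        transitions: Sequence[TransitionDef],
        guards: Mapping[str, Callable[[Mapping[str, Any]], bool]] | None = None,
    ):
        self.nodes: dict[str, StateNode] = dict(nodes)
        self.root = root
        self.transitions: tuple[TransitionDef, ...] = tuple(transitions)
        self.guards: dict[str, Callable[[Mapping[str, Any]], bool]] = dict(guards or {})

        violations = validate_chart(self)
        if violations:
            raise ChartError("invalid chart: " + "; ".join(violations))

        # ancestor chain (nearest first), depth, and subtree (descendants incl. self)
        self.ancestors: dict[str, tuple[str, ...]] = {}
        self.depth: dict[str, int] = {}
        for sid in self.nodes:
            chain = []
            cur = self.nodes[sid].parent
            while cur is not None:
                chain.append(cur)
                cur = self.nodes[cur].parent
            self.ancestors[sid] = tuple(chain)
            self.depth[sid] = len(chain)
        self.subtree: dict[str, frozenset[str]] = {}
        for sid in self.nodes:
            members = {sid}
            stack = list(self.nodes[sid].children)
            while stack:
                c = stack.pop()
                members.add(c)
                stack.extend(self.nodes[c].children)
            self.subtree[sid] = frozenset(members)

        # transitions by trigger, priority order: deeper source first, then id
        by_trigger: dict[str, list[TransitionDef]] = {}
        for t in self.transitions:
            by_trigger.setdefault(t.trigger, []).append(t)
        self.by_trigger: dict[str, tuple[TransitionDef, ...]] = {
            ev: tuple(sorted(ts, key=lambda t: (-self._raw_depth(t.source), t.id)))
            for ev, ts in by_trigger.items()
        }
        # transition scope: (domain, exit set template computed per-dispatch)
        self._domain: dict[str, str] = {t.id: self._lca_domain(t) for t in self.transitions}

    def _raw_depth(self, sid: str) -> int:
        d = 0
        cur = self.nodes[sid].parent
        while cur is not None:
            d += 1
            cur = self.nodes[cur].parent
        return d

    def _lca_domain(self, t: TransitionDef) -> str:
        """Lowest compound ancestor common to source and target (both proper).

        Cross-region transitions (LCA orthogonal) are rejected by validation,
        so walking up past orthogonal nodes here is safe.
        """
        anc_s = list(self._chain(t.source))
        anc_t = set(self._chain(t.target))
        for a in anc_s:
            if a in anc_t and self.nodes[a].kind != ORTHOGONAL:
                return a
        return self.root

    def _chain(self, sid: str) -> Iterable[str]:
        cur = self.nodes[sid].parent
        while cur is not None:
            yield cur
            cur = self.nodes[cur].parent

    def bind_guards(self, guards: Mapping[str, Callable[[Mapping[str, Any]], bool]]) -> "ChartDef":
        self.guards.update(guards)
        return self


@dataclass(frozen=True)
class ChartInstance:
    """One agent's live configuration of active states (immutable)."""

    chart: ChartDef
    configuration: frozenset[str]
    context: Mapping[str, Any] = field(default_factory=dict)


def validate_chart(chart: "ChartDef" | Any) -> list[str]:
    """Return every structural violation of the chart, in deterministic order.

    Violations are data, not exceptions: an empty list means the chart is
    valid. Accepts a ChartDef or any object with ``nodes``/``root``/
    ``transitions`` attributes, so it can run before ChartDef finishes
    construction.
    """
    nodes: Mapping[str, StateNode] = chart.nodes
    root: str = chart.root
    out: list[str] = []

    if root not in nodes:
        return [f"root '{root}' is not a node"]

    # tree structure: parent/child consistency, single root, no cycles
    for sid in sorted(nodes):
        n = nodes[sid]
        if n.id != sid:
            out.append(f"node '{sid}': key does not match id '{n.id}'")
        if n.kind not in _KINDS:
            out.append(f"node '{sid}': unknown kind '{n.kind}'")
        if sid == root:
            if n.parent is not None:
                out.append(f"node '{sid}': root must have no parent")
        elif n.parent is None:
            out.append(f"node '{sid}': orphan (no parent and not root)")
        elif n.parent not in nodes:
            out.append(f"node '{sid}': unknown parent '{n.parent}'")
        elif sid not in nodes[n.parent].children:
            out.append(f"node '{sid}': not listed among children of '{n.parent}'")
        for c in n.children:
            if c not in nodes:
                out.append(f"node '{sid}': unknown child '{c}'")
            elif nodes[c].parent != sid:
                out.append(f"node '{sid}': child '{c}' has parent '{nodes[c].parent}'")
        if n.kind == BASIC:
            if n.children:
                out.append(f"node '{sid}': basic node has children")
            if n.initial is not None:
                out.append(f"node '{sid}': basic node has an initial child")
        elif n.kind == COMPOUND:
            if not n.children:
                out.append(f"node '{sid}': compound node has no children")
            if n.initial is None:
                out.append(f"node '{sid}': compound node missing 'initial'")
            elif n.initial not in n.children:
                out.append(f"node '{sid}': initial '{n.initial}' is not a child")
        elif n.kind == ORTHOGONAL:
            if len(n.children) < 2:
                out.append(f"node '{sid}': orthogonal node needs >=2 regions")
            for c in n.children:
                if c in nodes and nodes[c].kind != COMPOUND:
                    out.append(f"node '{sid}': region '{c}' is not compound")

    # cycle check: every node must reach root by parent links
    for sid in sorted(nodes):
        seen = {sid}
        cur = nodes[sid].parent
        ok = sid == root
        while cur is not None and cur in nodes:
            if cur in seen:
                out.append(f"node '{sid}': cycle in parent chain")
                break
            seen.add(cur)
            if cur == root:
                ok = True
            cur = nodes[cur].parent if cur in nodes else None
        else:
            if not ok and nodes[sid].parent in nodes:
                out.append(f"node '{sid}': not connected to root")

    seen_t: set[str] = set()
    for t in sorted(chart.transitions, key=lambda t: t.id):
        if t.id in seen_t:
            out.append(f"transition '{t.id}': duplicate id")
        seen_t.add(t.id)
        if not t.trigger:
            out.append(f"transition '{t.id}': empty trigger")
        if t.source not in nodes:
            out.append(f"transition '{t.id}': unknown source '{t.source}'")
        if t.target not in nodes:
            out.append(f"transition '{t.id}': unknown target '{t.target}'")
        if t.source in nodes and t.target in nodes:
            # reject transitions whose least common ancestor is orthogonal
            # (they would cross concurrent regions)
            lca = _lca(nodes, t.source, t.target)
            if lca is not None and nodes[lca].kind == ORTHOGONAL:
                out.append(f"transition '{t.id}': crosses orthogonal regions")
    return out


def _lca(nodes: Mapping[str, StateNode], a: str, b: str) -> str | None:
    chain_a = []
    cur = nodes[a].parent
    guard = 0
    while cur is not None and cur in nodes and guard < len(nodes) + 1:
        chain_a.append(cur)
        cur = nodes[cur].parent
        guard += 1
    chain_b = set()
    cur = nodes[b].parent
    guard = 0
    while cur is not None and cur in nodes and guard < len(nodes) + 1:
        chain_b.add(cur)
        cur = nodes[cur].parent
        guard += 1
    for x in chain_a:
        if x in chain_b:
            return x
    return None


def _default_completion(chart: ChartDef, sid: str, out: set[str]) -> None:
    """Add sid and its recursive default completion to out."""
    out.add(sid)
    node = chart.nodes[sid]
    if node.kind == COMPOUND:
        _default_completion(chart, node.initial, out)  # type: ignore[arg-type]
    elif node.kind == ORTHOGONAL:
        for region in node.children:
            _default_completion(chart, region, out)


def enter_initial(chart: ChartDef, context: Mapping[str, Any] | None = None) -> ChartInstance:
    """Instance in the chart's default configuration (recursive initial entry)."""
    cfg: set[str] = set()
    _default_completion(chart, chart.root, cfg)
    return ChartInstance(chart=chart, configuration=frozenset(cfg), context=dict(context or {}))


def is_in(instance: ChartInstance, state: str) -> bool:
    if state not in instance.chart.nodes:
        raise KeyError(f"unknown state id '{state}'")
    return state in instance.configuration


def _entry_path(chart: ChartDef, domain: str, target: str, out: list[str]) -> None:
    """States entered when transitioning into `target` under `domain`.

    Walks the ancestor path domain→target, then default-completes the target;
    any orthogonal node on the path has its off-path regions default-completed.
    """
    path = [target]
    cur = chart.nodes[target].parent
    while cur is not None and cur != domain:
        path.append(cur)
        cur = chart.nodes[cur].parent
    path.reverse()  # outermost first, ends at target
    on_path = set(path)
    entered: set[str] = set()
    for node_id in path:
        entered.add(node_id)
        node = chart.nodes[node_id]
        if node.kind == ORTHOGONAL:
            for region in node.children:
                if region not in on_path:
                    _default_completion(chart, region, entered)
    _default_completion(chart, target, entered)
    out.extend(sorted(entered, key=lambda s: (chart.depth[s], s)))


def dispatch(
    instance: ChartInstance,
    event: str,
    context: Mapping[str, Any] | None = None,
    guards: Mapping[str, Callable[[Mapping[str, Any]], bool]] | None = None,
) -> tuple[ChartInstance, list[str]]:
    """Run-to-completion dispatch of one event.

    All maximal non-conflicting enabled transitions fire (at most one per
    orthogonal region); a transition whose source lies deeper in the tree
    takes priority over an ancestor's, and ties among equal-depth candidates
    break on the lexicographically lowest transition id. Returns the new
    instance and the fired action tags in execution order. An event with no
    enabled transition is a no-op, not an error.
    """
    chart = instance.chart
    ctx = context if context is not None else instance.context
    config = instance.configuration

    candidates = chart.by_trigger.get(event, ())
    if not candidates:
        return (ChartInstance(chart, config, dict(ctx)), [])

    guard_map = chart.guards if guards is None else {**chart.guards, **guards}

    fired: list[TransitionDef] = []
    claimed: set[str] = set()  # union of exit sets of selected transitions
    for t in candidates:
        if t.source not in config:
            continue
        if t.guard is not None:
            fn = guard_map.get(t.guard)
            if fn is None:
                raise GuardError(f"transition '{t.id}': unresolved guard '{t.guard}'")
            try:
                enabled = bool(fn(ctx))
            except Exception as exc:  # noqa: BLE001 - reported with transition name
                raise GuardError(f"transition '{t.id}': guard '{t.guard}' raised {exc!r}") from exc
            if not enabled:
                continue
        domain = chart._domain[t.id]
        exit_set = (chart.subtree[domain] - {domain}) & config
        if exit_set & claimed:
            continue  # conflicts with a higher-priority transition
        claimed |= exit_set
        fired.append(t)

    if not fired:
        return (ChartInstance(chart, config, dict(ctx)), [])

    new_config = set(config)
    actions: list[str] = []
    for t in fired:
        domain = chart._domain[t.id]
        new_config -= chart.subtree[domain] - {domain}
        entry: list[str] = []
        _entry_path(chart, domain, t.target, entry)
        new_config.update(entry)
        actions.extend(t.actions)

    return (ChartInstance(chart, frozenset(new_config), dict(ctx)), actions)


def check_configuration(instance: ChartInstance) -> list[str]:
    """Configuration-consistency violations (empty when consistent).

    Used by tests after every dispatch: root active; active compound nodes
    have exactly one active child; active orthogonal nodes have all regions
    active; no inactive node has an active descendant.
    """
    chart = instance.chart
    cfg = instance.configuration
    out: list[str] = []
    if chart.root not in cfg:
        out.append("root not active")
    for sid in sorted(cfg):
        node = chart.nodes[sid]
        active_children = [c for c in node.children if c in cfg]
        if node.kind == COMPOUND and len(active_children) != 1:
            out.append(f"compound '{sid}' has {len(active_children)} active children")
        if node.kind == ORTHOGONAL and len(active_children) != len(node.children):
            out.append(f"orthogonal '{sid}' missing active regions")
    for sid in sorted(cfg):
        parent = chart.nodes[sid].parent
        if parent is not None and parent not in cfg:
            out.append(f"active '{sid}' under inactive parent '{parent}'")
    return out


# ---------------------------------------------------------------------------
# chart document loading (YAML; JSON is a YAML subset)

def build_chart(doc: Mapping[str, Any],
                guards: Mapping[str, Callable[[Mapping[str, Any]], bool]] | None = None) -> ChartDef:
    """Build a ChartDef from a nested mapping with ``states`` and ``transitions``.

    ``states`` is the root node as a nested tree: each node has ``id``,
    ``kind`` (default basic), optionally ``initial`` and ``children`` (list of
    nodes). Rejects documents failing validation.
    """
    if "states" not in doc:
        raise ChartError("chart document missing 'states'")
    nodes: dict[str, StateNode] = {}

    def walk(node_doc: Mapping[str, Any], parent: str | None) -> str:
        sid = str(node_doc["id"])
        kids = node_doc.get("children", []) or []
        kid_ids = []
        for k in kids:
            if isinstance(k, str):  # shorthand: bare id means a basic leaf
                k = {"id": k}
            kid_ids.append(str(k["id"]))
        if sid in nodes:
            raise ChartError(f"duplicate state id '{sid}'")
        kind = node_doc.get("kind")
        if kind is None:
            kind = COMPOUND if kid_ids else BASIC
        initial = node_doc.get("initial")
        nodes[sid] = StateNode(id=sid, kind=str(kind), children=tuple(kid_ids),
                               initial=None if initial is None else str(initial),
                               parent=parent)
        for k in kids:
            if isinstance(k, str):
                k = {"id": k}
            walk(k, sid)
        return sid

    root = walk(doc["states"], None)
    transitions = []
    for i, t in enumerate(doc.get("transitions", []) or []):
        actions = t.get("actions", []) or []
        transitions.append(TransitionDef(
            id=str(t.get("id", f"t{i}")),
            source=str(t["source"]), target=str(t["target"]),
            trigger=str(t["trigger"]),
            guard=None if t.get("guard") is None else str(t["guard"]),
            actions=tuple(str(a) for a in actions),
        ))
    return ChartDef(nodes, root, transitions, guards=guards)


def load_chart(path: str,
               guards: Mapping[str, Callable[[Mapping[str, Any]], bool]] | None = None) -> ChartDef:
    """Load a chart definition file (YAML or JSON dialect)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ChartError(f"chart file '{path}' is not a mapping document")
    return build_chart(doc, guards=guards)
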