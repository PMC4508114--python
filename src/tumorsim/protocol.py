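"""Reactive-animation wire protocol: XML step streams, recordings, commands.

The simulator and any viewer communicate through XML documents, one per
simulation step: object diffs (``create`` / ``update`` / ``delete``) plus a
``stats`` summary, so a renderer can maintain the scene incrementally.
Inbound control commands (set a parameter, kill/create objects, query,
pause/speed) travel the other way as small XML fragments.

The schema here is this package's own, versioned design (see
docs/protocol.md): it carries object diffs, per-step statistics and control
commands over newline-delimited XML documents — one document per line — so
recordings are streamable, seekable and diff-able. Encoding is byte-stable:
attribute order is fixed and reals are rendered with ``%.9g``, so identical
runs produce identical recording files. Transport (sockets, pipes) is a thin
adapter outside this module; everything here works on strings, byte streams
and files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping
from xml.sax.saxutils import quoteattr

__all__ = [
    "PROTOCOL_VERSION",
    "AnimMessage",
    "Command",
    "RunRecording",
    "StreamRecorder",
    "ProtocolError",
    "VersionError",
    "encode_step",
    "decode_step",
    "encode_command",
    "decode_command",
    "apply_command",
    "record",
    "replay",
    "reconstruct",
    "diff_messages",
]

PROTOCOL_VERSION = "1"

KIND_CREATE = "create"
KIND_UPDATE = "update"
KIND_DELETE = "delete"
_OBJ_KINDS = (KIND_CREATE, KIND_UPDATE, KIND_DELETE)

_CMD_KINDS = ("set_param", "kill", "create", "query", "pause", "speed")


class ProtocolError(ValueError):
    """Malformed or schema-violating protocol document."""


class VersionError(ProtocolError):
    """Recording/stream produced by an incompatible protocol version."""


def _fmt_real(x: float) -> str:
    return f"{x:.9g}"


@dataclass(frozen=True)
class AnimMessage:
    """One wire event: an object diff within one step document."""

    kind: str                               # create | update | delete
    obj_id: int
    obj_type: str | None = None             # tumor_cell | endothelial_cell
    position: tuple[int, int, int] | None = None
    state: str | None = None
    pred: int | None = None                 # endothelial tube-rendering link

    def __post_init__(self) -> None:
        if self.kind not in _OBJ_KINDS:
            raise ProtocolError(f"unknown message kind '{self.kind}'")
        if self.kind in (KIND_CREATE, KIND_UPDATE):
            if self.obj_type is None or self.position is None or self.state is None:
                raise ProtocolError(f"{self.kind} message requires type/position/state")


@dataclass(frozen=True)
class Command:
    """One inbound control command."""

    kind: str
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _CMD_KINDS:
            raise ProtocolError(f"unknown command kind '{self.kind}'")


# ---------------------------------------------------------------------------
# step documents

def encode_step(step: int, messages: Iterable[AnimMessage],
                stats: Mapping[tuple[str, str], int]) -> str:
    """Serialize one step document (no whitespace, fixed attribute order).

    The document is ``<step t="...">`` with one child per message, then one
    ``<stats>`` element holding per-(type, state) counts sorted by key.
    """
    parts = [f'<step t="{int(step)}">']
    seen_created: set[int] = set()
    seen_deleted: set[int] = set()
    for m in messages:
        if m.obj_id in seen_deleted:
            raise ProtocolError(f"message for id {m.obj_id} after its delete")
        if m.kind == KIND_CREATE:
            if m.obj_id in seen_created:
                raise ProtocolError(f"duplicate create for id {m.obj_id}")
            seen_created.add(m.obj_id)
        if m.kind == KIND_DELETE:
            seen_deleted.add(m.obj_id)
            parts.append(f'<delete id="{int(m.obj_id)}"/>')
            continue
        x, y, z = m.position  # type: ignore[misc]
        attrs = (f'id="{int(m.obj_id)}" type={quoteattr(m.obj_type)} '
                 f'x="{int(x)}" y="{int(y)}" z="{int(z)}" state={quoteattr(m.state)}')
        if m.pred is not None:
            attrs += f' pred="{int(m.pred)}"'
        parts.append(f"<{m.kind} {attrs}/>")
    stat_items = sorted(stats.items())
    if stat_items:
        parts.append("<stats>")
        for (otype, stag), n in stat_items:
            parts.append(f'<count type={quoteattr(otype)} state={quoteattr(stag)} n="{int(n)}"/>')
        parts.append("</stats>")
    else:
        parts.append("<stats/>")
    parts.append("</step>")
    return "".join(parts)


_ALLOWED_ATTRS = {
    "create": {"id", "type", "x", "y", "z", "state", "pred"},
    "update": {"id", "type", "x", "y", "z", "state", "pred"},
    "delete": {"id"},
    "count": {"type", "state", "n"},
}


def _parse_xml(doc: str) -> ET.Element:
    try:
        return ET.fromstring(doc)
    except ET.ParseError as exc:
        raise ProtocolError(f"malformed XML at line {exc.position[0]}, "
                            f"column {exc.position[1]}: {exc.msg}") from exc


def decode_step(doc: str) -> tuple[int, list[AnimMessage], dict[tuple[str, str], int]]:
    """Inverse of encode_step. Unknown elements or attributes are rejected."""
    root = _parse_xml(doc)
    if root.tag != "step":
        raise ProtocolError(f"expected <step>, got <{root.tag}>")
    extra = set(root.attrib) - {"t"}
    if extra or "t" not in root.attrib:
        raise ProtocolError(f"<step> must carry exactly attribute 't', got {sorted(root.attrib)}")
    t = int(root.attrib["t"])
    messages: list[AnimMessage] = []
    stats: dict[tuple[str, str], int] = {}
    seen_stats = False
    for el in root:
        if el.tag == "stats":
            if seen_stats:
                raise ProtocolError("duplicate <stats> element")
            seen_stats = True
            for c in el:
                if c.tag != "count":
                    raise ProtocolError(f"unknown element <{c.tag}> in <stats>")
                if set(c.attrib) != _ALLOWED_ATTRS["count"]:
                    raise ProtocolError(f"<count> attributes must be type/state/n, got {sorted(c.attrib)}")
                stats[(c.attrib["type"], c.attrib["state"])] = int(c.attrib["n"])
            continue
        if el.tag not in _OBJ_KINDS:
            raise ProtocolError(f"unknown element <{el.tag}> in <step>")
        allowed = _ALLOWED_ATTRS[el.tag]
        extra = set(el.attrib) - allowed
        if extra:
            raise ProtocolError(f"unknown attributes {sorted(extra)} on <{el.tag}>")
        if el.tag == KIND_DELETE:
            messages.append(AnimMessage(kind=KIND_DELETE, obj_id=int(el.attrib["id"])))
            continue
        for req in ("id", "type", "x", "y", "z", "state"):
            if req not in el.attrib:
                raise ProtocolError(f"<{el.tag}> missing attribute '{req}'")
        messages.append(AnimMessage(
            kind=el.tag, obj_id=int(el.attrib["id"]), obj_type=el.attrib["type"],
            position=(int(el.attrib["x"]), int(el.attrib["y"]), int(el.attrib["z"])),
            state=el.attrib["state"],
            pred=int(el.attrib["pred"]) if "pred" in el.attrib else None))
    if not seen_stats:
        raise ProtocolError("<step> missing <stats>")
    return t, messages, stats


# ---------------------------------------------------------------------------
# commands

def encode_command(cmd: Command) -> str:
    p = cmd.payload
    if cmd.kind == "set_param":
        return f'<set param={quoteattr(p["param"])} value={quoteattr(str(p["value"]))}/>'
    if cmd.kind == "kill":
        if p.get("mode") == "random":
            return f'<kill type={quoteattr(p["type"])} mode="random"/>'
        return f'<kill id="{int(p["id"])}"/>'
    if cmd.kind == "create":
        x, y, z = p["voxel"]
        return f'<create type={quoteattr(p["type"])} x="{int(x)}" y="{int(y)}" z="{int(z)}"/>'
    if cmd.kind == "query":
        return f'<query id="{int(p["id"])}"/>'
    if cmd.kind == "pause":
        return "<pause/>"
    if cmd.kind == "speed":
        return f'<speed factor="{_fmt_real(float(p["factor"]))}"/>'
    raise ProtocolError(f"unknown command kind '{cmd.kind}'")


def decode_command(doc: str) -> Command:
    el = _parse_xml(doc)
    tag = el.tag
    attrs = dict(el.attrib)
    if tag == "set":
        if set(attrs) != {"param", "value"}:
            raise ProtocolError("<set> requires exactly param and value")
        return Command("set_param", {"param": attrs["param"], "value": attrs["value"]})
    if tag == "kill":
        if set(attrs) == {"id"}:
            return Command("kill", {"id": int(attrs["id"])})
        if set(attrs) == {"type", "mode"} and attrs["mode"] == "random":
            return Command("kill", {"type": attrs["type"], "mode": "random"})
        raise ProtocolError("<kill> requires id=... or type=... mode=\"random\"")
    if tag == "create":
        if set(attrs) != {"type", "x", "y", "z"}:
            raise ProtocolError("<create> requires type and x/y/z")
        return Command("create", {"type": attrs["type"],
                                  "voxel": (int(attrs["x"]), int(attrs["y"]), int(attrs["z"]))})
    if tag == "query":
        if set(attrs) != {"id"}:
            raise ProtocolError("<query> requires exactly id")
        return Command("query", {"id": int(attrs["id"])})
    if tag == "pause":
        if attrs:
            raise ProtocolError("<pause> takes no attributes")
        return Command("pause")
    if tag == "speed":
        if set(attrs) != {"factor"}:
            raise ProtocolError("<speed> requires exactly factor")
        return Command("speed", {"factor": float(attrs["factor"])})
    raise ProtocolError(f"unknown command <{tag}>")


def apply_command(state, config, cmd: Command) -> dict[str, Any]:
    """Apply one decoded command to a live simulation; returns the reply.

    ``set_param`` mutates a dotted parameter path (e.g. ``tumor.s_V``) for
    all subsequent steps; an unknown path or invalid value produces an error
    reply and mutates nothing. ``kill``/``create``/``query`` delegate to the
    simulator; ``pause``/``speed`` are pacing metadata only and are
    acknowledged without touching the state.
    """
    from . import sim as _sim

    try:
        if cmd.kind == "set_param":
            path, raw = cmd.payload["param"], cmd.payload["value"]
            parts = path.split(".")
            if len(parts) == 2 and parts[0] in ("tumor", "angio", "fields"):
                target = getattr(config, parts[0])
                attr = parts[1]
            elif len(parts) == 1:
                target, attr = config, parts[0]
            else:
                raise _sim.CommandRejected(f"unknown parameter path '{path}'")
            if not hasattr(target, attr):
                raise _sim.CommandRejected(f"unknown parameter path '{path}'")
            old = getattr(target, attr)
            if isinstance(old, bool):
                value: Any = str(raw).strip().lower() in ("1", "true", "yes")
            elif isinstance(old, int):
                value = int(raw)
            elif isinstance(old, float):
                value = float(raw)
            elif isinstance(old, str):
                value = str(raw)
            else:
                raise _sim.CommandRejected(f"parameter '{path}' is not settable")
            setattr(target, attr, value)
            try:
                config.validate()
            except Exception as exc:
                setattr(target, attr, old)
                raise _sim.CommandRejected(f"invalid value for '{path}': {exc}") from exc
            return {"status": "ok", "command": "set_param", "param": path, "value": value}
        if cmd.kind == "kill":
            victim = _sim.kill_object(
                state, config,
                obj_id=cmd.payload.get("id"),
                obj_type=cmd.payload.get("type"))
            return {"status": "ok", "command": "kill", "id": victim}
        if cmd.kind == "create":
            new_id = _sim.create_object(state, config, cmd.payload["type"], cmd.payload["voxel"])
            return {"status": "ok", "command": "create", "id": new_id}
        if cmd.kind == "query":
            info = _sim.query_object(state, cmd.payload["id"])
            return {"status": "ok", "command": "query", **info}
        if cmd.kind in ("pause", "speed"):
            return {"status": "ok", "command": cmd.kind,
                    **({"factor": cmd.payload["factor"]} if cmd.kind == "speed" else {})}
    except (_sim.CommandRejected, ValueError) as exc:
        return {"status": "error", "command": cmd.kind, "message": str(exc)}
    return {"status": "error", "command": cmd.kind, "message": "unhandled command"}


# ---------------------------------------------------------------------------
# recording and replay

def _header_line(seed: int, config_digest: str) -> str:
    return (f'<run version="{PROTOCOL_VERSION}" seed="{int(seed)}" '
            f'config={quoteattr(config_digest)}/>')


def _parse_header(line: str) -> dict[str, str]:
    el = _parse_xml(line)
    if el.tag != "run" or set(el.attrib) != {"version", "seed", "config"}:
        raise ProtocolError("invalid recording header")
    if el.attrib["version"] != PROTOCOL_VERSION:
        raise VersionError(
            f"recording version {el.attrib['version']} != supported {PROTOCOL_VERSION}")
    return dict(el.attrib)


@dataclass
class RunRecording:
    """A recorded run: header metadata plus one serialized document per step."""

    header: dict[str, str]
    steps: list[str] = field(default_factory=list)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_header_line(int(self.header["seed"]), self.header["config"]) + "\n")
            for line in self.steps:
                fh.write(line + "\n")

    @classmethod
    def load(cls, path: str) -> "RunRecording":
        with open(path, "r", encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise ProtocolError(f"empty recording '{path}'")
        header = _parse_header(lines[0])
        return cls(header=header, steps=lines[1:])


class StreamRecorder:
    """Accumulates per-step diffs of a live simulation into a recording."""

    def __init__(self, config) -> None:
        self.header = {"version": PROTOCOL_VERSION, "seed": str(config.seed),
                       "config": config.digest()}
        self.steps: list[str] = []
        self._prev: dict[int, tuple] = {}
        self._last_t: int | None = None

    def emit_step(self, state) -> str:
        from .sim import scene_snapshot

        scene = scene_snapshot(state)
        if self._last_t is not None and state.step <= self._last_t:
            raise ProtocolError("step indices must be strictly increasing")
        msgs = diff_messages(self._prev, scene)
        stats: dict[tuple[str, str], int] = {}
        for otype, _voxel, stag, _pred in scene.values():
            stats[(otype, stag)] = stats.get((otype, stag), 0) + 1
        doc = encode_step(state.step, msgs, stats)
        self.steps.append(doc)
        self._prev = scene
        self._last_t = state.step
        return doc

    def finish(self) -> RunRecording:
        return RunRecording(header=dict(self.header), steps=list(self.steps))


def diff_messages(prev: Mapping[int, tuple], cur: Mapping[int, tuple]) -> list[AnimMessage]:
    """Object diff between two scene snapshots, ascending id.

    Snapshots map id -> (type, voxel, state tag, pred). New ids become
    ``create``, changed tuples ``update``, vanished ids ``delete``.
    """
    out: list[AnimMessage] = []
    for cid in sorted(set(prev) | set(cur)):
        if cid not in prev:
            otype, voxel, stag, pred = cur[cid]
            out.append(AnimMessage(KIND_CREATE, cid, otype, voxel, stag, pred))
        elif cid not in cur:
            out.append(AnimMessage(KIND_DELETE, cid))
        elif prev[cid] != cur[cid]:
            otype, voxel, stag, pred = cur[cid]
            out.append(AnimMessage(KIND_UPDATE, cid, otype, voxel, stag, pred))
    return out


def record(recording: RunRecording, path: str) -> None:
    recording.save(path)


def replay(path: str, speed: float = 1.0
           ) -> Iterator[tuple[int, list[AnimMessage], dict[tuple[str, str], int], float]]:
    """Iterate a recording: yields (step, messages, stats, pacing hint).

    The pacing hint is the suggested inter-step delay ``1/speed`` (relative
    units); the speed factor never affects decoded content. Raises at the
    failing step index on truncation or version mismatch.
    """
    if speed <= 0:
        raise ProtocolError("speed factor must be positive")
    rec = RunRecording.load(path)
    last_t: int | None = None
    for i, line in enumerate(rec.steps):
        try:
            t, msgs, stats = decode_step(line)
        except ProtocolError as exc:
            raise ProtocolError(f"replay failed at step document {i}: {exc}") from exc
        if last_t is not None and t <= last_t:
            raise ProtocolError(f"replay failed at step document {i}: non-increasing step {t}")
        last_t = t
        yield t, msgs, stats, 1.0 / speed


def reconstruct(steps: Iterable[tuple[int, list[AnimMessage], dict]]) -> Iterator[
        tuple[int, dict[int, tuple], dict]]:
    """Apply decoded step diffs to an empty scene, yielding the scene per step.

    The scene maps id -> (type, position, state, pred); equality with the
    live simulation's snapshot at every step is the stream-completeness
    contract.
    """
    scene: dict[int, tuple] = {}
    for t, msgs, stats in steps:
        for m in msgs:
            if m.kind == KIND_CREATE:
                if m.obj_id in scene:
                    raise ProtocolError(f"create of existing id {m.obj_id} at step {t}")
                scene[m.obj_id] = (m.obj_type, m.position, m.state, m.pred)
            elif m.kind == KIND_UPDATE:
                if m.obj_id not in scene:
                    raise ProtocolError(f"update of unknown id {m.obj_id} at step {t}")
                scene[m.obj_id] = (m.obj_type, m.position, m.state, m.pred)
            else:
                if m.obj_id not in scene:
                    raise ProtocolError(f"delete of unknown id {m.obj_id} at step {t}")
                del scene[m.obj_id]
        yield t, dict(scene), stats
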