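# Wire protocol reference (version 1)

The simulator streams its state to viewers as XML documents, one per
simulation step, and accepts XML control commands. The schema is versioned
and deliberately small: object diffs, per-step statistics, and six command
kinds. Transport is out of scope — the package reads and writes strings,
byte streams and files; wiring to a socket is a thin adapter.

## Step documents

One document per step, no whitespace between elements, fixed attribute
order, reals rendered with `%.9g` — encoding is byte-stable, so identical
runs produce identical streams.

```xml
<step t="12">
  <create id="41" type="tumor_cell" x="20" y="21" z="20" state="Proliferating"/>
  <update id="3" type="endothelial_cell" x="5" y="1" z="0" state="Migrating" pred="17"/>
  <delete id="9"/>
  <stats>
    <count type="tumor_cell" state="Proliferating" n="12"/>
    <count type="tumor_cell" state="Necrotic" n="3"/>
  </stats>
</step>
```

Rules:

* `create` precedes any `update`/`delete` for the same id within a stream;
  `delete` is terminal per id.
* `type` is `tumor_cell` or `endothelial_cell`; `state` is the agent's
  statechart leaf state.
* `pred` appears only on endothelial cells and names the predecessor cell
  along the vessel, which is the adjacency a viewer should use for
  tube rendering.
* `<stats>` holds one `<count>` per (type, state) pair, sorted by key; an
  empty step is `<step t="5"><stats/></step>`.
* Decoders are strict: unknown elements or attributes are rejected, not
  ignored.

## Commands (viewer → model)

```xml
<set param="tumor.s_V" value="2.0"/>     <!-- dotted parameter path -->
<kill id="17"/>
<kill type="tumor_cell" mode="random"/>
<create type="tumor_cell" x="1" y="2" z="3"/>
<query id="17"/>
<pause/>
<speed factor="2.0"/>
```

`set` mutates the named parameter for all subsequent steps (unknown paths
or invalid values produce an error reply and mutate nothing). `kill` and
`create` delegate to the simulator (random kills consume the simulation
rng and are reproducible). `query` returns position, state, parent and the
local field values. `pause`/`speed` are pacing metadata only and never
affect simulation content.

## Recording files (`.ras.xml`)

Newline-delimited UTF-8: a header line, then one step document per line.

```
<run version="1" seed="3" config="1f0c9a7b2d6e4a81"/>
<step t="0">...</step>
<step t="1">...</step>
```

`config` is a content hash of the generating configuration. Step indices
are strictly increasing. Replay verifies the version and yields decoded
steps with a pacing hint (`1/speed`); the speed factor never changes
decoded content. Applying the diffs of a recording to an empty scene
reconstructs, at every step, exactly the live simulation's set of
(id, type, position, state, pred) tuples — this stream-completeness
property is tested, and equal (config, seed) pairs produce byte-identical
files.
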