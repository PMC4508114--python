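"""Wire protocol: encoding, decoding, commands, recording, replay."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorsim import protocol
from tumorsim.presets import baseline
from tumorsim.protocol import (
    AnimMessage,
    Command,
    ProtocolError,
    RunRecording,
    StreamRecorder,
    VersionError,
    apply_command,
    decode_command,
    decode_step,
    diff_messages,
    encode_command,
    encode_step,
    reconstruct,
    replay,
)
from tumorsim.sim import SimConfig, init_scenario, scene_snapshot, step


def small_config(**kw):
    base = dict(dims=(12, 12, 12), n_steps=0, snapshot_every=5)
    base.update(kw)
    cfg = SimConfig(**base)
    cfg.validate()
    return cfg


class TestStepDocuments:
    def test_empty_step_document(self):
        assert encode_step(5, [], {}) == '<step t="5"><stats/></step>'

    def test_single_create_schema(self):
        msg = AnimMessage("create", 3, "tumor_cell", (1, 2, 3), "Proliferating")
        doc = encode_step(0, [msg], {("tumor_cell", "Proliferating"): 1})
        assert doc.count("<create") == 1
        for frag in ('id="3"', 'type="tumor_cell"', 'x="1"', 'y="2"', 'z="3"',
                     'state="Proliferating"'):
            assert frag in doc

    def test_pred_attribute_only_for_linked_cells(self):
        with_pred = AnimMessage("create", 4, "endothelial_cell", (0, 0, 0), "Elongating", pred=2)
        doc = encode_step(0, [with_pred], {})
        assert 'pred="2"' in doc
        t, msgs, _ = decode_step(doc)
        assert msgs[0].pred == 2

    def test_roundtrip_identity(self):
        msgs = [
            AnimMessage("create", 1, "tumor_cell", (5, 5, 5), "Proliferating"),
            AnimMessage("update", 1, "tumor_cell", (5, 5, 5), "Hypoxic"),
            AnimMessage("create", 2, "endothelial_cell", (0, 1, 2), "Migrating", pred=1),
            AnimMessage("delete", 1),
        ]
        stats = {("tumor_cell", "Hypoxic"): 1, ("endothelial_cell", "Migrating"): 1}
        t, back, s = decode_step(encode_step(42, msgs, stats))
        assert (t, back, s) == (42, msgs, stats)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_valid_diffs_roundtrip(self, seed):
        rnd = random.Random(seed)
        msgs, active, nid = [], [], 0
        for _ in range(rnd.randint(0, 10)):
            kind = rnd.choice(["create", "create", "update", "delete"])
            if kind == "delete" and active:
                msgs.append(AnimMessage("delete", active.pop(rnd.randrange(len(active)))))
                continue
            if kind == "update" and active:
                oid = rnd.choice(active)
            else:
                oid, nid = nid, nid + 1
                active.append(oid)
                kind = "create"
            otype = rnd.choice(["tumor_cell", "endothelial_cell"])
            msgs.append(AnimMessage(
                kind, oid, otype,
                (rnd.randint(0, 39), rnd.randint(0, 39), rnd.randint(0, 39)),
                rnd.choice(["Proliferating", "Necrotic", "Migrating"]),
                rnd.randint(0, 50) if otype == "endothelial_cell" else None))
        stats = {("tumor_cell", "Quiescent"): rnd.randint(0, 99)}
        doc = encode_step(7, msgs, stats)
        t, back, s = decode_step(doc)
        assert (t, back, s) == (7, msgs, stats)
        assert encode_step(t, back, s) == doc  # byte-stable re-encoding

    def test_truncated_document_is_a_parse_error(self):
        doc = encode_step(1, [], {})
        with pytest.raises(ProtocolError, match="line"):
            decode_step(doc[:-5])

    def test_unknown_elements_and_attributes_rejected(self):
        with pytest.raises(ProtocolError, match="unknown"):
            decode_step('<step t="1"><blob/><stats/></step>')
        with pytest.raises(ProtocolError, match="unknown"):
            decode_step('<step t="1"><delete id="1" color="red"/><stats/></step>')
        with pytest.raises(ProtocolError):
            decode_step('<step t="1"></step>')  # stats element is mandatory

    def test_message_after_delete_rejected_at_encode(self):
        msgs = [AnimMessage("delete", 1),
                AnimMessage("update", 1, "tumor_cell", (0, 0, 0), "Hypoxic")]
        with pytest.raises(ProtocolError, match="delete"):
            encode_step(0, msgs, {})


class TestCommands:
    @pytest.mark.parametrize("cmd", [
        Command("set_param", {"param": "tumor.s_V", "value": "2.0"}),
        Command("kill", {"id": 17}),
        Command("kill", {"type": "tumor_cell", "mode": "random"}),
        Command("create", {"type": "tumor_cell", "voxel": (1, 2, 3)}),
        Command("query", {"id": 17}),
        Command("pause"),
        Command("speed", {"factor": 2.0}),
    ])
    def test_command_roundtrip(self, cmd):
        back = decode_command(encode_command(cmd))
        assert back.kind == cmd.kind
        for k, v in cmd.payload.items():
            got = back.payload[k]
            assert got == v or str(got) == str(v)

    def test_malformed_commands_rejected(self):
        for doc in ['<set param="x"/>', '<kill/>', '<speed/>', '<warp factor="9"/>']:
            with pytest.raises(ProtocolError):
                decode_command(doc)

    def test_set_param_takes_effect_for_subsequent_steps(self):
        """Changing s_V mid-run matches a fresh run that used the new value."""
        cfg_a = small_config(vessels_enabled=False, baseline_o2=0.1, n_steps=0)
        cfg_a.tumor.n_nec = 10**6   # keep the cell hypoxic and secreting
        st_a = init_scenario(cfg_a)
        apply_command(st_a, cfg_a, decode_command('<set param="tumor.s_V" value="3.0"/>'))
        assert cfg_a.tumor.s_V == 3.0
        cfg_b = small_config(vessels_enabled=False, baseline_o2=0.1, n_steps=0)
        cfg_b.tumor.n_nec = 10**6
        cfg_b.tumor.s_V = 3.0
        st_b = init_scenario(cfg_b)
        for _ in range(10):
            step(st_a, cfg_a)
            step(st_b, cfg_b)
        assert np.array_equal(st_a.vegf.values, st_b.vegf.values)
        assert st_a.vegf.values.sum() > 0

    def test_set_param_bogus_path_mutates_nothing(self):
        cfg = small_config()
        st = init_scenario(cfg)
        before = cfg.to_dict()
        reply = apply_command(st, cfg, Command("set_param", {"param": "tumor.nope", "value": "1"}))
        assert reply["status"] == "error"
        assert cfg.to_dict() == before

    def test_set_param_invalid_value_is_rolled_back(self):
        cfg = small_config()
        st = init_scenario(cfg)
        reply = apply_command(st, cfg,
                              Command("set_param", {"param": "tumor.T_hyp", "value": "9.0"}))
        assert reply["status"] == "error" and cfg.tumor.T_hyp < cfg.tumor.T_div

    def test_query_reply_contains_parent_none_for_founder(self):
        cfg = small_config()
        st = init_scenario(cfg)
        reply = apply_command(st, cfg, Command("query", {"id": 0}))
        assert reply["status"] == "ok" and reply["parent"] is None

    def test_kill_and_create_delegate_to_simulator(self):
        cfg = small_config()
        st = init_scenario(cfg)
        r1 = apply_command(st, cfg, Command("create", {"type": "tumor_cell", "voxel": (1, 1, 1)}))
        assert r1["status"] == "ok"
        r2 = apply_command(st, cfg, Command("kill", {"id": r1["id"]}))
        assert r2["status"] == "ok" and r1["id"] not in st.cells

    def test_pause_and_speed_do_not_touch_state(self):
        cfg = small_config()
        st = init_scenario(cfg)
        occ = st.occupancy.copy()
        assert apply_command(st, cfg, Command("pause"))["status"] == "ok"
        assert apply_command(st, cfg, Command("speed", {"factor": 4.0}))["factor"] == 4.0
        assert np.array_equal(st.occupancy, occ)


class TestRecordingReplay:
    def run_recorded(self, tmp_path, seed=3, n_steps=30):
        from tumorsim.sim import run
        cfg = baseline(seed=seed, n_steps=n_steps)
        cfg.dims = (16, 16, 16)
        cfg.baseline_o2 = 0.5      # small, fast-evolving world
        cfg.tumor.n_nec = 8
        cfg.record_path = str(tmp_path / f"run_{seed}.ras.xml")
        return run(cfg), cfg

    def test_record_then_replay_reconstructs_every_scene(self, tmp_path):
        result, cfg = self.run_recorded(tmp_path)
        # independent live rerun for the reference scenes
        cfg2 = baseline(seed=3, n_steps=30)
        cfg2.dims = (16, 16, 16)
        cfg2.baseline_o2 = 0.5
        cfg2.tumor.n_nec = 8
        st = init_scenario(cfg2)
        scenes = [dict(scene_snapshot(st))]
        for _ in range(30):
            step(st, cfg2)
            scenes.append(dict(scene_snapshot(st)))
        decoded = ((t, m, s) for t, m, s, _ in replay(cfg.record_path))
        count = 0
        for (t, scene, stats), live in zip(reconstruct(decoded), scenes):
            assert scene == live
            assert sum(stats.values()) == len(live)
            count += 1
        assert count == 31

    def test_same_seed_recordings_are_byte_identical(self, tmp_path):
        r1, c1 = self.run_recorded(tmp_path, seed=5)
        path1 = c1.record_path
        c2 = baseline(seed=5, n_steps=30)
        c2.dims = (16, 16, 16)
        c2.baseline_o2 = 0.5
        c2.tumor.n_nec = 8
        c2.record_path = str(tmp_path / "again.ras.xml")
        from tumorsim.sim import run
        run(c2)
        assert open(path1, "rb").read() == open(c2.record_path, "rb").read()

    def test_speed_factor_changes_pacing_not_content(self, tmp_path):
        _, cfg = self.run_recorded(tmp_path, seed=6, n_steps=10)
        slow = [(t, m, s) for t, m, s, _ in replay(cfg.record_path, speed=0.5)]
        fast = [(t, m, s) for t, m, s, _ in replay(cfg.record_path, speed=8.0)]
        assert slow == fast
        delays = {d for _, _, _, d in replay(cfg.record_path, speed=4.0)}
        assert delays == {0.25}

    def test_version_mismatch_is_detected(self, tmp_path):
        p = tmp_path / "old.ras.xml"
        p.write_text('<run version="99" seed="0" config="x"/>\n')
        with pytest.raises(VersionError):
            list(replay(str(p)))

    def test_truncated_recording_fails_at_the_bad_step(self, tmp_path):
        _, cfg = self.run_recorded(tmp_path, seed=7, n_steps=5)
        lines = open(cfg.record_path).read().splitlines()
        lines[-1] = lines[-1][:20]
        p = tmp_path / "trunc.ras.xml"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ProtocolError, match="step document"):
            list(replay(str(p)))

    def test_recorder_rejects_non_increasing_steps(self):
        cfg = small_config()
        st = init_scenario(cfg)
        rec = StreamRecorder(cfg)
        rec.emit_step(st)
        with pytest.raises(ProtocolError, match="increasing"):
            rec.emit_step(st)


class TestDiff:
    def test_diff_classifies_create_update_delete(self):
        prev = {1: ("tumor_cell", (0, 0, 0), "Proliferating", None),
                2: ("tumor_cell", (1, 0, 0), "Quiescent", None)}
        cur = {2: ("tumor_cell", (1, 0, 0), "Hypoxic", None),
               3: ("endothelial_cell", (2, 0, 0), "Migrating", 1)}
        msgs = diff_messages(prev, cur)
        assert [m.kind for m in msgs] == ["delete", "update", "create"]
        assert [m.obj_id for m in msgs] == [1, 2, 3]

    def test_identical_scenes_produce_no_messages(self):
        scene = {1: ("tumor_cell", (0, 0, 0), "Proliferating", None)}
        assert diff_messages(scene, dict(scene)) == []
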