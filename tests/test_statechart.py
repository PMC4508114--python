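"""Statechart engine: validation, default entry, dispatch semantics."""

import random

import pytest

from tumorsim.statechart import (
    ChartDef,
    ChartError,
    GuardError,
    StateNode,
    TransitionDef,
    build_chart,
    check_configuration,
    dispatch,
    enter_initial,
    is_in,
    load_chart,
    validate_chart,
)


def make_raw(nodes, root, transitions=()):
    """Unvalidated chart-like object for exercising validate_chart directly."""
    class Raw:
        pass
    r = Raw()
    r.nodes, r.root, r.transitions = nodes, root, tuple(transitions)
    return r


class TestValidation:
    def test_minimal_chart_is_valid(self):
        raw = make_raw({"root": StateNode("root")}, "root")
        assert validate_chart(raw) == []

    def test_compound_without_initial_is_one_violation(self):
        nodes = {
            "root": StateNode("root", "compound", ("A",)),
            "A": StateNode("A", parent="root"),
        }
        violations = validate_chart(make_raw(nodes, "root"))
        assert len(violations) == 1 and "initial" in violations[0] and "root" in violations[0]

    def test_transition_to_unknown_state_is_reported(self):
        nodes = {
            "root": StateNode("root", "compound", ("A",), initial="A"),
            "A": StateNode("A", parent="root"),
        }
        t = TransitionDef("t1", "A", "ZZZ", "e")
        violations = validate_chart(make_raw(nodes, "root", [t]))
        assert len(violations) == 1 and "t1" in violations[0] and "ZZZ" in violations[0]

    @pytest.mark.parametrize("doc, fragment", [
        ({"states": {"id": "root", "kind": "orthogonal",
                     "children": [{"id": "R1", "kind": "compound", "initial": "A",
                                   "children": ["A"]}]}}, "regions"),
        ({"states": {"id": "root", "kind": "basic", "children": ["A"]}}, "children"),
    ])
    def test_bad_structures_rejected_at_build(self, doc, fragment):
        with pytest.raises(ChartError, match=fragment):
            build_chart(doc)

    def test_cross_region_transition_rejected(self, orthogonal_chart):
        doc = {
            "states": {"id": "root", "kind": "orthogonal", "children": [
                {"id": "R1", "kind": "compound", "initial": "A", "children": ["A"]},
                {"id": "R2", "kind": "compound", "initial": "B", "children": ["B"]},
            ]},
            "transitions": [{"id": "tx", "source": "A", "target": "B", "trigger": "e"}],
        }
        with pytest.raises(ChartError, match="orthogonal"):
            build_chart(doc)


class TestEnterInitial:
    def test_compound_default_entry(self, flat_chart):
        inst = enter_initial(flat_chart)
        assert inst.configuration == {"root", "A"}

    def test_orthogonal_enters_all_regions(self, orthogonal_chart):
        inst = enter_initial(orthogonal_chart)
        assert inst.configuration == {"root", "R1", "A", "R2", "C"}

    def test_basic_root(self):
        chart = build_chart({"states": {"id": "root", "kind": "basic"}})
        assert enter_initial(chart).configuration == {"root"}


class TestDispatch:
    def test_single_enabled_transition(self, flat_chart):
        inst = enter_initial(flat_chart)
        inst, actions = dispatch(inst, "e")
        assert inst.configuration == {"root", "B"}
        assert actions == []

    def test_orthogonal_regions_fire_in_parallel(self, orthogonal_chart):
        inst = enter_initial(orthogonal_chart)
        inst, _ = dispatch(inst, "e")
        assert inst.configuration == {"root", "R1", "B", "R2", "D"}

    def test_unknown_event_is_noop(self, flat_chart):
        inst = enter_initial(flat_chart)
        after, actions = dispatch(inst, "nothing")
        assert after.configuration == inst.configuration and actions == []

    def test_is_in(self, flat_chart):
        inst = enter_initial(flat_chart)
        assert is_in(inst, "A") and not is_in(inst, "B") and is_in(inst, "root")
        with pytest.raises(KeyError):
            is_in(inst, "nope")

    def test_guard_controls_enabledness_and_errors(self):
        chart = build_chart({
            "states": {"id": "root", "kind": "compound", "initial": "A",
                       "children": ["A", "B"]},
            "transitions": [{"id": "t1", "source": "A", "target": "B",
                             "trigger": "e", "guard": "go"}],
        }, guards={"go": lambda c: c.get("x", 0) > 1})
        inst = enter_initial(chart)
        same, _ = dispatch(inst, "e", {"x": 0})
        assert same.configuration == {"root", "A"}
        moved, _ = dispatch(inst, "e", {"x": 5})
        assert moved.configuration == {"root", "B"}
        bad = build_chart({
            "states": {"id": "root", "kind": "compound", "initial": "A",
                       "children": ["A", "B"]},
            "transitions": [{"id": "t1", "source": "A", "target": "B",
                             "trigger": "e", "guard": "missing"}],
        })
        with pytest.raises(GuardError, match="t1"):
            dispatch(enter_initial(bad), "e", {})

    def test_inner_transition_preempts_outer(self):
        chart = build_chart({
            "states": {"id": "root", "kind": "compound", "initial": "Outer",
                       "children": [
                           {"id": "Outer", "kind": "compound", "initial": "In",
                            "children": ["In", "In2"]},
                           {"id": "Other"}]},
            "transitions": [
                {"id": "a_outer", "source": "Outer", "target": "Other", "trigger": "e"},
                {"id": "z_inner", "source": "In", "target": "In2", "trigger": "e"},
            ],
        })
        inst, _ = dispatch(enter_initial(chart), "e")
        assert inst.configuration == {"root", "Outer", "In2"}

    def test_equal_depth_tie_breaks_on_lowest_transition_id(self):
        chart = build_chart({
            "states": {"id": "root", "kind": "compound", "initial": "A",
                       "children": ["A", "B", "C"]},
            "transitions": [
                {"id": "t2", "source": "A", "target": "C", "trigger": "e"},
                {"id": "t1", "source": "A", "target": "B", "trigger": "e"},
            ],
        })
        inst, _ = dispatch(enter_initial(chart), "e")
        assert inst.configuration == {"root", "B"}

    def test_entering_compound_target_completes_defaults(self):
        chart = build_chart({
            "states": {"id": "root", "kind": "compound", "initial": "A",
                       "children": ["A",
                                    {"id": "Comp", "kind": "compound", "initial": "X",
                                     "children": ["X", "Y"]}]},
            "transitions": [{"id": "t1", "source": "A", "target": "Comp",
                             "trigger": "e", "actions": ["hello"]}],
        })
        inst, actions = dispatch(enter_initial(chart), "e")
        assert inst.configuration == {"root", "Comp", "X"}
        assert actions == ["hello"]

    def test_determinism_identical_inputs_identical_results(self, orthogonal_chart):
        results = set()
        for _ in range(5):
            inst, acts = dispatch(enter_initial(orthogonal_chart), "e", {"k": 1})
            results.add((frozenset(inst.configuration), tuple(acts)))
        assert len(results) == 1


def _random_flat_chart(rnd: random.Random):
    n = rnd.randint(2, 5)
    names = [f"S{i}" for i in range(n)]
    doc = {"states": {"id": "root", "kind": "compound", "initial": names[0],
                      "children": list(names)},
           "transitions": [
               {"id": f"t{i:02d}", "source": rnd.choice(names),
                "target": rnd.choice(names), "trigger": rnd.choice("abc"),
                "actions": [f"act{i}"]}
               for i in range(rnd.randint(1, 10))]}
    return build_chart(doc), names


def _table_run(names, transitions, seq):
    """Independent oracle: explicit (state, event) -> transition table."""
    table = {}
    for t in sorted(transitions, key=lambda t: t.id):
        table.setdefault((t.source, t.trigger), t)
    state, trace, acts = names[0], [names[0]], []
    for ev in seq:
        t = table.get((state, ev))
        if t is not None:
            state = t.target
            acts.extend(t.actions)
        trace.append(state)
    return trace, acts


class TestOracleEquivalence:
    def test_flat_charts_match_transition_table(self):
        """Trajectories over random flat charts equal the table oracle's."""
        rnd = random.Random(7)
        for _ in range(40):
            chart, names = _random_flat_chart(rnd)
            for _ in range(20):
                seq = [rnd.choice("abc") for _ in range(50)]
                inst = enter_initial(chart)
                trace = [next(s for s in names if s in inst.configuration)]
                acts = []
                for ev in seq:
                    inst, fired = dispatch(inst, ev, {})
                    acts.extend(fired)
                    assert check_configuration(inst) == []
                    trace.append(next(s for s in names if s in inst.configuration))
                assert (trace, acts) == _table_run(names, chart.transitions, seq)

    def test_orthogonal_trace_equals_product_of_regions(self):
        """k independent regions behave as the product of each run alone."""
        rnd = random.Random(11)
        region_docs = []
        all_trans = []
        for r in range(3):
            names = [f"R{r}S{i}" for i in range(3)]
            region_docs.append({"id": f"R{r}", "kind": "compound",
                                "initial": names[0], "children": list(names)})
            for i in range(4):
                all_trans.append({"id": f"r{r}t{i}", "source": rnd.choice(names),
                                  "target": rnd.choice(names), "trigger": rnd.choice("ab")})
        product = build_chart({
            "states": {"id": "root", "kind": "orthogonal", "children": region_docs},
            "transitions": all_trans})
        singles = []
        for r in range(3):
            singles.append(build_chart({
                "states": {"id": "root", "kind": "compound",
                           "initial": region_docs[r]["children"][0],
                           "children": list(region_docs[r]["children"])},
                "transitions": [t for t in all_trans if t["id"].startswith(f"r{r}")]}))
        seq = [rnd.choice("ab") for _ in range(60)]
        inst_p = enter_initial(product)
        inst_s = [enter_initial(c) for c in singles]
        for ev in seq:
            inst_p, _ = dispatch(inst_p, ev)
            inst_s = [dispatch(i, ev)[0] for i in inst_s]
            combined = set().union(*(i.configuration - {"root"} for i in inst_s))
            assert inst_p.configuration - {"root", "R0", "R1", "R2"} == combined


def test_load_chart_yaml_roundtrip(tmp_path):
    p = tmp_path / "chart.yaml"
    p.write_text(
        "states:\n  id: root\n  kind: compound\n  initial: A\n"
        "  children: [A, B]\n"
        "transitions:\n  - {id: t1, source: A, target: B, trigger: go}\n")
    chart = load_chart(str(p))
    inst, _ = dispatch(enter_initial(chart), "go")
    assert inst.configuration == {"root", "B"}
    bad = tmp_path / "bad.yaml"
    bad.write_text("states:\n  id: root\n  kind: compound\n  children: [A]\n")
    with pytest.raises(ChartError):
        load_chart(str(bad))
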