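"""Engine semantics: class definitions, instantiation, series resolution,
per-tick solving and full runs."""

import math

import numpy as np
import pytest

from tcob.engine import (DT, CobInconsistencyError, CobDefinitionError,
                         CobParameterError, CobUnderdeterminedError,
                         ConstraintStore, Constructor, TimeGrid, comp_array,
                         cond, const, define_class, eq, forall, nxt, prev,
                         ref, scalar, series, sum_eq)


def _component():
    return define_class("component", attributes=[series("V"), series("I")])


def _resistor(parent):
    return define_class(
        "resistor", parent=parent,
        attributes=[scalar("R")],
        constraints=[eq(ref("V"), ref("I") * ref("R"))],
        constructor=Constructor(("r",), (eq(ref("R"), ref("r")),)))


class TestDefineClass:
    def test_inheritance_merges_attributes_and_constraints(self):
        comp = _component()
        res = _resistor(comp)
        merged = res.merged_attributes()
        assert set(merged) == {"V", "I", "R"}
        assert len(res.merged_constraints()) == 1

    def test_zero_constraints_is_valid_pure_data(self, tiny_store):
        cls = define_class("bag", attributes=[series("x")])
        inst = tiny_store.instantiate(cls)
        inst.set_initial("x", 1, 3.0)
        tiny_store.run()
        assert inst.value("x", 1) == 3.0

    def test_redeclaring_parent_attribute_is_definition_error(self):
        comp = _component()
        with pytest.raises(CobDefinitionError, match="V"):
            define_class("bad", parent=comp, attributes=[series("V")])

    def test_duplicate_own_attribute_is_definition_error(self):
        with pytest.raises(CobDefinitionError, match="x"):
            define_class("bad", attributes=[scalar("x"), series("x")])

    def test_unknown_symbol_in_constraint_is_definition_error(self):
        with pytest.raises(CobDefinitionError, match="mystery"):
            define_class("bad", attributes=[series("x")],
                         constraints=[eq(ref("x"), ref("mystery"))])

    def test_future_reference_deeper_than_one_tick_rejected(self):
        with pytest.raises(CobDefinitionError, match="future"):
            nxt(nxt(ref("x")))


class TestInstantiate:
    def test_resistor_forward_solve(self, tiny_store):
        res = tiny_store.instantiate(_resistor(_component()), {"r": 5.0},
                                     name="r1")
        for k in range(1, 6):
            res.set_initial("I", k, 2.0)
        tiny_store.run()
        assert res.value("V", 3) == pytest.approx(10.0)
        assert res.scalar("R") == 5.0

    def test_quantified_constraints_expand_per_element(self, tiny_store):
        comp = _component()
        par = define_class(
            "parallel", parent=comp,
            attributes=[comp_array("comps")],
            constraints=[forall("comps", eq(ref("$.V"), ref("V"))),
                         sum_eq("comps", ref("$.I"), ref("I"))])
        a = tiny_store.instantiate(comp, name="a")
        b = tiny_store.instantiate(comp, name="b")
        before = len(tiny_store.simples)
        tiny_store.instantiate(par, {"comps": [a, b]}, name="p")
        # forall -> 2 equality constraints, sum -> 1 aggregate constraint
        assert len(tiny_store.simples) - before == 3

    def test_constructor_arity_mismatch(self, tiny_store):
        with pytest.raises(CobParameterError, match="missing"):
            tiny_store.instantiate(_resistor(_component()), {})

    def test_unsatisfiable_creational_constraint(self, tiny_store):
        bad = define_class("bad", attributes=[scalar("x")],
                           constructor=Constructor((), (eq(const(1), const(2)),)))
        with pytest.raises(CobInconsistencyError):
            tiny_store.instantiate(bad)


class TestResolveSeries:
    def test_past_reference_resolves_initialized_value(self, tiny_store):
        cls = define_class("v", attributes=[series("v", init={1: 5.0})])
        inst = tiny_store.instantiate(cls, name="o")
        assert tiny_store.resolve_series("o.v", -1, 2) == 5.0

    def test_past_reference_before_initializer_errors(self, tiny_store):
        cls = define_class("v", attributes=[series("v")])
        tiny_store.instantiate(cls, name="o")
        with pytest.raises(CobUnderdeterminedError, match="o.v"):
            tiny_store.resolve_series("o.v", -1, 1)

    def test_unsolved_current_tick_is_an_open_unknown(self, tiny_store):
        cls = define_class("v", attributes=[series("v")])
        tiny_store.instantiate(cls, name="o")
        assert tiny_store.resolve_series("o.v", 0, 1) is None


def _controller():
    return define_class(
        "controller",
        attributes=[series("C", init={1: "on"})],
        constraints=[
            cond(ref("C").eq("on"), [eq(nxt(ref("C")), "off")]),
            cond(ref("C").eq("off"), [eq(nxt(ref("C")), "on")]),
        ])


class TestStep:
    def test_on_off_controller_alternates(self):
        store = ConstraintStore(TimeGrid(t_end=3, dt=1.0))
        c = store.instantiate(_controller(), name="ctl")
        store.run()
        assert [c.value("C", k) for k in (1, 2, 3)] == ["on", "off", "on"]

    def test_capacitor_difference_equation_linear_ramp(self):
        # I = Cap * (V - prev V) / dt with constant I gives
        # V(k) = V(1) + (k-1) * dt * I / Cap
        dt, Cap, I = 0.5, 2.0, 4.0
        store = ConstraintStore(TimeGrid(t_end=10, dt=dt))
        cap = define_class(
            "cap", attributes=[scalar("Cap"), series("V", init={1: 0.0}),
                               series("I")],
            constraints=[eq(ref("I"),
                            ref("Cap") * (ref("V") - prev(ref("V"))) / DT)])
        inst = store.instantiate(cap, {"Cap": Cap}, name="c")
        for k in range(1, 11):
            inst.set_initial("I", k, I)
        store.run()
        for k in range(1, 11):
            assert inst.value("V", k) == pytest.approx((k - 1) * dt * I / Cap)

    def test_instantiated_contradiction_is_inconsistency(self, tiny_store):
        bad = define_class("bad", attributes=[series("x")],
                           constraints=[eq(const(0.0), const(1.0))])
        tiny_store.instantiate(bad)
        with pytest.raises(CobInconsistencyError):
            tiny_store.step(1)

    def test_underdetermined_unknowns_fail_loudly(self, tiny_store):
        cls = define_class("uv", attributes=[series("x"), series("y")],
                           constraints=[eq(ref("x") + ref("y"), 3.0)])
        tiny_store.instantiate(cls)
        with pytest.raises(CobUnderdeterminedError):
            tiny_store.step(1)

    def test_solved_values_are_immutable(self, tiny_store):
        cls = define_class("v", attributes=[series("x", init={1: 1.0})])
        inst = tiny_store.instantiate(cls, name="o")
        tiny_store.step(1)
        with pytest.raises(CobInconsistencyError, match="conflicting"):
            tiny_store.set_value("o.x", 1, 2.0)


class TestRun:
    def test_zero_constraint_store_returns_initializers(self):
        store = ConstraintStore(TimeGrid(t_end=10, dt=1.0))
        cls = define_class("d", attributes=[series("x", init={1: 7.0})])
        store.instantiate(cls, name="o")
        table = store.run()
        assert len(table) == 10
        col = table.column("o.x")
        assert col[0] == 7.0
        assert np.isnan(col[1:]).all()

    def test_time_column_scales_ticks_by_dt(self):
        store = ConstraintStore(TimeGrid(t_end=4, dt=0.25))
        table = store.run()
        assert table.time == pytest.approx([0.25, 0.5, 0.75, 1.0])

    def test_declaration_order_independence(self):
        # same coupled constraints in reversed declaration order
        def build(reverse):
            cons = [eq(ref("x"), prev(ref("y")) + 1.0),
                    eq(ref("y"), ref("x") * 0.5),
                    eq(ref("z"), ref("x") + ref("y"))]
            cls = define_class(
                "m", attributes=[series("x"), series("y", init={1: 1.0}),
                                 series("z")],
                constraints=list(reversed(cons)) if reverse else cons)
            store = ConstraintStore(TimeGrid(t_end=20, dt=1.0))
            inst = store.instantiate(cls, name="m")
            store.run()
            return np.array([[inst.value(v, k) for k in range(2, 21)]
                             for v in "xyz"])
        a, b = build(False), build(True)
        assert np.max(np.abs(a - b)) <= 1e-12

    def test_residual_sweep_reports_machine_zero(self):
        store = ConstraintStore(TimeGrid(t_end=5, dt=1.0))
        cls = define_class("m", attributes=[series("x", init={1: 1.0})],
                           constraints=[eq(ref("x"), prev(ref("x")) * 1.1)])
        store.instantiate(cls)
        store.run()
        assert store.residual_sweep() <= 1e-9


class TestTimeGrid:
    def test_rejects_nonpositive_dt(self):
        with pytest.raises(CobParameterError):
            TimeGrid(t_end=10, dt=0.0)

    def test_ticks_start_at_one_by_default(self):
        assert list(TimeGrid(t_end=3, dt=1.0).ticks()) == [1, 2, 3]

    def test_steps_must_be_consecutive(self, tiny_store):
        tiny_store.step(1)
        with pytest.raises(CobParameterError, match="consecutive"):
            tiny_store.step(3)
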