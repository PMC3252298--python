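"""Cable solver: initialization, stepping accuracy, stability, checkpointing."""

import numpy as np
import pytest

from arborsim.binding.types import CommandEvent
from arborsim.fixtures import make_fixture
from arborsim.model.container import ModelContainer
from arborsim.solver.cable import (
    CableSolver,
    CheckpointError,
    IncompleteModelError,
    NumericalDivergence,
    suggest_dt,
)


def _model(kind="passive_soma", **kw):
    mtext, _ = make_fixture(kind, **kw)
    return ModelContainer.from_text(mtext).expand().solvers[0]


def _set_current(solver, amps, comp=0):
    solver.execute_commands(
        [CommandEvent(time=0.0, opcode="set_current", target=(0, comp), payload=amps)]
    )


def _trace(solver, n_steps, comp=0):
    out = np.empty(n_steps + 1)
    out[0] = solver.v[comp]
    for k in range(n_steps):
        solver.advance(1)
        out[k + 1] = solver.v[comp]
    return out


class TestInitialization:
    def test_passive_rest_is_a_fixed_point(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        v0 = solver.v.copy()
        solver.advance(100)
        assert np.max(np.abs(solver.v - v0)) < 1e-12
        assert np.allclose(v0, -0.065)

    def test_rest_is_conserved_over_a_hundred_thousand_steps(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        v0 = solver.v.copy()
        solver.advance(100_000)
        assert np.max(np.abs(solver.v - v0)) < 1e-12

    def test_hh_gates_start_at_their_steady_state(self):
        model = _model("hh_soma")
        solver = CableSolver(model, dt=1e-5)
        comp = model.compartments[0]
        v0 = comp.v_init
        expected = []
        for ch in comp.channels:
            for g in ch.gates:
                a, b = float(g.alpha(v0)), float(g.beta(v0))
                expected.append(a / (a + b))
        assert solver.gates == pytest.approx(expected, rel=1e-9)

    def test_incomplete_model_refused_with_paths(self):
        mtext, _ = make_fixture("ball_and_stick", n=1)
        container = ModelContainer.from_text(mtext)
        container.set_parameter("/cell/dend0", "RA", value=None)
        model = container.expand().solvers[0]
        with pytest.raises(IncompleteModelError) as err:
            CableSolver(model, dt=1e-5)
        assert "/cell/dend0" in str(err.value) and "RA" in str(err.value)

    def test_nonpositive_dt_refused(self):
        with pytest.raises(ValueError):
            CableSolver(_model(), dt=0.0)

    def test_suggested_dt_is_a_fraction_of_tau(self):
        model = _model()
        comp = model.compartments[0]
        assert suggest_dt(model) == pytest.approx(0.01 * comp.cm / comp.g_leak)


class TestAccuracy:
    def test_step_current_matches_charging_curve(self):
        model = _model()
        comp = model.compartments[0]
        tau = comp.cm / comp.g_leak
        solver = CableSolver(model, dt=tau / 1000)
        i0 = 0.1e-9
        _set_current(solver, i0)
        v = _trace(solver, 5000)
        t = np.arange(5001) * (tau / 1000)
        rm = 1.0 / comp.g_leak
        exact = comp.e_leak + i0 * rm * (1 - np.exp(-t / tau))
        assert np.max(np.abs(v - exact)) / (i0 * rm) < 1e-4

    def test_halving_dt_quarters_the_error(self):
        model = _model()
        comp = model.compartments[0]
        tau = comp.cm / comp.g_leak
        rm = 1.0 / comp.g_leak
        i0 = 0.1e-9
        errs = []
        for divisions in (100, 200, 400):
            solver = CableSolver(model, dt=tau / divisions)
            _set_current(solver, i0)
            n = 2 * divisions
            v = _trace(solver, n)
            t = np.arange(n + 1) * (tau / divisions)
            exact = comp.e_leak + i0 * rm * (1 - np.exp(-t / tau))
            errs.append(np.max(np.abs(v - exact)))
        for coarse, fine in zip(errs, errs[1:]):
            assert 3.2 < coarse / fine < 4.8

    def test_unconditionally_stable_at_ten_tau(self):
        model = _model()
        comp = model.compartments[0]
        tau = comp.cm / comp.g_leak
        solver = CableSolver(model, dt=10 * tau)
        _set_current(solver, 0.1e-9)
        v = _trace(solver, 200)
        assert np.all(np.isfinite(v))
        assert np.max(np.abs(v)) < 1.0  # stays physically bounded

    def test_gates_remain_in_unit_interval_during_spiking(self):
        model = _model("hh_soma")
        solver = CableSolver(model, dt=1e-5)
        _set_current(solver, 0.5e-9)
        for _ in range(50):
            solver.advance(40)
            assert np.all(solver.gates >= 0.0) and np.all(solver.gates <= 1.0)

    def test_divergence_raises_with_step_index(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        _set_current(solver, 1e300)
        with pytest.raises(NumericalDivergence) as err:
            solver.advance(1000)
        assert err.value.step >= 1


class TestCommands:
    def test_current_applies_to_the_upcoming_step(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        v_rest = solver.v[0]
        solver.advance(1)
        assert solver.v[0] == v_rest  # no stimulus yet
        _set_current(solver, 0.1e-9)
        solver.advance(1)
        assert solver.v[0] > v_rest  # depolarization begins this step

    def test_off_event_zeroes_injected_current(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        _set_current(solver, 0.1e-9)
        assert solver.i_inj[0] == 0.1e-9
        _set_current(solver, 0.0)
        assert solver.i_inj[0] == 0.0

    def test_same_time_events_later_declaration_wins(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        solver.execute_commands([
            CommandEvent(time=0.0, opcode="set_current", target=(0, 0), payload=1e-10, seq=0),
            CommandEvent(time=0.0, opcode="set_current", target=(0, 0), payload=2e-10, seq=1),
        ])
        assert solver.i_inj[0] == 2e-10

    def test_voltage_clamp_pins_the_membrane(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        v_cmd = -0.040
        solver.execute_commands([
            CommandEvent(time=0.0, opcode="set_clamp", target=(0, 0),
                         payload=v_cmd, gain=1e-5)
        ])
        solver.advance(2000)
        assert solver.v[0] == pytest.approx(v_cmd, abs=1e-5)
        solver.execute_commands([
            CommandEvent(time=0.0, opcode="stop_clamp", target=(0, 0))
        ])
        solver.advance(5000)
        assert solver.v[0] == pytest.approx(model.compartments[0].e_leak, abs=1e-4)


class TestCheckpoint:
    def test_restore_then_advance_is_bitwise_identical(self):
        model = _model("hh_soma")
        solver = CableSolver(model, dt=1e-5)
        _set_current(solver, 0.3e-9)
        solver.advance(100)
        blob = solver.checkpoint()
        twin = CableSolver.restore(blob, model)
        solver.advance(100)
        twin.advance(100)
        assert np.array_equal(solver.v, twin.v)
        assert np.array_equal(solver.gates, twin.gates)
        assert solver.step_count == twin.step_count == 200

    def test_checkpoint_preserves_mid_pulse_current(self):
        model = _model()
        solver = CableSolver(model, dt=1e-4)
        _set_current(solver, 0.2e-9)
        solver.advance(7)
        twin = CableSolver.restore(solver.checkpoint(), model)
        assert twin.i_inj[0] == 0.2e-9
        assert twin.step_count == 7
        assert np.array_equal(twin.v, solver.v)

    def test_restore_against_different_binding_fails(self):
        blob = CableSolver(_model(), dt=1e-4).checkpoint()
        other = _model("ball_and_stick", n=3)
        with pytest.raises(CheckpointError):
            CableSolver(other, dt=1e-4).load_checkpoint(blob)

    def test_table_dedup_does_not_change_results(self):
        model = _model("hh_soma")
        from arborsim.solver.tables import TableRegistry

        shared = CableSolver(model, dt=1e-5, registry=TableRegistry(), share_tables=True)
        private = CableSolver(model, dt=1e-5, share_tables=False)
        for s in (shared, private):
            _set_current(s, 0.3e-9)
            s.advance(2000)
        assert np.array_equal(shared.v, private.v)
        assert np.array_equal(shared.gates, private.gates)

    def test_reset_restores_post_init_state(self):
        model = _model("hh_soma")
        solver = CableSolver(model, dt=1e-5)
        v0, g0 = solver.v.copy(), solver.gates.copy()
        _set_current(solver, 0.3e-9)
        solver.advance(500)
        solver.reset()
        assert np.array_equal(solver.v, v0)
        assert np.array_equal(solver.gates, g0)
        assert solver.i_inj[0] == 0.0
        assert solver.step_count == 0
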