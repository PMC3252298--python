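"""Controller and serial communication infrastructure.

The controller owns the global clock and the ordered registry of back-ends and
drives the simulation loop.  Within each step the order is fixed and is part
of the reproducibility contract:

1. command executors apply events due at the current clock time,
2. the spike queue delivers events that have matured,
3. every solver advances one step, in registry order,
4. threshold crossings detected on the just-updated voltages are enqueued,
5. outputs are sampled.

The initial state is sampled once before the first update, so a run of N
steps yields N/stride + 1 samples.  Spike detection is a strictly upward
crossing (V_prev < theta <= V_now), one event per crossing; a crossing
detected at step k with delay d is delivered before the update of step
k + ceil(d/dt), so its effect on the target begins exactly one delay later.

The controller touches back-ends only through their numerical interface
(advance / execute_commands / deliver_spike / state_value); it knows nothing
of the biological model.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Clock", "SpikeEventQueue", "OutputBuffer", "Controller"]

_TIME_EPS_REL = 1e-9


@dataclass
class Clock:
    """Simulation time; integer step counting is authoritative."""

    dt: float
    step: int = 0

    @property
    def t(self) -> float:
        return self.step * self.dt

    def steps_until(self, t_end: float) -> int:
        return max(0, math.ceil(t_end / self.dt - _TIME_EPS_REL))


class SpikeEventQueue:
    """Pending (delivery step, target solver, target port, weight) events."""

    def __init__(self) -> None:
        self._heap: list[tuple[int, int, int, int, float]] = []
        self._seq = 0
        self.n_enqueued = 0
        self.n_delivered = 0

    def push(self, deliver_step: int, solver: int, comp: int, weight: float) -> None:
        heapq.heappush(self._heap, (deliver_step, self._seq, solver, comp, weight))
        self._seq += 1
        self.n_enqueued += 1

    def pop_due(self, step: int) -> list[tuple[int, int, float]]:
        out = []
        while self._heap and self._heap[0][0] <= step:
            _, _, solver, comp, weight = heapq.heappop(self._heap)
            out.append((solver, comp, weight))
            self.n_delivered += 1
        return out

    def clear(self) -> None:
        self._heap.clear()
        self._seq = 0
        self.n_enqueued = 0
        self.n_delivered = 0

    def __len__(self) -> int:
        return len(self._heap)


@dataclass
class OutputBuffer:
    """Sampled time series of one solver state variable."""

    label: str
    solver_id: int
    var_index: int
    stride: int = 1
    times: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.values)


@dataclass(frozen=True)
class _WireRuntime:
    pre_solver: int
    pre_comp: int
    threshold: float
    post_solver: int
    post_comp: int
    weight: float
    delay_steps: int


class Controller:
    """Global clock, back-end registry, spike routing and output sampling."""

    def __init__(self, dt: float):
        self.clock = Clock(dt=dt)
        self.solvers: list = []  # ordered registry of numerical back-ends
        self.executors: list = []
        self.queue = SpikeEventQueue()
        self.wires: list[_WireRuntime] = []
        self.outputs: list[OutputBuffer] = []
        self._stop_requested = False
        self._initial_sampled = False
        self._prev_pre_v: dict[tuple[int, int], float] = {}

    # -- registry -------------------------------------------------------------
    def register_solver(self, solver) -> int:
        if any(s is solver for s in self.solvers):
            raise ValueError("back-end already registered")
        if abs(solver.dt - self.clock.dt) > _TIME_EPS_REL * self.clock.dt:
            raise ValueError("solver dt differs from controller dt")
        self.solvers.append(solver)
        return len(self.solvers) - 1

    def register_executor(self, executor) -> None:
        if any(e is executor for e in self.executors):
            raise ValueError("executor already registered")
        self.executors.append(executor)

    def connect_spike(
        self,
        source: tuple[int, int, float],
        target: tuple[int, int],
        weight: float,
        delay: float,
        tau: float = 2e-3,
        esyn: float = 0.0,
    ) -> None:
        """Wire a spike source (solver, compartment, threshold) to a synaptic
        target port.  ``delay`` must be at least one step; delivery honors it
        exactly on the step grid."""
        dt = self.clock.dt
        if delay < dt * (1.0 - _TIME_EPS_REL):
            raise ValueError(f"spike delay {delay} is below one time step {dt}")
        pre_solver, pre_comp, threshold = source
        post_solver, post_comp = target
        self.solvers[post_solver].configure_synapse(post_comp, tau, esyn)
        wire = _WireRuntime(
            pre_solver=pre_solver,
            pre_comp=pre_comp,
            threshold=threshold,
            post_solver=post_solver,
            post_comp=post_comp,
            weight=weight,
            delay_steps=max(1, math.ceil(delay / dt - _TIME_EPS_REL)),
        )
        self.wires.append(wire)
        self._prev_pre_v[(pre_solver, pre_comp)] = self.solvers[pre_solver].state_value(pre_comp)

    def add_output(self, label: str, solver_id: int, var_index: int, stride: int = 1) -> OutputBuffer:
        buf = OutputBuffer(label=label, solver_id=solver_id, var_index=var_index, stride=stride)
        self.outputs.append(buf)
        return buf

    # -- stepping ---------------------------------------------------------------
    def _sample(self) -> None:
        step = self.clock.step
        t = self.clock.t
        for buf in self.outputs:
            if step % buf.stride == 0:
                buf.times.append(t)
                buf.values.append(self.solvers[buf.solver_id].state_value(buf.var_index))

    def step(self) -> None:
        """Advance the whole federation by one dt (the documented order)."""
        k = self.clock.step
        for ex in self.executors:
            for event in ex.due(k):
                self.solvers[event.target[0]].execute_commands([event])
        for solver_id, comp, weight in self.queue.pop_due(k):
            self.solvers[solver_id].deliver_spike(comp, weight)
        try:
            for solver in self.solvers:
                solver.advance(1)
        except ArithmeticError as exc:
            raise type(exc)(f"at global step {k}: {exc}") from exc
        for wire in self.wires:
            key = (wire.pre_solver, wire.pre_comp)
            v_now = self.solvers[wire.pre_solver].state_value(wire.pre_comp)
            v_prev = self._prev_pre_v[key]
            if v_prev < wire.threshold <= v_now:
                self.queue.push(k + wire.delay_steps, wire.post_solver,
                                wire.post_comp, wire.weight)
        for key in self._prev_pre_v:
            self._prev_pre_v[key] = self.solvers[key[0]].state_value(key[1])
        self.clock.step += 1
        self._sample()

    def run(self, t_end: float, callback=None) -> int:
        """Run until the clock reaches ``t_end``; returns steps executed.

        ``stop()`` is honored at step boundaries; ``callback(controller)``,
        when given, runs after every step (e.g. checkpoint hooks, or a stop
        condition)."""
        if t_end <= 0:
            raise ValueError("t_end must be > 0")
        if not self._initial_sampled:
            self._sample()
            self._initial_sampled = True
        target = self.clock.steps_until(t_end)
        executed = 0
        self._stop_requested = False
        while self.clock.step < target and not self._stop_requested:
            self.step()
            executed += 1
            if callback is not None:
                callback(self)
        return executed

    def stop(self) -> None:
        self._stop_requested = True

    # -- resume support -----------------------------------------------------------
    def queue_dump(self) -> list:
        """Pending spike events as JSON-serializable tuples."""
        return sorted(self.queue._heap)

    def queue_load(self, entries: list) -> None:
        self.queue.clear()
        for deliver_step, _seq, solver, comp, weight in entries:
            self.queue.push(int(deliver_step), int(solver), int(comp), float(weight))

    def mark_resumed(self) -> None:
        """Skip the t=0 sample and refresh crossing detectors after a restore."""
        self._initial_sampled = True
        for key in self._prev_pre_v:
            self._prev_pre_v[key] = self.solvers[key[0]].state_value(key[1])

    def reset(self) -> None:
        """Restore every back-end to its post-initialization state."""
        for solver in self.solvers:
            solver.reset()
        for ex in self.executors:
            ex.rewind()
        self.queue.clear()
        self.clock.step = 0
        for buf in self.outputs:
            buf.times.clear()
            buf.values.clear()
        self._initial_sampled = False
        for key in self._prev_pre_v:
            self._prev_pre_v[key] = self.solvers[key[0]].state_value(key[1])
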