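"""Command Sequence Executor: replays time-sorted events during a run.

The executor is a back-end like any solver: the controller asks it, once per
step, for the events due at the current simulation time.  Events stamped at
time t are due at the first step whose clock reads >= t (i.e. they are applied
before the update that advances t -> t+dt), so a pulse of duration W spans
exactly ceil(W/dt) steps.
"""

from __future__ import annotations

import math

from ..binding.types import CommandEvent

__all__ = ["CommandSequenceExecutor"]

_TIME_EPS_REL = 1e-9


class CommandSequenceExecutor:
    def __init__(self, events: list[CommandEvent], dt: float):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = dt
        self.events = sorted(events, key=lambda e: (e.time, e.seq))
        # precompute due-step per event: first step with step*dt >= time,
        # with a relative tolerance so grid-aligned times do not round up
        self._due_step = [
            max(0, math.ceil(e.time / dt - _TIME_EPS_REL)) for e in self.events
        ]
        self._cursor = 0

    def due(self, step: int) -> list[CommandEvent]:
        """Events to apply before the update of ``step`` (consumed in order)."""
        out = []
        while self._cursor < len(self.events) and self._due_step[self._cursor] <= step:
            out.append(self.events[self._cursor])
            self._cursor += 1
        return out

    def rewind(self) -> None:
        self._cursor = 0

    def seek(self, step: int) -> None:
        """Position the cursor as if steps < ``step`` had already consumed
        their events (used when resuming from a checkpoint)."""
        self._cursor = 0
        while self._cursor < len(self.events) and self._due_step[self._cursor] < step:
            self._cursor += 1

    @property
    def exhausted(self) -> bool:
        return self._cursor >= len(self.events)
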