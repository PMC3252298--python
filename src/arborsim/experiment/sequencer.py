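"""The sequencer bridge: protocols -> time-sorted command events.

Events are resolved to (solver, compartment) coordinates through a resolver
callable (the model container's ``resolve_identifier``), stably sorted by
(time, declaration order), and handed to the Command Sequence Executor.
Events stamped at time t are applied before the solver step that advances
t -> t+dt, so a pulse of duration W spans exactly ceil(W/dt) steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from ..binding.types import CommandEvent
from .protocols import Experiment, PulseProtocol, VClampProtocol

__all__ = ["sequence_events", "validate_experiment", "ExperimentReport"]

Resolver = Callable[[str, str], tuple[int, int]]


@dataclass
class ExperimentReport:
    """Validation outcome: failures as (path, reason) pairs."""

    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.failures


def sequence_events(protocols, t_end: float, resolve: Resolver) -> list[CommandEvent]:
    """Unroll protocols into a sorted CommandEvent list up to ``t_end``.

    A pulse (delay D, duration W, amplitude A) becomes (D, set_current, A) and
    (D+W, set_current, 0); repeats are unrolled while their onset lies before
    t_end.  Clamp levels become set_clamp events carrying the clamp gain.
    Ties at equal times keep declaration order (stable sort on sequence
    number), and the executor applies later declarations last, so they win.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    events: list[CommandEvent] = []
    seq = 0
    for proto in protocols:
        if isinstance(proto, PulseProtocol):
            target = resolve(proto.target, "Vm")
            onset = proto.delay
            while onset < t_end:
                events.append(CommandEvent(time=onset, opcode="set_current",
                                           target=target, payload=proto.amplitude, seq=seq))
                seq += 1
                events.append(CommandEvent(time=onset + proto.duration,
                                           opcode="set_current", target=target,
                                           payload=0.0, seq=seq))
                seq += 1
                if proto.repeat_interval is None:
                    break
                onset += proto.repeat_interval
        elif isinstance(proto, VClampProtocol):
            target = resolve(proto.target, "Vm")
            for start, v_cmd in proto.levels:
                if start >= t_end:
                    break
                events.append(CommandEvent(time=start, opcode="set_clamp", target=target,
                                           payload=v_cmd, gain=proto.gain, seq=seq))
                seq += 1
        else:
            raise TypeError(f"unknown protocol type {type(proto).__name__}")
    events.sort(key=lambda e: (e.time, e.seq))
    return events


def validate_experiment(experiment: Experiment, resolve: Resolver) -> ExperimentReport:
    """Check that every protocol target and output variable resolves."""
    report = ExperimentReport()
    for i, proto in enumerate(experiment.protocols):
        try:
            resolve(proto.target, "Vm")
        except KeyError:
            report.failures.append((f"/protocols[{i}]", f"target {proto.target!r} does not resolve"))
    for i, out in enumerate(experiment.outputs):
        try:
            resolve(out.path, out.variable)
        except KeyError:
            report.failures.append(
                (f"/outputs[{i}]", f"variable {out.variable!r} at {out.path!r} does not resolve")
            )
    return report
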