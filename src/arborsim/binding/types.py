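"""Binding-layer data structures: the flat numerical face of a model.

These types are the only currency exchanged between the biological layer and
the numerical back-ends.  They carry plain numbers (SI) plus provenance paths;
no solver algorithms and no biological semantics beyond identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..kinetics import RateLaw

__all__ = [
    "GateBinding",
    "ChannelInstance",
    "Compartment",
    "MathematicalModel",
    "Wire",
    "CommandEvent",
    "NetworkBinding",
]


@dataclass(frozen=True)
class GateBinding:
    """One gate instance: rate laws + exponent, ready for tabulation."""

    name: str
    power: int
    alpha: RateLaw
    beta: RateLaw

    def table_key(self) -> tuple:
        return (self.alpha.key(), self.beta.key())


@dataclass(frozen=True)
class ChannelInstance:
    """A channel population on one compartment, scaled to absolute conductance."""

    name: str
    gmax: float  # S (density * cylinder area, spines excluded)
    erev: float  # V
    gates: tuple[GateBinding, ...]


@dataclass
class Compartment:
    """One numerical compartment in Hines (leaf-to-root) order.

    ``ra`` is the axial resistance between this compartment and its parent
    (None for the root).  ``parent_index`` always exceeds ``index`` in the
    ordering produced by :func:`arborsim.binding.discretize.linearize`, which
    makes ascending-index elimination fill-in free.
    """

    index: int
    parent_index: int | None
    cm: float  # F
    ra: float | None  # ohm
    g_leak: float  # S
    e_leak: float  # V
    v_init: float  # V
    area: float  # m^2, cylinder lateral area (no spines)
    source_path: str  # biological provenance, e.g. "/cell/dend.2"
    channels: tuple[ChannelInstance, ...] = ()


@dataclass
class MathematicalModel:
    """The expanded representation of one cell instance, for one solver.

    The solver state vector is laid out as the ``n`` compartment voltages
    followed by every gate variable in (compartment, channel, gate) order;
    ``state_layout`` names each entry as ``(source_path, variable)``.
    """

    origin: str  # instance path, e.g. "/cell" or "/pop/3"
    compartments: list[Compartment]
    complete: bool = True
    missing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def state_layout(self) -> list[tuple[str, str]]:
        layout = [(c.source_path, "Vm") for c in self.compartments]
        for c in self.compartments:
            for ch in c.channels:
                for g in ch.gates:
                    layout.append((c.source_path, f"{ch.name}.{g.name}"))
        return layout

    def structure_fingerprint(self) -> str:
        import hashlib

        parts = []
        for c in self.compartments:
            parts.append((c.index, c.parent_index, c.source_path,
                          tuple((ch.name, len(ch.gates)) for ch in c.channels)))
        blob = repr((self.origin, parts)).encode()
        return hashlib.sha1(blob).hexdigest()


@dataclass(frozen=True)
class Wire:
    """One translated connection between two solver endpoints.

    Spike side: an upward crossing of ``threshold`` at compartment
    ``pre_comp`` of solver ``pre_solver`` emits an event delivered, after
    ``delay`` seconds, to the synaptic port at compartment ``post_comp`` of
    solver ``post_solver``, incrementing its conductance by ``weight``.
    """

    pre_solver: int
    pre_comp: int
    threshold: float  # V
    post_solver: int
    post_comp: int
    weight: float  # S
    delay: float  # s
    tau: float  # s, synaptic decay time constant
    esyn: float  # V, synaptic reversal


@dataclass(frozen=True)
class CommandEvent:
    """A time-stamped command for the Command Sequence Executor.

    ``target`` is a (solver id, compartment index) pair; ``payload`` the
    numeric argument (amperes for set_current, volts for set_clamp).  ``gain``
    accompanies set_clamp (clamp conductance, siemens).  ``seq`` preserves
    declaration order for stable tie-breaking at equal times.
    """

    time: float
    opcode: str  # set_current | set_clamp | stop_clamp
    target: tuple[int, int]
    payload: float = 0.0
    gain: float | None = None
    seq: int = 0


@dataclass
class NetworkBinding:
    """Everything the run-time needs: one MathematicalModel per cell instance
    plus the translated wiring between them."""

    solvers: list[MathematicalModel]
    wiring: list[Wire] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return all(m.complete for m in self.solvers)

    @property
    def missing(self) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for m in self.solvers:
            out.extend(m.missing)
        return out
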