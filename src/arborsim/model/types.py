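"""Biological domain types: the in-memory tree representation of a model.

These dataclasses form the "biology" quadrant: hierarchical cells made of
segments carrying passive membrane parameters and channel populations, plus
network populations and projections.  All quantities are SI.  Numeric membrane
parameters are optional so that partially specified models remain loadable and
inspectable; :meth:`arborsim.model.container.ModelContainer.check_completeness`
reports what is missing before simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..kinetics import RateLaw

__all__ = [
    "ModelValidationError",
    "GateSpec",
    "ChannelSpec",
    "ChannelPlacement",
    "SegmentSpec",
    "CellModel",
    "PopulationSpec",
    "ProjectionSpec",
    "AlgorithmRef",
    "ConceptualModel",
    "CompletenessReport",
]

#: segment parameters a compartmental solver cannot do without
REQUIRED_SEGMENT_PARAMS = ("length", "diameter", "RA", "RM", "CM", "Em")


class ModelValidationError(ValueError):
    """An invariant violation, carrying the path of the offending element."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass
class GateSpec:
    """One Hodgkin-Huxley gate: x' = alpha(V)(1-x) - beta(V)x, raised to ``power``."""

    name: str
    power: int
    alpha: RateLaw
    beta: RateLaw

    def validate(self, path: str) -> None:
        if not isinstance(self.power, int) or self.power < 0:
            raise ModelValidationError(path, "gate power must be a non-negative integer")


@dataclass
class ChannelSpec:
    """A channel type: a named product of gates."""

    name: str
    gates: list[GateSpec]

    def validate(self, path: str) -> None:
        if not self.gates:
            raise ModelValidationError(path, "channel must declare at least one gate")
        seen: set[str] = set()
        for g in self.gates:
            if g.name in seen:
                raise ModelValidationError(path, f"duplicate gate name {g.name!r}")
            seen.add(g.name)
            g.validate(f"{path}/{g.name}")


@dataclass
class ChannelPlacement:
    """A channel population on a segment: density (S/m^2) and reversal (V)."""

    channel: str
    density: float
    erev: float

    def validate(self, path: str) -> None:
        if self.density < 0:
            raise ModelValidationError(path, "channel density must be >= 0")


@dataclass
class SegmentSpec:
    """A cylindrical piece of membrane in the biological tree.

    ``spine_area`` is the extra membrane area contributed by dendritic spines,
    modeled as an additive area (not per-spine geometry).  ``vinit`` is the
    initial membrane potential; defaults to the leak reversal ``em``.
    """

    name: str
    parent: str | None = None
    length: float | None = None  # m
    diameter: float | None = None  # m
    ra: float | None = None  # ohm*m axial resistivity
    rm: float | None = None  # ohm*m^2 specific membrane resistance
    cm: float | None = None  # F/m^2 specific membrane capacitance
    em: float | None = None  # V leak reversal
    vinit: float | None = None  # V initial potential (default: em)
    spine_area: float = 0.0  # m^2
    channels: list[ChannelPlacement] = field(default_factory=list)

    def validate(self, path: str) -> None:
        if self.length is not None and self.length <= 0:
            raise ModelValidationError(path, "length must be > 0")
        if self.diameter is not None and self.diameter <= 0:
            raise ModelValidationError(path, "diameter must be > 0")
        if self.spine_area < 0:
            raise ModelValidationError(path, "spine_area must be >= 0")
        for pl in self.channels:
            pl.validate(f"{path}/channels/{pl.channel}")

    def missing_parameters(self) -> list[str]:
        attr = {"length": self.length, "diameter": self.diameter, "RA": self.ra,
                "RM": self.rm, "CM": self.cm, "Em": self.em}
        return [name for name in REQUIRED_SEGMENT_PARAMS if attr[name] is None]


@dataclass
class CellModel:
    """A cell: a tree of segments with a single root."""

    name: str
    segments: list[SegmentSpec]

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def children_of(self, name: str | None) -> list[SegmentSpec]:
        return [s for s in self.segments if s.parent == name]

    def root(self) -> SegmentSpec:
        roots = self.children_of(None)
        if len(roots) != 1:  # validate() enforces this; defensive
            raise ModelValidationError(f"/{self.name}", "cell must have exactly one root")
        return roots[0]

    def validate(self, path: str) -> None:
        if not self.segments:
            raise ModelValidationError(path, "cell has no segments")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelValidationError(path, "segment names must be unique within a cell")
        known = set(names)
        roots = 0
        for s in self.segments:
            spath = f"{path}/{s.name}"
            if s.parent is None:
                roots += 1
            elif s.parent not in known:
                raise ModelValidationError(spath, f"parent {s.parent!r} is not a declared segment")
            s.validate(spath)
        if roots != 1:
            raise ModelValidationError(path, f"cell must have exactly one root segment, found {roots}")
        # cycle check by walking to root from every segment
        parent = {s.name: s.parent for s in self.segments}
        for s in self.segments:
            seen = set()
            cur: str | None = s.name
            while cur is not None:
                if cur in seen:
                    raise ModelValidationError(f"{path}/{s.name}", "segment parent chain forms a cycle")
                seen.add(cur)
                cur = parent[cur]


@dataclass
class PopulationSpec:
    name: str
    cell: str  # cell template identifier
    count: int

    def validate(self, path: str) -> None:
        if self.count < 1:
            raise ModelValidationError(path, "population count must be >= 1")


@dataclass
class ProjectionSpec:
    """Connectivity between two populations.

    ``rule`` is ``("all_to_all",)`` or ``("probabilistic", p, seed)``.
    ``pre`` names the spike-source segment within the source cell, ``post`` the
    synaptic target segment within the target cell.  The synapse delivered at
    the target is a single-exponential conductance (time constant ``tau``,
    reversal ``esyn``); a presynaptic spike is an upward crossing of
    ``threshold`` at the source compartment.
    """

    name: str
    source: str
    target: str
    rule: tuple
    weight: float  # S, conductance increment per delivered spike
    delay: float  # s
    pre: str = ""  # source segment name ("" = root)
    post: str = ""  # target segment name ("" = root)
    threshold: float = 0.0  # V
    tau: float = 2e-3  # s
    esyn: float = 0.0  # V
    self_connections: bool = True

    def validate(self, path: str) -> None:
        kind = self.rule[0]
        if kind == "probabilistic":
            p = self.rule[1]
            if not 0.0 <= p <= 1.0:
                raise ModelValidationError(path, "connection probability must be in [0, 1]")
        elif kind != "all_to_all":
            raise ModelValidationError(path, f"unknown connection rule {kind!r}")
        if self.delay < 0:
            raise ModelValidationError(path, "delay must be >= 0")
        if self.tau <= 0:
            raise ModelValidationError(path, "synaptic tau must be > 0")


@dataclass
class AlgorithmRef:
    """Reference to an expansion-time algorithm plus its parameters."""

    name: str
    params: dict[str, float] = field(default_factory=dict)


@dataclass
class ConceptualModel:
    """The full enumerated model: concepts, relationships, algorithm refs."""

    name: str = "model"
    channels: dict[str, ChannelSpec] = field(default_factory=dict)
    cells: dict[str, CellModel] = field(default_factory=dict)
    populations: list[PopulationSpec] = field(default_factory=list)
    projections: list[ProjectionSpec] = field(default_factory=list)
    algorithms: list[AlgorithmRef] = field(default_factory=list)

    def validate(self) -> None:
        for cname, ch in self.channels.items():
            ch.validate(f"/channels/{cname}")
        for cell in self.cells.values():
            cell.validate(f"/{cell.name}")
            for seg in cell.segments:
                for pl in seg.channels:
                    if pl.channel not in self.channels:
                        raise ModelValidationError(
                            f"/{cell.name}/{seg.name}",
                            f"channel {pl.channel!r} is not declared",
                        )
        popnames = set()
        for pop in self.populations:
            ppath = f"/populations/{pop.name}"
            pop.validate(ppath)
            if pop.name in popnames:
                raise ModelValidationError(ppath, "duplicate population name")
            popnames.add(pop.name)
            if pop.cell not in self.cells:
                raise ModelValidationError(ppath, f"cell template {pop.cell!r} is not declared")
        for proj in self.projections:
            jpath = f"/projections/{proj.name}"
            proj.validate(jpath)
            for endpoint in (proj.source, proj.target):
                if endpoint not in popnames:
                    raise ModelValidationError(jpath, f"population {endpoint!r} is not declared")


@dataclass
class CompletenessReport:
    """Which (path, parameter) pairs required for simulation are absent."""

    missing: list[tuple[str, str]]

    @property
    def complete(self) -> bool:
        return not self.missing
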