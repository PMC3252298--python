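"""Experiment container types and their document dialect.

An experiment is independent of any particular model: it names biological
targets by path, and can be combined with any model on which those targets
resolve.  The document dialect mirrors the model dialect (versioned YAML,
optional units block, unknown keys rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ..units import UnitContext

__all__ = [
    "ExperimentError",
    "PulseProtocol",
    "VClampProtocol",
    "OutputSpec",
    "Experiment",
    "load_experiment",
    "save_experiment",
]

DOCUMENT_VERSION = 1


class ExperimentError(ValueError):
    pass


@dataclass
class PulseProtocol:
    """Square current pulse: amplitude from delay to delay+duration, optionally
    repeating every ``repeat_interval`` seconds."""

    target: str  # biological path, e.g. "/cell/soma"
    delay: float  # s
    duration: float  # s
    amplitude: float  # A
    repeat_interval: float | None = None

    def validate(self, path: str) -> None:
        if self.delay < 0:
            raise ExperimentError(f"{path}: delay must be >= 0")
        if self.duration <= 0:
            raise ExperimentError(f"{path}: duration must be > 0")
        if self.repeat_interval is not None and self.repeat_interval <= self.duration:
            raise ExperimentError(f"{path}: repeat_interval must exceed duration")


@dataclass
class VClampProtocol:
    """Voltage clamp: a staircase of command levels, realized as a high-gain
    current source I = gain * (V_cmd - Vm) at the target."""

    target: str
    levels: list[tuple[float, float]]  # (start s, command V), starts increasing
    gain: float  # S

    def validate(self, path: str) -> None:
        if self.gain <= 0:
            raise ExperimentError(f"{path}: clamp gain must be > 0")
        starts = [t for t, _v in self.levels]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ExperimentError(f"{path}: level start times must be strictly increasing")
        if any(t < 0 for t in starts):
            raise ExperimentError(f"{path}: level start times must be >= 0")


@dataclass
class OutputSpec:
    """One recorded variable: (path, name) sampled every ``stride`` steps."""

    path: str
    variable: str = "Vm"
    destination: str = "out"
    stride: int = 1

    def validate(self, path: str) -> None:
        if self.stride < 1:
            raise ExperimentError(f"{path}: stride must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.path}:{self.variable}"


@dataclass
class Experiment:
    name: str = "experiment"
    protocols: list = field(default_factory=list)  # Pulse/VClamp in declaration order
    outputs: list[OutputSpec] = field(default_factory=list)

    def validate(self) -> None:
        for i, p in enumerate(self.protocols):
            p.validate(f"/protocols[{i}]")
        for i, o in enumerate(self.outputs):
            o.validate(f"/outputs[{i}]")


def _check_keys(node: dict, allowed: set[str], path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ExperimentError(f"{path}: unknown key(s): {', '.join(sorted(map(str, unknown)))}")


def load_experiment(text: str) -> Experiment:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ExperimentError(f"document does not parse as YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ExperimentError("/: expected a mapping")
    _check_keys(doc, {"version", "name", "units", "protocols", "outputs"}, "/")
    if doc.get("version") != DOCUMENT_VERSION:
        raise ExperimentError(f"/version: unsupported document version {doc.get('version')!r}")
    units = UnitContext(doc.get("units") or None)
    exp = Experiment(name=str(doc.get("name", "experiment")))
    for i, node in enumerate(doc.get("protocols") or []):
        path = f"/protocols[{i}]"
        if not isinstance(node, dict):
            raise ExperimentError(f"{path}: expected a mapping")
        kind = node.get("kind")
        if kind == "pulse":
            _check_keys(node, {"kind", "target", "delay", "duration", "amplitude",
                               "repeat_interval"}, path)
            exp.protocols.append(
                PulseProtocol(
                    target=str(node["target"]),
                    delay=units.convert(node["delay"], "time"),
                    duration=units.convert(node["duration"], "time"),
                    amplitude=units.convert(node["amplitude"], "current"),
                    repeat_interval=units.convert(node.get("repeat_interval"), "time"),
                )
            )
        elif kind == "vclamp":
            _check_keys(node, {"kind", "target", "gain", "levels"}, path)
            levels = [
                (units.convert(lv["start"], "time"), units.convert(lv["voltage"], "voltage"))
                for lv in node["levels"]
            ]
            exp.protocols.append(
                VClampProtocol(target=str(node["target"]),
                               levels=levels,
                               gain=units.convert(node["gain"], "conductance"))
            )
        else:
            raise ExperimentError(f"{path}: unknown protocol kind {kind!r}")
    for i, node in enumerate(doc.get("outputs") or []):
        path = f"/outputs[{i}]"
        _check_keys(node, {"path", "variable", "destination", "stride"}, path)
        exp.outputs.append(
            OutputSpec(
                path=str(node["path"]),
                variable=str(node.get("variable", "Vm")),
                destination=str(node.get("destination", "out")),
                stride=int(node.get("stride", 1)),
            )
        )
    exp.validate()
    return exp


def save_experiment(exp: Experiment) -> str:
    exp.validate()
    doc: dict = {"version": DOCUMENT_VERSION, "name": exp.name, "protocols": [], "outputs": []}
    for p in exp.protocols:
        if isinstance(p, PulseProtocol):
            node = {"kind": "pulse", "target": p.target, "delay": p.delay,
                    "duration": p.duration, "amplitude": p.amplitude}
            if p.repeat_interval is not None:
                node["repeat_interval"] = p.repeat_interval
        else:
            node = {"kind": "vclamp", "target": p.target, "gain": p.gain,
                    "levels": [{"start": t, "voltage": v} for t, v in p.levels]}
        doc["protocols"].append(node)
    for o in exp.outputs:
        doc["outputs"].append({"path": o.path, "variable": o.variable,
                               "destination": o.destination, "stride": o.stride})
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
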