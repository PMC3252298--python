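"""Load and save the declarative model document dialect (YAML).

The conceptual representation of a model is a versioned YAML document with
top-level keys ``version``, ``name``, ``units``, ``channels``, ``cells``,
``populations``, ``projections``, ``algorithms``.  Unknown keys anywhere are
rejected with their path.  The full schema is documented in
``docs/model_format.md``.  Saving always emits canonical SI (no units block),
so ``load(save(m))`` reproduces ``m`` exactly.
"""

from __future__ import annotations

import yaml

from ..kinetics import FAMILIES, RateLaw
from ..units import UnitContext
from .types import (
    AlgorithmRef,
    CellModel,
    ChannelPlacement,
    ChannelSpec,
    ConceptualModel,
    GateSpec,
    ModelValidationError,
    PopulationSpec,
    ProjectionSpec,
    SegmentSpec,
)

__all__ = ["DocumentError", "load_model", "save_model"]

DOCUMENT_VERSION = 1


class DocumentError(ValueError):
    """Malformed document (parse failure, unknown key, missing field)."""


def _require_mapping(node, path):
    if not isinstance(node, dict):
        raise DocumentError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _check_keys(node: dict, allowed: set[str], path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        names = ", ".join(sorted(str(k) for k in unknown))
        raise DocumentError(f"{path}: unknown key(s): {names}")


def _get(node: dict, key: str, path: str, required: bool = True, default=None):
    if key not in node:
        if required:
            raise DocumentError(f"{path}: missing required key {key!r}")
        return default
    return node[key]


def _ratelaw(node, path: str, units: UnitContext) -> RateLaw:
    node = _require_mapping(node, path)
    _check_keys(node, {"family", "A", "V0", "K"}, path)
    family = _get(node, "family", path)
    if family not in FAMILIES:
        raise DocumentError(f"{path}: unknown rate-law family {family!r}")
    rate_f = units.factor("rate")
    volt_f = units.factor("voltage")
    a = float(_get(node, "A", path))
    if family == "constant":
        return RateLaw("constant", (a * rate_f,))
    v0 = float(_get(node, "V0", path)) * volt_f
    k = float(_get(node, "K", path)) * volt_f
    if family == "exp_linear":
        a *= rate_f / volt_f  # A has dimension rate/voltage in this family
    else:
        a *= rate_f
    return RateLaw(family, (a, v0, k))


def _channel(name: str, node, path: str, units: UnitContext) -> ChannelSpec:
    node = _require_mapping(node, path)
    _check_keys(node, {"gates"}, path)
    gates_node = _get(node, "gates", path)
    if not isinstance(gates_node, list):
        raise DocumentError(f"{path}/gates: expected a list")
    gates = []
    for i, gnode in enumerate(gates_node):
        gpath = f"{path}/gates[{i}]"
        gnode = _require_mapping(gnode, gpath)
        _check_keys(gnode, {"name", "power", "alpha", "beta"}, gpath)
        gname = str(_get(gnode, "name", gpath, required=False, default=f"gate{i}"))
        power = _get(gnode, "power", gpath)
        if not isinstance(power, int) or isinstance(power, bool):
            raise DocumentError(f"{gpath}: power must be an integer")
        gates.append(
            GateSpec(
                name=gname,
                power=power,
                alpha=_ratelaw(_get(gnode, "alpha", gpath), f"{gpath}/alpha", units),
                beta=_ratelaw(_get(gnode, "beta", gpath), f"{gpath}/beta", units),
            )
        )
    return ChannelSpec(name=name, gates=gates)


_SEGMENT_KEYS = {
    "parent", "length", "diameter", "RA", "RM", "CM", "Em", "Vinit",
    "spine_area", "channels",
}


def _segment(name: str, node, path: str, units: UnitContext) -> SegmentSpec:
    node = _require_mapping(node, path)
    _check_keys(node, _SEGMENT_KEYS, path)
    placements = []
    for i, pnode in enumerate(node.get("channels") or []):
        ppath = f"{path}/channels[{i}]"
        pnode = _require_mapping(pnode, ppath)
        _check_keys(pnode, {"channel", "density", "Erev"}, ppath)
        placements.append(
            ChannelPlacement(
                channel=str(_get(pnode, "channel", ppath)),
                density=units.convert(_get(pnode, "density", ppath), "conductance_density"),
                erev=units.convert(_get(pnode, "Erev", ppath), "voltage"),
            )
        )
    parent = node.get("parent")
    return SegmentSpec(
        name=name,
        parent=None if parent is None else str(parent),
        length=units.convert(node.get("length"), "length"),
        diameter=units.convert(node.get("diameter"), "length"),
        ra=units.convert(node.get("RA"), "axial_resistivity"),
        rm=units.convert(node.get("RM"), "membrane_resistance"),
        cm=units.convert(node.get("CM"), "capacitance_density"),
        em=units.convert(node.get("Em"), "voltage"),
        vinit=units.convert(node.get("Vinit"), "voltage"),
        spine_area=units.convert(node.get("spine_area", 0.0), "area"),
        channels=placements,
    )


def _projection(node, path: str, units: UnitContext) -> ProjectionSpec:
    node = _require_mapping(node, path)
    _check_keys(
        node,
        {"name", "source", "target", "rule", "weight", "delay", "pre", "post",
         "threshold", "tau", "Esyn", "self_connections"},
        path,
    )
    rnode = _require_mapping(_get(node, "rule", path), f"{path}/rule")
    _check_keys(rnode, {"kind", "p", "seed"}, f"{path}/rule")
    kind = _get(rnode, "kind", f"{path}/rule")
    if kind == "all_to_all":
        rule: tuple = ("all_to_all",)
    elif kind == "probabilistic":
        rule = ("probabilistic", float(_get(rnode, "p", f"{path}/rule")),
                int(_get(rnode, "seed", f"{path}/rule")))
    else:
        raise DocumentError(f"{path}/rule: unknown rule kind {kind!r}")
    return ProjectionSpec(
        name=str(_get(node, "name", path)),
        source=str(_get(node, "source", path)),
        target=str(_get(node, "target", path)),
        rule=rule,
        weight=units.convert(_get(node, "weight", path), "conductance"),
        delay=units.convert(_get(node, "delay", path), "time"),
        pre=str(node.get("pre", "")),
        post=str(node.get("post", "")),
        threshold=units.convert(node.get("threshold", 0.0), "voltage"),
        tau=units.convert(node.get("tau", 2e-3), "time"),
        esyn=units.convert(node.get("Esyn", 0.0), "voltage"),
        self_connections=bool(node.get("self_connections", True)),
    )


def load_model(text: str) -> ConceptualModel:
    """Parse a declarative model document into a validated ConceptualModel."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise DocumentError(f"document does not parse as YAML: {exc}") from exc
    doc = _require_mapping(doc, "/")
    _check_keys(
        doc,
        {"version", "name", "units", "channels", "cells", "populations",
         "projections", "algorithms"},
        "/",
    )
    version = _get(doc, "version", "/")
    if version != DOCUMENT_VERSION:
        raise DocumentError(f"/version: unsupported document version {version!r}")
    units = UnitContext(_require_mapping(doc["units"], "/units") if doc.get("units") else None)

    model = ConceptualModel(name=str(doc.get("name", "model")))

    for cname, cnode in (_require_mapping(doc.get("channels") or {}, "/channels")).items():
        model.channels[str(cname)] = _channel(str(cname), cnode, f"/channels/{cname}", units)

    for cellname, cellnode in (_require_mapping(doc.get("cells") or {}, "/cells")).items():
        cpath = f"/cells/{cellname}"
        cellnode = _require_mapping(cellnode, cpath)
        _check_keys(cellnode, {"segments"}, cpath)
        segnodes = _require_mapping(_get(cellnode, "segments", cpath), f"{cpath}/segments")
        segments = [
            _segment(str(sname), snode, f"{cpath}/segments/{sname}", units)
            for sname, snode in segnodes.items()
        ]
        model.cells[str(cellname)] = CellModel(name=str(cellname), segments=segments)

    for i, pnode in enumerate(doc.get("populations") or []):
        ppath = f"/populations[{i}]"
        pnode = _require_mapping(pnode, ppath)
        _check_keys(pnode, {"name", "cell", "count"}, ppath)
        model.populations.append(
            PopulationSpec(
                name=str(_get(pnode, "name", ppath)),
                cell=str(_get(pnode, "cell", ppath)),
                count=int(_get(pnode, "count", ppath)),
            )
        )

    for i, jnode in enumerate(doc.get("projections") or []):
        model.projections.append(_projection(jnode, f"/projections[{i}]", units))

    for i, anode in enumerate(doc.get("algorithms") or []):
        apath = f"/algorithms[{i}]"
        anode = _require_mapping(anode, apath)
        _check_keys(anode, {"name", "params"}, apath)
        params = _require_mapping(anode.get("params") or {}, f"{apath}/params")
        model.algorithms.append(
            AlgorithmRef(name=str(_get(anode, "name", apath)),
                         params={str(k): float(v) for k, v in params.items()})
        )

    try:
        model.validate()
    except ModelValidationError:
        raise
    return model


def _ratelaw_dict(law: RateLaw) -> dict:
    d = {"family": law.family, "A": law.params[0]}
    if law.family != "constant":
        d["V0"] = law.params[1]
        d["K"] = law.params[2]
    return d


def save_model(model: ConceptualModel) -> str:
    """Serialize a ConceptualModel to its canonical SI document."""
    model.validate()
    doc: dict = {"version": DOCUMENT_VERSION, "name": model.name}
    if model.channels:
        doc["channels"] = {
            name: {
                "gates": [
                    {"name": g.name, "power": g.power,
                     "alpha": _ratelaw_dict(g.alpha), "beta": _ratelaw_dict(g.beta)}
                    for g in ch.gates
                ]
            }
            for name, ch in model.channels.items()
        }
    if model.cells:
        cells: dict = {}
        for cellname, cell in model.cells.items():
            segs: dict = {}
            for s in cell.segments:
                node: dict = {"parent": s.parent}
                for key, val in (("length", s.length), ("diameter", s.diameter),
                                 ("RA", s.ra), ("RM", s.rm), ("CM", s.cm),
                                 ("Em", s.em), ("Vinit", s.vinit)):
                    if val is not None:
                        node[key] = val
                if s.spine_area:
                    node["spine_area"] = s.spine_area
                if s.channels:
                    node["channels"] = [
                        {"channel": p.channel, "density": p.density, "Erev": p.erev}
                        for p in s.channels
                    ]
                segs[s.name] = node
            cells[cellname] = {"segments": segs}
        doc["cells"] = cells
    if model.populations:
        doc["populations"] = [
            {"name": p.name, "cell": p.cell, "count": p.count} for p in model.populations
        ]
    if model.projections:
        projs = []
        for j in model.projections:
            rule = {"kind": j.rule[0]}
            if j.rule[0] == "probabilistic":
                rule["p"] = j.rule[1]
                rule["seed"] = j.rule[2]
            node = {"name": j.name, "source": j.source, "target": j.target,
                    "rule": rule, "weight": j.weight, "delay": j.delay}
            if j.pre:
                node["pre"] = j.pre
            if j.post:
                node["post"] = j.post
            node["threshold"] = j.threshold
            node["tau"] = j.tau
            node["Esyn"] = j.esyn
            if not j.self_connections:
                node["self_connections"] = False
            projs.append(node)
        doc["projections"] = projs
    if model.algorithms:
        doc["algorithms"] = [
            {"name": a.name, "params": dict(a.params)} for a in model.algorithms
        ]
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
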