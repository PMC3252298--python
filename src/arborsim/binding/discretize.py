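"""Discretization and scaling: biological tree -> Hines-ordered compartments.

Three steps, each a pure one-to-one mapping with no solver algorithms:

``compartmentalize``
    Split segments whose electrotonic length L/lambda exceeds ``l_max`` into
    ceil(L_e / l_max) equal sub-segments (lambda = sqrt(RM*d / (4*RA)), the
    infinite-cable length constant).  Total length, membrane area, and channel
    densities are preserved exactly.
``linearize``
    Order the (sub-)segment tree leaf-to-root (post-order, root last) so that
    Gaussian elimination in ascending index introduces zero fill-in.
``scale_parameters``
    Convert intensive membrane densities to absolute per-compartment values.
    Spine membrane area enters the capacitance and leak scaling but NOT the
    channel conductance scaling (spines are assumed passive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from ..model.types import CellModel, ChannelSpec, SegmentSpec
from .types import ChannelInstance, Compartment, GateBinding, MathematicalModel

__all__ = [
    "BindingError",
    "electrotonic_length",
    "compartmentalize",
    "linearize",
    "scale_parameters",
    "expand_cell",
]


class BindingError(ValueError):
    pass


def electrotonic_length(segment: SegmentSpec) -> float:
    """L / lambda with lambda = sqrt(RM * d / (4 * RA))."""
    if segment.rm is None or segment.ra is None:
        raise BindingError(f"segment {segment.name!r}: RM and RA required for electrotonic length")
    if segment.length is None or segment.diameter is None:
        raise BindingError(f"segment {segment.name!r}: geometry required for electrotonic length")
    lam = math.sqrt(segment.rm * segment.diameter / (4.0 * segment.ra))
    return segment.length / lam


def compartmentalize(cell: CellModel, l_max: float) -> CellModel:
    """Split long segments into equal sub-segments bounded by ``l_max``.

    Sub-segments of ``seg`` are named ``seg.0 .. seg.k-1`` (segments that do
    not split keep their name), chained distally, with spine area divided
    equally and channel densities inherited unchanged (they are intensive).
    """
    if l_max <= 0:
        raise BindingError("l_max must be > 0")
    new_segments: list[SegmentSpec] = []
    tail_name: dict[str, str] = {}  # original name -> name of its distal sub-segment
    # walk parents before children so tail_name is always populated
    order: list[SegmentSpec] = []
    stack = [s for s in cell.segments if s.parent is None]
    while stack:
        seg = stack.pop()
        order.append(seg)
        stack.extend(cell.children_of(seg.name))
    for seg in order:
        n_sub = max(1, math.ceil(electrotonic_length(seg) / l_max - 1e-12))
        parent = None if seg.parent is None else tail_name[seg.parent]
        if n_sub == 1:
            new_segments.append(replace(seg, parent=parent))
            tail_name[seg.name] = seg.name
            continue
        for k in range(n_sub):
            sub = replace(
                seg,
                name=f"{seg.name}.{k}",
                parent=parent,
                length=seg.length / n_sub,
                spine_area=seg.spine_area / n_sub,
                channels=list(seg.channels),
            )
            new_segments.append(sub)
            parent = sub.name
        tail_name[seg.name] = parent
    return CellModel(name=cell.name, segments=new_segments)


def linearize(cell: CellModel) -> list[SegmentSpec]:
    """Return segments in Hines order: children before parents, root last.

    In the returned list every segment's parent appears at a strictly larger
    index, which is exactly the zero-fill-in elimination order for the
    branched-cable system.  Children are visited in declaration order.
    """
    by_parent: dict[str | None, list[SegmentSpec]] = {}
    for s in cell.segments:
        by_parent.setdefault(s.parent, []).append(s)
    roots = by_parent.get(None, [])
    if len(roots) != 1:
        raise BindingError(f"cell {cell.name!r} must have exactly one root")
    ordered: list[SegmentSpec] = []
    seen: set[str] = set()

    def visit(seg: SegmentSpec) -> None:
        if seg.name in seen:  # defensive against cycles
            raise BindingError(f"cycle detected at segment {seg.name!r}")
        seen.add(seg.name)
        for child in by_parent.get(seg.name, []):
            visit(child)
        ordered.append(seg)

    visit(roots[0])
    if len(ordered) != len(cell.segments):
        raise BindingError(f"cell {cell.name!r}: disconnected segments present")
    return ordered


def scale_parameters(
    segment: SegmentSpec,
    channels: dict[str, ChannelSpec],
    index: int,
    parent_index: int | None,
    source_path: str,
) -> Compartment:
    """Scale one segment's densities to absolute values.

    Cm     = CM * (pi*d*L + spine_area)
    G_leak = (pi*d*L + spine_area) / RM
    Gmax   = density * pi*d*L          (spine area deliberately excluded)
    Ra     = RA * L / (pi * (d/2)^2)
    """
    missing = segment.missing_parameters()
    if missing:
        raise BindingError(f"{source_path}: missing parameter(s) {', '.join(missing)}")
    area = math.pi * segment.diameter * segment.length
    area_with_spines = area + segment.spine_area
    instances = []
    for placement in segment.channels:
        try:
            spec = channels[placement.channel]
        except KeyError:
            raise BindingError(f"{source_path}: undeclared channel {placement.channel!r}") from None
        gates = tuple(
            GateBinding(name=g.name, power=g.power, alpha=g.alpha, beta=g.beta)
            for g in spec.gates
        )
        instances.append(
            ChannelInstance(
                name=spec.name,
                gmax=placement.density * area,
                erev=placement.erev,
                gates=gates,
            )
        )
    return Compartment(
        index=index,
        parent_index=parent_index,
        cm=segment.cm * area_with_spines,
        ra=None if parent_index is None else segment.ra * segment.length
        / (math.pi * (segment.diameter / 2.0) ** 2),
        g_leak=area_with_spines / segment.rm,
        e_leak=segment.em,
        v_init=segment.vinit if segment.vinit is not None else segment.em,
        area=area,
        source_path=source_path,
        channels=tuple(instances),
    )


def expand_cell(
    cell: CellModel,
    channels: dict[str, ChannelSpec],
    instance_path: str,
    l_max: float | None = None,
) -> MathematicalModel:
    """Full expansion of one cell instance into a MathematicalModel.

    An incomplete cell (missing membrane parameters) yields a model with
    ``complete=False`` and an empty compartment list: it stays inspectable at
    the biological level but refuses numerical binding.
    """
    missing = [
        (f"{instance_path}/{seg.name}", p)
        for seg in cell.segments
        for p in seg.missing_parameters()
    ]
    if missing:
        return MathematicalModel(origin=instance_path, compartments=[],
                                 complete=False, missing=missing)
    working = compartmentalize(cell, l_max) if l_max is not None else cell
    ordered = linearize(working)
    pos = {seg.name: i for i, seg in enumerate(ordered)}
    comps = [
        scale_parameters(
            seg,
            channels,
            index=i,
            parent_index=None if seg.parent is None else pos[seg.parent],
            source_path=f"{instance_path}/{seg.name}",
        )
        for i, seg in enumerate(ordered)
    ]
    return MathematicalModel(origin=instance_path, compartments=comps)
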