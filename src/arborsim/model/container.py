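"""The biology model container.

Stores the three faces of a model — the in-memory biological tree, its
serialized conceptual document, and the expanded mathematical representation —
and answers biological queries (surface area, channel tables, completeness)
and identifier resolution from biological paths to solver state coordinates.

Identifier paths are slash-separated from the model root and case-sensitive:
``/cellname/segment`` for stand-alone cells, ``/population/i/segment`` for the
i-th instance of a population.  When a document declares populations, solvers
are instantiated per population instance and the declared cells act as
templates only; otherwise each declared cell gets one solver.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

from .document import load_model, save_model
from .types import CellModel, CompletenessReport, ConceptualModel

if TYPE_CHECKING:  # the binding layer imports model.types; avoid a cycle at runtime
    from ..binding.types import NetworkBinding

__all__ = ["ModelContainer", "UnknownPathError"]


class UnknownPathError(KeyError):
    def __init__(self, path: str, detail: str = "unknown path"):
        self.path = path
        super().__init__(f"{detail}: {path}")


class ModelContainer:
    """Owns a ConceptualModel; expansion is cached and invalidated on mutation."""

    def __init__(self, model: ConceptualModel):
        model.validate()
        self.model = model
        self._binding: NetworkBinding | None = None
        self._var_index: dict[tuple[str, str], tuple[int, int]] | None = None
        self._instance_paths: list[str] | None = None

    # -- conceptual representation -------------------------------------------------
    @classmethod
    def from_text(cls, text: str) -> "ModelContainer":
        return cls(load_model(text))

    @classmethod
    def from_file(cls, path) -> "ModelContainer":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_text(fh.read())

    def to_text(self) -> str:
        return save_model(self.model)

    # -- queries (pure) ------------------------------------------------------------
    def _cell(self, cell: str) -> CellModel:
        try:
            return self.model.cells[cell]
        except KeyError:
            raise UnknownPathError(f"/{cell}", "unknown cell") from None

    def check_completeness(self) -> CompletenessReport:
        """List every (path, parameter) required for simulation but absent."""
        missing: list[tuple[str, str]] = []
        for cell in self.model.cells.values():
            for seg in cell.segments:
                for p in seg.missing_parameters():
                    missing.append((f"/{cell.name}/{seg.name}", p))
        return CompletenessReport(missing=missing)

    def query_surface_area(self, cell: str, spine_corrected: bool = False) -> float:
        """Total membrane area of a cell in m^2: sum of cylinder lateral areas
        pi*d*L, plus summed spine areas when ``spine_corrected``."""
        c = self._cell(cell)
        total = 0.0
        for seg in c.segments:
            if seg.length is None or seg.diameter is None:
                from ..binding.discretize import BindingError

                raise BindingError(f"/{cell}/{seg.name}: geometry (length, diameter) missing")
            total += math.pi * seg.diameter * seg.length
            if spine_corrected:
                total += seg.spine_area
        return total

    def query_channel_table(self, cell: str) -> list[tuple[str, str, float, float]]:
        """(segment path, channel, density S/m^2, Erev V) rows, sorted by
        segment path then channel name."""
        c = self._cell(cell)
        rows = [
            (f"/{cell}/{seg.name}", pl.channel, pl.density, pl.erev)
            for seg in c.segments
            for pl in seg.channels
        ]
        rows.sort(key=lambda r: (r[0], r[1]))
        return rows

    # -- mutation ------------------------------------------------------------------
    _SEG_ATTRS = {"length": "length", "diameter": "diameter", "RA": "ra", "RM": "rm",
                  "CM": "cm", "Em": "em", "Vinit": "vinit", "spine_area": "spine_area"}

    def set_parameter(self, path: str, param: str, value: float | None = None,
                      scale: float | None = None) -> None:
        """Override a segment parameter (absolute ``value`` or multiplicative
        ``scale``); invalidates any cached expansion."""
        seg = self._segment_at(path)
        if param not in self._SEG_ATTRS:
            raise UnknownPathError(path, f"unknown parameter {param!r}")
        attr = self._SEG_ATTRS[param]
        if scale is not None:
            current = getattr(seg, attr)
            if current is None:
                from ..binding.discretize import BindingError

                raise BindingError(f"{path}: cannot scale unset parameter {param!r}")
            setattr(seg, attr, current * scale)
        else:
            setattr(seg, attr, value)
        self.invalidate()

    def _segment_at(self, path: str):
        parts = [p for p in path.split("/") if p]
        if not parts:
            raise UnknownPathError(path)
        cellname, segname = parts[0], parts[-1]
        if cellname in self.model.cells:
            cell = self.model.cells[cellname]
        else:
            # population path: /pop/i/segment -> the template cell
            pops = {p.name: p for p in self.model.populations}
            if cellname not in pops:
                raise UnknownPathError(path, "unknown cell or population")
            cell = self.model.cells[pops[cellname].cell]
        try:
            return cell.segment(segname)
        except KeyError:
            raise UnknownPathError(path, "unknown segment") from None

    def invalidate(self) -> None:
        self._binding = None
        self._var_index = None
        self._instance_paths = None

    # -- expansion -----------------------------------------------------------------
    def _l_max(self) -> float | None:
        from ..binding.discretize import BindingError

        for alg in self.model.algorithms:
            if alg.name == "compartmentalize":
                try:
                    return float(alg.params["L_max"])
                except KeyError:
                    raise BindingError(
                        "/algorithms/compartmentalize: parameter L_max required"
                    ) from None
        return None

    def instance_paths(self) -> list[str]:
        """Solver instance paths in deterministic declaration order."""
        if self._instance_paths is None:
            if self.model.populations:
                self._instance_paths = [
                    f"/{pop.name}/{i}"
                    for pop in self.model.populations
                    for i in range(pop.count)
                ]
            else:
                self._instance_paths = [f"/{name}" for name in self.model.cells]
        return self._instance_paths

    def expand(self, force: bool = False) -> "NetworkBinding":
        """Produce (and cache) the fully expanded mathematical representation."""
        from ..binding.connectivity import translate_connectivity
        from ..binding.discretize import expand_cell
        from ..binding.types import NetworkBinding

        if self._binding is not None and not force:
            return self._binding
        l_max = self._l_max()
        solvers = []
        instance_solvers: dict[str, list[int]] = {}
        if self.model.populations:
            idx = 0
            for pop in self.model.populations:
                ids = []
                template = self.model.cells[pop.cell]
                for i in range(pop.count):
                    solvers.append(
                        expand_cell(template, self.model.channels,
                                    f"/{pop.name}/{i}", l_max)
                    )
                    ids.append(idx)
                    idx += 1
                instance_solvers[pop.name] = ids
        else:
            for name, cell in self.model.cells.items():
                solvers.append(expand_cell(cell, self.model.channels, f"/{name}", l_max))

        binding = NetworkBinding(solvers=solvers)

        if binding.complete and self.model.projections:
            def resolve_comp(solver_id: int, seg: str) -> int:
                m = binding.solvers[solver_id]
                if seg == "":
                    return m.n_compartments - 1  # root is last in Hines order
                prefix = f"{m.origin}/{seg}"
                return self._comp_by_path(m, prefix)

            binding.wiring = translate_connectivity(
                self.model.populations, self.model.projections,
                instance_solvers, resolve_comp,
            )

        self._binding = binding
        self._build_var_index()
        return binding

    @staticmethod
    def _comp_by_path(m, path: str) -> int:
        for c in m.compartments:
            if c.source_path == path:
                return c.index
        # a compartmentalized segment: pick the middle sub-segment
        subs = [c for c in m.compartments if c.source_path.startswith(path + ".")]
        if subs:
            return subs[(len(subs) - 1) // 2].index
        raise KeyError(path)

    def _build_var_index(self) -> None:
        index: dict[tuple[str, str], tuple[int, int]] = {}
        assert self._binding is not None
        for sid, m in enumerate(self._binding.solvers):
            for vi, (path, var) in enumerate(m.state_layout()):
                index[(path, var)] = (sid, vi)
        self._var_index = index

    # -- identifier resolution -----------------------------------------------------
    def resolve_identifier(self, path: str, variable: str = "Vm") -> tuple[int, int]:
        """Biological path + variable name -> (solver id, state-vector index).

        The mapping is total over compartment voltages and gate variables and
        injective (each state entry has exactly one biological name).
        Requires :meth:`expand` to have produced a complete binding.
        """
        if self._binding is None:
            raise RuntimeError("model not expanded: call expand() before resolving identifiers")
        assert self._var_index is not None
        try:
            return self._var_index[(path, variable)]
        except KeyError:
            pass
        # original segment that was split by compartmentalization
        candidates = sorted(
            (p, v) for (p, v) in self._var_index if v == variable and p.startswith(path + ".")
        )
        if candidates:
            mid = candidates[(len(candidates) - 1) // 2]
            return self._var_index[mid]
        known_paths = {p for (p, _v) in self._var_index}
        if path in known_paths or any(p.startswith(path + ".") for p in known_paths):
            raise UnknownPathError(path, f"unknown variable {variable!r} at")
        raise UnknownPathError(path)

    def variable_index(self) -> dict[tuple[str, str], tuple[int, int]]:
        """The full biological-variable -> (solver, index) mapping."""
        if self._var_index is None:
            raise RuntimeError("model not expanded")
        return dict(self._var_index)
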