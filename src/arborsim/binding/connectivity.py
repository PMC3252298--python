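"""Connectivity translation: biological projections -> solver wiring.

Populations expand to per-instance solvers elsewhere; this module only turns
projection rules into explicit ordered (source, target) pairs and resolves
their endpoints to (solver, compartment) coordinates through a resolver
callable supplied by the model container.  Probabilistic rules draw one
independent Bernoulli sample per ordered pair, in row-major (source-major)
order, from the seed stated in the rule — a fixed draw order is what makes a
network reproducible.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from ..model.types import PopulationSpec, ProjectionSpec
from .types import Wire

__all__ = ["ConnectivityError", "translate_connectivity"]


class ConnectivityError(ValueError):
    pass


def translate_connectivity(
    populations: Sequence[PopulationSpec],
    projections: Sequence[ProjectionSpec],
    instance_solvers: dict[str, list[int]],
    resolve: Callable[[int, str], int],
) -> list[Wire]:
    """Translate projections into a flat wiring list.

    Parameters
    ----------
    instance_solvers
        population name -> ordered list of solver ids, one per cell instance.
    resolve
        ``resolve(solver_id, segment_name)`` -> compartment index within that
        solver ("" selects the root compartment).  Raises KeyError on unknown
        segments; re-raised here as :class:`ConnectivityError` with the path.
    """
    wires: list[Wire] = []
    for proj in projections:
        for endpoint in (proj.source, proj.target):
            if endpoint not in instance_solvers:
                raise ConnectivityError(
                    f"/projections/{proj.name}: population {endpoint!r} not expanded"
                )
        src_ids = instance_solvers[proj.source]
        tgt_ids = instance_solvers[proj.target]
        same_pop = proj.source == proj.target

        def _comp(solver_id: int, seg: str, role: str) -> int:
            try:
                return resolve(solver_id, seg)
            except KeyError:
                raise ConnectivityError(
                    f"/projections/{proj.name}: {role} segment {seg!r} does not "
                    f"resolve in population cell"
                ) from None

        kind = proj.rule[0]
        if kind == "probabilistic":
            p, seed = proj.rule[1], proj.rule[2]
            rng = np.random.default_rng(seed)
            draws = rng.random((len(src_ids), len(tgt_ids)))
        else:
            p, draws = None, None

        for i, s_id in enumerate(src_ids):
            for j, t_id in enumerate(tgt_ids):
                if same_pop and not proj.self_connections and i == j:
                    continue
                if draws is not None and not (draws[i, j] < p):
                    continue
                wires.append(
                    Wire(
                        pre_solver=s_id,
                        pre_comp=_comp(s_id, proj.pre, "pre"),
                        threshold=proj.threshold,
                        post_solver=t_id,
                        post_comp=_comp(t_id, proj.post, "post"),
                        weight=proj.weight,
                        delay=proj.delay,
                        tau=proj.tau,
                        esyn=proj.esyn,
                    )
                )
    return wires
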