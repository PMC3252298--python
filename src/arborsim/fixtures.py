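"""Programmatic generators for test models and experiments.

Every fixture is emitted as a pair of declarative documents (model text,
experiment text) in the same dialect users write, so the whole test suite
builds its inputs at run time with no external data.  Generators are
deterministic for a given seed.

The Hodgkin-Huxley fixtures use the classical squid-axon parameterization:
membrane capacitance 1 uF/cm^2 (0.01 F/m^2), peak densities gNa = 120, gK =
36, g_leak = 0.3 mS/cm^2, reversals ENa = +50, EK = -77, E_leak = -54.387 mV,
resting potential -65 mV.  The rate-law coefficients are vendored in
``data/hh_squid.yaml`` rather than hard-coded here, keeping the kinetics with
the biology rather than the generator logic.
"""

from __future__ import annotations

import importlib.resources
import math

import numpy as np

from .experiment.protocols import Experiment, OutputSpec, PulseProtocol, save_experiment
from .model.document import load_model, save_model
from .model.types import (
    AlgorithmRef,
    CellModel,
    ChannelPlacement,
    ConceptualModel,
    PopulationSpec,
    ProjectionSpec,
    SegmentSpec,
)

__all__ = ["make_fixture", "FIXTURE_KINDS", "hh_channels", "with_compartmentalization"]

FIXTURE_KINDS = (
    "passive_soma",
    "hh_soma",
    "ball_and_stick",
    "passive_cable",
    "y_branch",
    "random_tree",
    "random_network",
    "two_cell_relay",
)

# passive study-condition defaults: RM = 1 ohm*m^2, CM = 0.01 F/m^2 gives the
# canonical 10 ms membrane time constant; RA = 1 ohm*m is within the usual
# 0.5-3 ohm*m cytoplasmic range.
PASSIVE = dict(ra=1.0, rm=1.0, cm=0.01, em=-0.065)

# squid-axon membrane (SI): leak 3 S/m^2 -> RM = 1/3 ohm*m^2
HH_MEMBRANE = dict(ra=1.0, rm=1.0 / 3.0, cm=0.01, em=-0.054387, vinit=-0.065)
HH_GNA = 1200.0  # S/m^2
HH_GK = 360.0
HH_ENA = 0.050  # V
HH_EK = -0.077


def hh_channels():
    """The vendored squid-axon channel specs (SI), keyed 'na' and 'k'."""
    text = (
        importlib.resources.files("arborsim.data").joinpath("hh_squid.yaml").read_text()
    )
    return load_model(text).channels


def _drop(model: ConceptualModel, drop_params: dict[str, list[str]] | None) -> None:
    attr = {"length": "length", "diameter": "diameter", "RA": "ra", "RM": "rm",
            "CM": "cm", "Em": "em"}
    for cell in model.cells.values():
        for segname, params in (drop_params or {}).items():
            try:
                seg = cell.segment(segname)
            except KeyError:
                continue
            for p in params:
                setattr(seg, attr[p], None)


def _pulse_experiment(target: str, delay: float, duration: float, amplitude: float,
                      stride: int = 1) -> Experiment:
    return Experiment(
        name="pulse",
        protocols=[PulseProtocol(target=target, delay=delay, duration=duration,
                                 amplitude=amplitude)],
        outputs=[OutputSpec(path=target, variable="Vm", stride=stride)],
    )


def _passive_soma_model(name: str = "cell", length: float = 100e-6,
                        diameter: float = 10e-6, spine_area: float = 0.0,
                        **membrane) -> ConceptualModel:
    params = {**PASSIVE, **membrane}
    soma = SegmentSpec(name="soma", parent=None, length=length, diameter=diameter,
                       spine_area=spine_area, **params)
    return ConceptualModel(name=name, cells={name: CellModel(name=name, segments=[soma])})


def _hh_cell(name: str, length: float = 30e-6, diameter: float = 30e-6) -> ConceptualModel:
    soma = SegmentSpec(
        name="soma", parent=None, length=length, diameter=diameter,
        channels=[
            ChannelPlacement(channel="na", density=HH_GNA, erev=HH_ENA),
            ChannelPlacement(channel="k", density=HH_GK, erev=HH_EK),
        ],
        **HH_MEMBRANE,
    )
    return ConceptualModel(
        name=name,
        channels=hh_channels(),
        cells={name: CellModel(name=name, segments=[soma])},
    )


def make_fixture(kind: str, **params) -> tuple[str, str]:
    """Build a (model document, experiment document) pair for ``kind``.

    Recognized kinds and their main parameters:

    - ``passive_soma``: ``length``, ``diameter``, ``spine_area``, membrane
      overrides, ``drop_params`` (e.g. ``{"soma": ["RA"]}``).
    - ``hh_soma``: squid-axon soma; ``amplitude`` (A) of the test pulse.
    - ``ball_and_stick``: soma + chain of ``n`` dendrite segments.
    - ``passive_cable``: ``n`` identical chained segments totaling
      ``total_length`` (default one length constant), current step at the root.
    - ``y_branch``: 7-segment branched tree.
    - ``random_tree``: ``n`` segments, random topology/geometry from ``seed``.
    - ``random_network``: ``n_cells`` HH somata, probabilistic projection
      (``p``, ``seed``).
    - ``two_cell_relay``: two HH somata in separate populations, A drives B
      across a delayed synapse (``delay``, ``weight``).
    """
    if kind == "passive_soma":
        drop_params = params.pop("drop_params", None)
        amplitude = params.pop("amplitude", 0.1e-9)
        model = _passive_soma_model(**params)
        _drop(model, drop_params)
        exp = _pulse_experiment(f"/{model.name}/soma", delay=10e-3, duration=20e-3,
                                amplitude=amplitude)
        return save_model(model), save_experiment(exp)

    if kind == "hh_soma":
        amplitude = params.pop("amplitude", 0.3e-9)
        delay = params.pop("delay", 5e-3)
        duration = params.pop("duration", 20e-3)
        model = _hh_cell(params.pop("name", "cell"), **params)
        exp = _pulse_experiment(f"/{model.name}/soma", delay=delay, duration=duration,
                                amplitude=amplitude)
        return save_model(model), save_experiment(exp)

    if kind == "ball_and_stick":
        n = params.pop("n", 5)
        segs = [SegmentSpec(name="soma", parent=None, length=20e-6, diameter=20e-6,
                            **PASSIVE)]
        parent = "soma"
        for i in range(n):
            name = f"dend{i}"
            segs.append(SegmentSpec(name=name, parent=parent, length=100e-6,
                                    diameter=2e-6, **PASSIVE))
            parent = name
        model = ConceptualModel(name="cell", cells={"cell": CellModel("cell", segs)})
        exp = _pulse_experiment("/cell/soma", delay=10e-3, duration=20e-3, amplitude=0.1e-9)
        return save_model(model), save_experiment(exp)

    if kind == "passive_cable":
        n = params.pop("n", 11)
        diameter = params.pop("diameter", 2e-6)
        lam = math.sqrt(PASSIVE["rm"] * diameter / (4.0 * PASSIVE["ra"]))
        total = params.pop("total_length", lam)
        amplitude = params.pop("amplitude", 0.01e-9)
        seg_len = total / n
        segs = []
        parent = None
        for i in range(n):
            name = f"c{i}"
            segs.append(SegmentSpec(name=name, parent=parent, length=seg_len,
                                    diameter=diameter, **PASSIVE))
            parent = name
        model = ConceptualModel(name="cable", cells={"cable": CellModel("cable", segs)})
        exp = Experiment(
            name="step",
            protocols=[PulseProtocol(target="/cable/c0", delay=0.0, duration=10.0,
                                     amplitude=amplitude)],
            outputs=[OutputSpec(path=f"/cable/c{i}", variable="Vm", stride=100)
                     for i in range(n)],
        )
        return save_model(model), save_experiment(exp)

    if kind == "y_branch":
        segs = [
            SegmentSpec(name="soma", parent=None, length=20e-6, diameter=20e-6, **PASSIVE),
            SegmentSpec(name="trunk", parent="soma", length=50e-6, diameter=4e-6, **PASSIVE),
            SegmentSpec(name="l1", parent="trunk", length=80e-6, diameter=2e-6, **PASSIVE),
            SegmentSpec(name="l2", parent="l1", length=80e-6, diameter=1.5e-6, **PASSIVE),
            SegmentSpec(name="r1", parent="trunk", length=60e-6, diameter=2e-6, **PASSIVE),
            SegmentSpec(name="r2", parent="r1", length=60e-6, diameter=1.5e-6, **PASSIVE),
            SegmentSpec(name="r3", parent="r2", length=60e-6, diameter=1e-6, **PASSIVE),
        ]
        model = ConceptualModel(name="ycell", cells={"ycell": CellModel("ycell", segs)})
        exp = _pulse_experiment("/ycell/soma", delay=10e-3, duration=20e-3, amplitude=0.05e-9)
        return save_model(model), save_experiment(exp)

    if kind == "random_tree":
        n = params.pop("n", 50)
        seed = params.pop("seed", 0)
        rng = np.random.default_rng(seed)
        segs = [SegmentSpec(name="seg0", parent=None, length=float(rng.uniform(20e-6, 200e-6)),
                            diameter=float(rng.uniform(1e-6, 20e-6)),
                            spine_area=float(rng.uniform(0, 1e-10)), **PASSIVE)]
        for i in range(1, n):
            parent = f"seg{int(rng.integers(0, i))}"
            segs.append(SegmentSpec(name=f"seg{i}", parent=parent,
                                    length=float(rng.uniform(20e-6, 200e-6)),
                                    diameter=float(rng.uniform(0.5e-6, 5e-6)),
                                    spine_area=float(rng.uniform(0, 1e-10)), **PASSIVE))
        model = ConceptualModel(name="rtree", cells={"rtree": CellModel("rtree", segs)})
        exp = _pulse_experiment("/rtree/seg0", delay=10e-3, duration=20e-3, amplitude=0.05e-9)
        return save_model(model), save_experiment(exp)

    if kind == "random_network":
        n_cells = params.pop("n_cells", 10)
        p = params.pop("p", 0.3)
        seed = params.pop("seed", 0)
        base = _hh_cell("hhcell")
        base.populations = [PopulationSpec(name="pop", cell="hhcell", count=n_cells)]
        base.projections = [
            ProjectionSpec(
                name="recurrent", source="pop", target="pop",
                rule=("probabilistic", p, seed),
                weight=params.pop("weight", 5e-9), delay=params.pop("delay", 5e-3),
                pre="soma", post="soma", threshold=0.0, tau=2e-3, esyn=0.0,
                self_connections=False,
            )
        ]
        base.name = "net"
        exp = _pulse_experiment("/pop/0/soma", delay=5e-3, duration=20e-3, amplitude=0.3e-9)
        return save_model(base), save_experiment(exp)

    if kind == "two_cell_relay":
        delay = params.pop("delay", 5e-3)
        weight = params.pop("weight", 50e-9)
        base = _hh_cell("hhcell")
        base.name = "relay"
        base.populations = [
            PopulationSpec(name="a", cell="hhcell", count=1),
            PopulationSpec(name="b", cell="hhcell", count=1),
        ]
        base.projections = [
            ProjectionSpec(name="ab", source="a", target="b", rule=("all_to_all",),
                           weight=weight, delay=delay, pre="soma", post="soma",
                           threshold=0.0, tau=2e-3, esyn=0.0)
        ]
        exp = Experiment(
            name="relay",
            protocols=[PulseProtocol(target="/a/0/soma", delay=5e-3, duration=20e-3,
                                     amplitude=0.3e-9)],
            outputs=[OutputSpec(path="/a/0/soma"), OutputSpec(path="/b/0/soma")],
        )
        return save_model(base), save_experiment(exp)

    raise ValueError(f"unknown fixture kind {kind!r} (known: {', '.join(FIXTURE_KINDS)})")


def with_compartmentalization(model_text: str, l_max: float) -> str:
    """Attach the compartmentalization algorithm reference to a model document."""
    model = load_model(model_text)
    model.algorithms = [a for a in model.algorithms if a.name != "compartmentalize"]
    model.algorithms.append(AlgorithmRef(name="compartmentalize", params={"L_max": l_max}))
    return save_model(model)
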