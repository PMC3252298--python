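"""The scheduler: wire components from a configuration file and run them.

The scheduler instantiates the model container, expansion, solvers, command
executor and controller, applies per-simulation parameter overrides through
the model container, and runs the federation — it performs no numerical work
of its own.  Batch iteration expands a grid of overrides into independent
runs, each with its own output files and JSON run record.

Configuration document (YAML, versioned)::

    version: 1
    model: model.yaml          # required
    experiment: experiment.yaml
    dt: auto                   # seconds, or "auto" = min membrane tau / 100
    t_end: 0.05                # seconds, required
    seed: 1
    output_dir: results
    hdf5: false                # also mirror outputs to HDF5
    overrides:                 # applied via the model container
      - {path: /cell/soma, param: RM, scale: 2.0}
    checkpoint: {every: 1000}  # steps; writes <output_dir>/checkpoint.npz
    iterate:                   # batch grid (cartesian product)
      - {path: /cell/soma, param: RM, values: [0.5, 1.0, 2.0]}
"""

from __future__ import annotations

import hashlib
import io
import itertools
import json
import time as _time
from dataclasses import dataclass, field, replace as _replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .control.controller import Controller
from .experiment.protocols import load_experiment
from .experiment.sequencer import sequence_events, validate_experiment
from .model.container import ModelContainer
from .outputs import write_hdf5, write_tsv
from .solver.cable import CableSolver, suggest_dt
from .solver.executor import CommandSequenceExecutor
from .solver.tables import TableRegistry

__all__ = ["SimulationConfig", "Simulation", "RunRecord", "schedule", "iterate", "resume"]

CONFIG_VERSION = 1


class SchedulerError(ValueError):
    pass


@dataclass
class Override:
    path: str
    param: str
    value: float | None = None
    scale: float | None = None


@dataclass
class SimulationConfig:
    model: Path
    t_end: float
    experiment: Path | None = None
    dt: float | str = "auto"
    seed: int = 0
    output_dir: Path = Path("results")
    hdf5: bool = False
    overrides: list[Override] = field(default_factory=list)
    protocol_overrides: list[dict] = field(default_factory=list)
    checkpoint_every: int | None = None
    iterate: list[dict] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise SchedulerError("config: expected a mapping")
        unknown = set(doc) - {"version", "model", "experiment", "dt", "t_end", "seed",
                              "output_dir", "hdf5", "overrides", "protocol_overrides",
                              "checkpoint", "iterate"}
        if unknown:
            raise SchedulerError(f"config: unknown key(s): {', '.join(sorted(unknown))}")
        if doc.get("version") != CONFIG_VERSION:
            raise SchedulerError(f"config: unsupported version {doc.get('version')!r}")
        base = path.parent
        ckpt = doc.get("checkpoint") or {}
        overrides = [
            Override(path=o["path"], param=o["param"], value=o.get("value"),
                     scale=o.get("scale"))
            for o in doc.get("overrides") or []
        ]
        return cls(
            model=base / doc["model"],
            experiment=(base / doc["experiment"]) if doc.get("experiment") else None,
            dt=doc.get("dt", "auto"),
            t_end=float(doc["t_end"]),
            seed=int(doc.get("seed", 0)),
            output_dir=base / doc.get("output_dir", "results"),
            hdf5=bool(doc.get("hdf5", False)),
            overrides=overrides,
            protocol_overrides=list(doc.get("protocol_overrides") or []),
            checkpoint_every=int(ckpt["every"]) if ckpt.get("every") else None,
            iterate=list(doc.get("iterate") or []),
        )

    def canonical(self) -> dict:
        return {
            "version": CONFIG_VERSION,
            "model": str(self.model),
            "experiment": str(self.experiment) if self.experiment else None,
            "dt": self.dt,
            "t_end": self.t_end,
            "seed": self.seed,
            "hdf5": self.hdf5,
            "overrides": [
                {"path": o.path, "param": o.param, "value": o.value, "scale": o.scale}
                for o in self.overrides
            ],
            "protocol_overrides": self.protocol_overrides,
            "checkpoint_every": self.checkpoint_every,
        }

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(self.canonical(), sort_keys=True).encode()).hexdigest()


@dataclass
class RunRecord:
    """Provenance sidecar for one run, written atomically at run end."""

    config_hash: str
    versions: dict[str, str]
    seed: int
    outputs: list[str]
    status: str = "completed"
    error: str | None = None
    checkpoint: str | None = None

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")
        tmp.replace(path)


class Simulation:
    """A fully wired, initialized simulation ready to run."""

    def __init__(self, config: SimulationConfig):
        if config.t_end <= 0:
            raise SchedulerError("t_end must be > 0")
        if not Path(config.model).exists():
            raise SchedulerError(f"model file not found: {config.model}")
        if config.experiment is not None and not Path(config.experiment).exists():
            raise SchedulerError(f"experiment file not found: {config.experiment}")
        self.config = config

        self.container = ModelContainer.from_file(config.model)
        for o in config.overrides:
            self.container.set_parameter(o.path, o.param, value=o.value, scale=o.scale)
        binding = self.container.expand()

        if config.dt == "auto":
            self.dt = min(suggest_dt(m) for m in binding.solvers)
        else:
            self.dt = float(config.dt)

        self.registry = TableRegistry()
        self.controller = Controller(dt=self.dt)
        self.solvers = [
            CableSolver(m, dt=self.dt, registry=self.registry) for m in binding.solvers
        ]
        for s in self.solvers:
            self.controller.register_solver(s)
        for wire in binding.wiring:
            self.controller.connect_spike(
                source=(wire.pre_solver, wire.pre_comp, wire.threshold),
                target=(wire.post_solver, wire.post_comp),
                weight=wire.weight, delay=wire.delay, tau=wire.tau, esyn=wire.esyn,
            )

        self.experiment = None
        if config.experiment is not None:
            with open(config.experiment, "r", encoding="utf-8") as fh:
                self.experiment = load_experiment(fh.read())
            for po in config.protocol_overrides:
                proto = self.experiment.protocols[int(po["protocol"])]
                if not hasattr(proto, po["param"]):
                    raise SchedulerError(f"protocol has no parameter {po['param']!r}")
                setattr(proto, po["param"], float(po["value"]))
            self.experiment.validate()
            report = validate_experiment(self.experiment, self.container.resolve_identifier)
            if not report.valid:
                detail = "; ".join(f"{p}: {r}" for p, r in report.failures)
                raise SchedulerError(f"experiment does not apply to model: {detail}")
            events = sequence_events(self.experiment.protocols, config.t_end,
                                     self.container.resolve_identifier)
            self.controller.register_executor(CommandSequenceExecutor(events, self.dt))
            for out in self.experiment.outputs:
                sid, vi = self.container.resolve_identifier(out.path, out.variable)
                self.controller.add_output(out.label, sid, vi, stride=out.stride)
        if not self.controller.outputs:
            # always record something: the root voltage of each solver
            for sid, m in enumerate(binding.solvers):
                comp = m.compartments[-1]
                self.controller.add_output(f"{comp.source_path}:Vm", sid,
                                           comp.index, stride=1)

    # -- persistence ------------------------------------------------------------
    def checkpoint_path(self) -> Path:
        return Path(self.config.output_dir) / "checkpoint.npz"

    def write_checkpoint(self) -> None:
        """Save all solver states + controller bookkeeping in one container."""
        path = self.checkpoint_path()
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "step": self.controller.clock.step,
            "dt": self.dt,
            "queue": self.controller.queue_dump(),
        }
        buf = io.BytesIO()
        np.savez(
            buf,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"solver_{i}": np.frombuffer(s.checkpoint(), dtype=np.uint8)
               for i, s in enumerate(self.solvers)},
        )
        path.write_bytes(buf.getvalue())

    def load_checkpoint(self, path) -> None:
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            for i, s in enumerate(self.solvers):
                s.load_checkpoint(bytes(data[f"solver_{i}"]))
        self.controller.clock.step = int(meta["step"])
        self.controller.queue_load(meta["queue"])
        for ex in self.controller.executors:
            ex.seek(self.controller.clock.step)
        self.controller.mark_resumed()

    # -- execution ----------------------------------------------------------------
    def run(self) -> RunRecord:
        cfg = self.config
        out_dir = Path(cfg.output_dir)
        record = RunRecord(config_hash=cfg.hash(), versions={"arborsim": __version__},
                           seed=cfg.seed, outputs=[])
        started = _time.time()
        try:
            if cfg.checkpoint_every:
                every = cfg.checkpoint_every

                def hook(controller):
                    if controller.clock.step % every == 0:
                        self.write_checkpoint()

                self.controller.run(cfg.t_end, callback=hook)
                record.checkpoint = str(self.checkpoint_path())
            else:
                self.controller.run(cfg.t_end)
        except ArithmeticError as exc:
            record.status = "failed"
            record.error = str(exc)
        record.outputs = self._flush_outputs(out_dir)
        record.write(out_dir / "run.json")
        self.elapsed = _time.time() - started
        return record

    def _flush_outputs(self, out_dir: Path) -> list[str]:
        """Group buffers by destination stream and write one TSV per stream."""
        by_dest: dict[str, list] = {}
        dests = {}
        if self.experiment is not None:
            dests = {o.label: o.destination for o in self.experiment.outputs}
        for buf in self.controller.outputs:
            by_dest.setdefault(dests.get(buf.label, "out"), []).append(buf)
        written = []
        header = {"config": self.config.hash(), "seed": str(self.config.seed),
                  "dt": repr(self.dt), "arborsim": __version__}
        for dest, bufs in by_dest.items():
            times = bufs[0].times
            for b in bufs[1:]:
                if b.times != times:
                    raise SchedulerError(
                        f"outputs in stream {dest!r} have mismatched sampling strides"
                    )
            columns = {b.label: np.asarray(b.values) for b in bufs}
            path = out_dir / f"{dest}.tsv"
            write_tsv(path, times, columns, header=header)
            written.append(str(path))
            if self.config.hdf5:
                h5path = out_dir / f"{dest}.h5"
                write_hdf5(h5path, times, columns, attrs=header)
                written.append(str(h5path))
        return written


def schedule(config: SimulationConfig) -> Simulation:
    """Instantiate and wire all components for one run (no numerical work)."""
    return Simulation(config)


def iterate(config: SimulationConfig) -> list[RunRecord]:
    """Run the batch grid: one independent simulation per grid point."""
    axes = []
    for entry in config.iterate:
        axes.append([(entry, v) for v in entry["values"]])
    if not axes or any(len(a) == 0 for a in axes):
        return []
    records: list[RunRecord] = []
    for idx, combo in enumerate(itertools.product(*axes)):
        point_overrides = list(config.overrides)
        point_proto = list(config.protocol_overrides)
        for entry, v in combo:
            if "protocol" in entry:
                point_proto.append({"protocol": entry["protocol"],
                                    "param": entry["param"], "value": float(v)})
            else:
                point_overrides.append(Override(path=entry["path"], param=entry["param"],
                                                value=float(v)))
        sub = _replace(
            config,
            overrides=point_overrides,
            protocol_overrides=point_proto,
            iterate=[],
            output_dir=Path(config.output_dir) / f"run_{idx:03d}",
        )
        try:
            records.append(schedule(sub).run())
        except Exception as exc:  # per-run isolation: record and continue
            rec = RunRecord(config_hash=sub.hash(), versions={"arborsim": __version__},
                            seed=sub.seed, outputs=[], status="failed", error=str(exc))
            rec.write(Path(sub.output_dir) / "run.json")
            records.append(rec)
    return records


def resume(config: SimulationConfig, checkpoint_path) -> RunRecord:
    """Rebuild the federation from config, restore state, and continue."""
    sim = schedule(config)
    sim.load_checkpoint(checkpoint_path)
    return sim.run()
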