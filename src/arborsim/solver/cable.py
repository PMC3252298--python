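"""Implicit compartmental solver: Crank-Nicolson on the Hines-ordered tree.

The membrane equation per compartment i,

    Cm_i dV_i/dt = -G_leak_i (V_i - E_leak_i)
                   - sum_ch Gmax_ch * prod_g x_g^p (V_i - E_ch)
                   - g_syn_i (V_i - E_syn_i) - g_clamp_i (V_i - V_cmd_i)
                   + sum_axial (V_j - V_i)/Ra_ij + I_inj_i,

is advanced with the trapezoidal (Crank-Nicolson) rule: conductances are
frozen over the step after the gate variables have been updated, and the
resulting linear system

    [(2Cm/dt) I + D - A] V' = [(2Cm/dt) I - D + A] V + 2 b

(D the diagonal of total membrane conductance, A the symmetric axial coupling
matrix, b the current-source vector) is solved by one elimination/back-
substitution sweep in Hines order — the leaf-to-root numbering makes the sweep
fill-in free and O(n).  The 2Cm/dt terms are folded into precomputed
coefficients at initialization, not recomputed per step.

Gate variables follow dm/dt = alpha(V)(1-m) - beta(V)m with the exact
exponential update over dt at the step's starting voltage (rates read from
shared tables by linear interpolation), which is unconditionally stable and
keeps m in [0, 1].  Gating and voltage are staggered, not iterated, per step.
"""

from __future__ import annotations

import io
import json

import numpy as np

from ..binding.types import CommandEvent, MathematicalModel
from .tables import (
    DEFAULT_DIVISIONS,
    DEFAULT_V_MAX,
    DEFAULT_V_MIN,
    TableRegistry,
    tabulate_gate,
)

__all__ = [
    "CableSolver",
    "IncompleteModelError",
    "NumericalDivergence",
    "CheckpointError",
    "suggest_dt",
]

CHECKPOINT_VERSION = 1


class IncompleteModelError(ValueError):
    """The binding lacks parameters required for simulation."""

    def __init__(self, missing: list[tuple[str, str]]):
        self.missing = list(missing)
        detail = "; ".join(f"{path}:{param}" for path, param in self.missing)
        super().__init__(f"model is not mathematically complete, missing: {detail}")


class NumericalDivergence(ArithmeticError):
    """Non-finite state detected; carries the global step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite solver state after step {step}")


class CheckpointError(ValueError):
    pass


def suggest_dt(model: MathematicalModel, fraction: float = 0.01) -> float:
    """A conservative default time step: ``fraction`` of the fastest membrane
    time constant Cm/G_leak in the model."""
    taus = [c.cm / c.g_leak for c in model.compartments if c.g_leak > 0]
    if not taus:
        raise IncompleteModelError([("<model>", "G_leak")])
    return fraction * min(taus)


class CableSolver:
    """One back-end instance solving one cell's branched cable."""

    def __init__(
        self,
        model: MathematicalModel,
        dt: float,
        registry: TableRegistry | None = None,
        v_min: float = DEFAULT_V_MIN,
        v_max: float = DEFAULT_V_MAX,
        divisions: int = DEFAULT_DIVISIONS,
        share_tables: bool = True,
    ):
        if not model.complete:
            raise IncompleteModelError(model.missing)
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.model = model
        self.dt = float(dt)
        self.fingerprint = model.structure_fingerprint()
        n = model.n_compartments
        self.n = n

        comps = model.compartments
        for i, c in enumerate(comps):
            if c.index != i:
                raise ValueError("compartments must be listed in index order")
            if c.parent_index is not None and c.parent_index <= i:
                raise ValueError("compartment ordering is not leaf-to-root (Hines)")

        self.parent = np.array(
            [-1 if c.parent_index is None else c.parent_index for c in comps], dtype=int
        )
        self.cm = np.array([c.cm for c in comps])
        self.g_leak = np.array([c.g_leak for c in comps])
        self.e_leak = np.array([c.e_leak for c in comps])
        v_init = np.array([c.v_init for c in comps])

        # axial coupling: g_ax[i] couples i to parent[i] (0 for the root)
        self.g_ax = np.array(
            [0.0 if c.parent_index is None else 1.0 / c.ra for c in comps]
        )
        self.ax_diag = np.zeros(n)
        for i in range(n - 1):
            self.ax_diag[i] += self.g_ax[i]
            self.ax_diag[self.parent[i]] += self.g_ax[i]

        # folded Crank-Nicolson coefficient (the init-time Cm*dt product)
        self.inv2cdt = 2.0 * self.cm / self.dt

        # flatten channel instances and their gates
        ch_comp, ch_gmax, ch_erev = [], [], []
        gate_comp, gate_power, gate_tid = [], [], []
        ch_gate_start = []
        self._table_keys: list[str] = []
        tables = []
        key_to_tid: dict[str, int] = {}
        self.table_config = (float(v_min), float(v_max), int(divisions))
        for c in comps:
            for ch in c.channels:
                ch_comp.append(c.index)
                ch_gmax.append(ch.gmax)
                ch_erev.append(ch.erev)
                ch_gate_start.append(len(gate_comp))
                for g in ch.gates:
                    table = tabulate_gate(
                        g.alpha, g.beta, v_min, v_max, divisions,
                        registry=registry if share_tables else None,
                    )
                    if share_tables:
                        tid = key_to_tid.get(table.key)
                        if tid is None:
                            tid = len(tables)
                            tables.append(table)
                            key_to_tid[table.key] = tid
                    else:
                        # no dedup: every gate gets its own (identical) rows
                        tid = len(tables)
                        tables.append(table)
                    gate_comp.append(c.index)
                    gate_power.append(g.power)
                    gate_tid.append(tid)

        self.ch_comp = np.array(ch_comp, dtype=int)
        self.ch_gmax = np.array(ch_gmax)
        self.ch_erev = np.array(ch_erev)
        self.ch_gate_start = np.array(ch_gate_start, dtype=int)
        self.gate_comp = np.array(gate_comp, dtype=int)
        self.gate_power = np.array(gate_power, dtype=float)
        self.gate_tid = np.array(gate_tid, dtype=int)
        self.n_gates = len(gate_comp)
        self.tables = tables
        if tables:
            self.tab_alpha = np.vstack([t.alpha for t in tables])
            self.tab_beta = np.vstack([t.beta for t in tables])
        else:
            self.tab_alpha = np.zeros((0, divisions + 1))
            self.tab_beta = np.zeros((0, divisions + 1))
        self._dv = (v_max - v_min) / divisions

        # dynamic state
        self.v = v_init.copy()
        self.gates = self._steady_gates(v_init)
        self.i_inj = np.zeros(n)
        self.syn_g = np.zeros(n)
        self.syn_esyn = np.zeros(n)
        self.syn_decay = np.ones(n)  # exp(-dt/tau) once a synapse is configured
        self.clamp_gain = np.zeros(n)
        self.clamp_v = np.zeros(n)
        self.step_count = 0

        self._snapshot = self._state_arrays_copy()

    # -- state helpers ---------------------------------------------------------
    @property
    def t(self) -> float:
        # integer step counting is authoritative; t is derived
        return self.step_count * self.dt

    def _state_arrays_copy(self) -> dict[str, np.ndarray]:
        return {
            "v": self.v.copy(),
            "gates": self.gates.copy(),
            "i_inj": self.i_inj.copy(),
            "syn_g": self.syn_g.copy(),
            "syn_esyn": self.syn_esyn.copy(),
            "syn_decay": self.syn_decay.copy(),
            "clamp_gain": self.clamp_gain.copy(),
            "clamp_v": self.clamp_v.copy(),
        }

    def _rates_at(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (alpha, beta) for every gate instance at voltages v."""
        v_min, _v_max, divisions = self.table_config
        with np.errstate(over="ignore", invalid="ignore"):
            x = (v - v_min) / self._dv
        x = np.clip(np.nan_to_num(x, nan=0.0, posinf=float(divisions), neginf=0.0),
                    0.0, float(divisions))
        idx = np.minimum(x.astype(int), divisions - 1)
        frac = x - idx
        tid = self.gate_tid
        a = self.tab_alpha[tid, idx] * (1.0 - frac) + self.tab_alpha[tid, idx + 1] * frac
        b = self.tab_beta[tid, idx] * (1.0 - frac) + self.tab_beta[tid, idx + 1] * frac
        return a, b

    def _steady_gates(self, v_comp: np.ndarray) -> np.ndarray:
        if self.n_gates == 0:
            return np.zeros(0)
        a, b = self._rates_at(v_comp[self.gate_comp])
        s = a + b
        return np.where(s > 0, a / np.where(s > 0, s, 1.0), 0.0)

    def state_value(self, index: int) -> float:
        """Read one state-vector entry (voltages first, then gate variables)."""
        if index < self.n:
            return float(self.v[index])
        return float(self.gates[index - self.n])

    # -- external inputs -------------------------------------------------------
    def configure_synapse(self, comp: int, tau: float, esyn: float) -> None:
        decay = float(np.exp(-self.dt / tau))
        if self.syn_decay[comp] != 1.0 and (
            self.syn_decay[comp] != decay or self.syn_esyn[comp] != esyn
        ):
            raise ValueError(
                f"compartment {comp} already carries a synapse with different tau/Esyn"
            )
        self.syn_decay[comp] = decay
        self.syn_esyn[comp] = esyn
        self._snapshot["syn_decay"] = self.syn_decay.copy()
        self._snapshot["syn_esyn"] = self.syn_esyn.copy()

    def deliver_spike(self, comp: int, weight: float) -> None:
        self.syn_g[comp] += weight

    def execute_commands(self, events: list[CommandEvent]) -> None:
        """Apply due events (already time-sorted; later declarations win ties)."""
        for e in events:
            comp = e.target[1]
            if e.opcode == "set_current":
                self.i_inj[comp] = e.payload
            elif e.opcode == "set_clamp":
                self.clamp_gain[comp] = e.gain if e.gain is not None else 0.0
                self.clamp_v[comp] = e.payload
            elif e.opcode == "stop_clamp":
                self.clamp_gain[comp] = 0.0
            else:
                raise ValueError(f"unknown opcode {e.opcode!r}")

    # -- time stepping ----------------------------------------------------------
    def advance(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self._step()

    def _step(self) -> None:
        n = self.n
        v = self.v
        dt = self.dt

        if self.n_gates:
            a, b = self._rates_at(v[self.gate_comp])
            s = a + b
            inf = np.where(s > 0, a / np.where(s > 0, s, 1.0), 0.0)
            self.gates = inf + (self.gates - inf) * np.exp(-dt * s)
            powered = self.gates**self.gate_power
            prod = np.multiply.reduceat(powered, self.ch_gate_start)
            g_ch = self.ch_gmax * prod
            g_chan = np.bincount(self.ch_comp, weights=g_ch, minlength=n)
            b_chan = np.bincount(self.ch_comp, weights=g_ch * self.ch_erev, minlength=n)
        else:
            g_chan = 0.0
            b_chan = 0.0

        self.syn_g = self.syn_g * self.syn_decay

        d_total = self.g_leak + g_chan + self.syn_g + self.clamp_gain
        b_total = (
            self.g_leak * self.e_leak
            + b_chan
            + self.syn_g * self.syn_esyn
            + self.clamp_gain * self.clamp_v
            + self.i_inj
        )

        # axial flux A @ v via the link list
        av = np.zeros(n)
        if n > 1:
            child = np.arange(n - 1)
            par = self.parent[:-1]
            flux = self.g_ax[:-1] * (v[par] - v[child])
            np.add.at(av, child, flux)
            np.add.at(av, par, -flux)

        rhs = (self.inv2cdt - d_total) * v + av + 2.0 * b_total
        diag = self.inv2cdt + d_total + self.ax_diag

        # Hines sweep: ascending elimination (children first), then back-substitution
        d = diag.copy()
        r = rhs.copy()
        g_ax = self.g_ax
        parent = self.parent
        with np.errstate(over="ignore", invalid="ignore"):  # divergence caught below
            for i in range(n - 1):
                p = parent[i]
                f = g_ax[i] / d[i]
                d[p] -= g_ax[i] * f
                r[p] += r[i] * f
            v_new = np.empty(n)
            v_new[n - 1] = r[n - 1] / d[n - 1]
            for i in range(n - 2, -1, -1):
                v_new[i] = (r[i] + g_ax[i] * v_new[parent[i]]) / d[i]

        self.v = v_new
        self.step_count += 1
        if not np.all(np.isfinite(v_new)):
            raise NumericalDivergence(self.step_count)

    # -- reset / checkpoint ------------------------------------------------------
    def reset(self) -> None:
        """Restore the post-initialization state bitwise."""
        for name, arr in self._snapshot.items():
            setattr(self, name, arr.copy())
        self.step_count = 0

    _CKPT_ARRAYS = ("v", "gates", "i_inj", "syn_g", "syn_esyn", "syn_decay",
                    "clamp_gain", "clamp_v")

    def checkpoint(self) -> bytes:
        """Serialize the full dynamic state to a versioned binary blob."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "fingerprint": self.fingerprint,
            "dt": self.dt,
            "step_count": self.step_count,
        }
        buf = io.BytesIO()
        np.savez(
            buf,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{name: getattr(self, name) for name in self._CKPT_ARRAYS},
        )
        return buf.getvalue()

    def load_checkpoint(self, blob: bytes) -> None:
        """Restore state from :meth:`checkpoint`; the binding must match."""
        with np.load(io.BytesIO(blob)) as data:
            try:
                meta = json.loads(bytes(data["meta"]).decode())
            except Exception as exc:
                raise CheckpointError(f"unreadable checkpoint metadata: {exc}") from exc
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(f"unsupported checkpoint version {meta.get('version')!r}")
            if meta["fingerprint"] != self.fingerprint:
                raise CheckpointError("checkpoint was taken against a different model binding")
            for name in self._CKPT_ARRAYS:
                arr = data[name]
                if arr.shape != getattr(self, name).shape:
                    raise CheckpointError(f"checkpoint array {name!r} has mismatched shape")
                setattr(self, name, arr.copy())
            self.dt = float(meta["dt"])
            self.inv2cdt = 2.0 * self.cm / self.dt
            self.step_count = int(meta["step_count"])

    @classmethod
    def restore(cls, blob: bytes, model: MathematicalModel,
                registry: TableRegistry | None = None, **kwargs) -> "CableSolver":
        """Rebuild a solver from a binding and resume from a checkpoint."""
        with np.load(io.BytesIO(blob)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
        solver = cls(model, dt=float(meta["dt"]), registry=registry, **kwargs)
        solver.load_checkpoint(blob)
        return solver
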