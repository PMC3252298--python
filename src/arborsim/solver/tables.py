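"""Tabulated gate kinetics with automatic de-duplication.

Rate functions alpha(V), beta(V) are sampled on a uniform voltage grid once
and shared: a registry keyed by the canonical parameterization (rate-law
family + coefficients + grid) guarantees that identical gate kinetics — a
common occurrence when the same channel type appears on many compartments —
are tabulated exactly once.  Accuracy is user-settable through the grid range
and division count; lookups between nodes interpolate linearly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ..kinetics import RateLaw

__all__ = ["RateTable", "TableRegistry", "TabulationError", "tabulate_gate",
           "DEFAULT_V_MIN", "DEFAULT_V_MAX", "DEFAULT_DIVISIONS"]

DEFAULT_V_MIN = -0.100  # V
DEFAULT_V_MAX = 0.050  # V
DEFAULT_DIVISIONS = 3000


class TabulationError(ValueError):
    pass


@dataclass(frozen=True)
class RateTable:
    """Sampled alpha/beta over [v_min, v_max] on ``divisions`` intervals."""

    v_min: float
    v_max: float
    divisions: int
    alpha: np.ndarray  # shape (divisions + 1,), 1/s
    beta: np.ndarray
    key: str  # canonical hash of (families, coefficients, grid)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.v_min, self.v_max, self.divisions + 1)

    def lookup(self, v):
        """Linearly interpolated (alpha, beta) at voltage ``v`` (clamped to range)."""
        g = self.grid
        return np.interp(v, g, self.alpha), np.interp(v, g, self.beta)


def _canonical_key(alpha: RateLaw, beta: RateLaw, v_min: float, v_max: float,
                   divisions: int) -> str:
    blob = repr((alpha.key(), beta.key(), float(v_min), float(v_max), int(divisions)))
    return hashlib.sha1(blob.encode()).hexdigest()


def tabulate_gate(
    alpha: RateLaw,
    beta: RateLaw,
    v_min: float = DEFAULT_V_MIN,
    v_max: float = DEFAULT_V_MAX,
    divisions: int = DEFAULT_DIVISIONS,
    registry: "TableRegistry | None" = None,
) -> RateTable:
    """Tabulate one gate's rate laws; identical parameterizations are shared.

    With a registry, a second call with the same parameterization returns the
    already-registered table object (registry size unchanged).
    """
    if divisions < 2:
        raise TabulationError("divisions must be >= 2")
    if not v_max > v_min:
        raise TabulationError("v_max must exceed v_min")
    key = _canonical_key(alpha, beta, v_min, v_max, divisions)
    if registry is not None:
        hit = registry.get(key)
        if hit is not None:
            return hit
    grid = np.linspace(v_min, v_max, divisions + 1)
    a = np.asarray(alpha(grid), dtype=float)
    b = np.asarray(beta(grid), dtype=float)
    for name, samples in (("alpha", a), ("beta", b)):
        if not np.all(np.isfinite(samples)):
            raise TabulationError(f"{name} rate law non-finite on tabulation range")
        if np.any(samples < 0):
            raise TabulationError(f"{name} rate law negative on tabulation range")
    a.setflags(write=False)
    b.setflags(write=False)
    table = RateTable(v_min=v_min, v_max=v_max, divisions=divisions,
                      alpha=a, beta=b, key=key)
    if registry is not None:
        registry.put(table)
    return table


@dataclass
class TableRegistry:
    """Shared store of tabulated kinetics, keyed by canonical parameterization."""

    _tables: dict[str, RateTable] = field(default_factory=dict)

    def get(self, key: str) -> RateTable | None:
        return self._tables.get(key)

    def put(self, table: RateTable) -> None:
        existing = self._tables.get(table.key)
        if existing is not None and existing is not table:
            return  # first registration wins; identical content by construction
        self._tables[table.key] = table

    def __len__(self) -> int:
        return len(self._tables)

    def __contains__(self, key: str) -> bool:
        return key in self._tables
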