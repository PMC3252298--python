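"""Unit handling for the declarative document dialect.

Internally everything is SI (m, s, V, A, S, F, ohm).  A document may carry a
top-level ``units:`` block declaring, per physical dimension, the unit its
numeric fields use; values are converted to SI on load.  Documents written by
:func:`arborsim.model.document.save_model` are always canonical SI (no units
block), which keeps round-trips exact.
"""

from __future__ import annotations

__all__ = ["UnitError", "UnitContext", "UNIT_FACTORS"]


class UnitError(ValueError):
    pass


#: factor mapping unit-name -> multiplier to SI, per dimension
UNIT_FACTORS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6},
    "area": {"m^2": 1.0, "cm^2": 1e-4, "mm^2": 1e-6, "um^2": 1e-12},
    "voltage": {"V": 1.0, "mV": 1e-3},
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6},
    "current": {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12},
    "conductance": {"S": 1.0, "mS": 1e-3, "uS": 1e-6, "nS": 1e-9, "pS": 1e-12},
    # mS/cm^2 = 1e-3 S / 1e-4 m^2 = 10 S/m^2
    "conductance_density": {"S/m^2": 1.0, "mS/cm^2": 10.0, "S/cm^2": 1e4},
    # uF/cm^2 = 1e-6 F / 1e-4 m^2 = 1e-2 F/m^2
    "capacitance_density": {"F/m^2": 1.0, "uF/cm^2": 1e-2},
    "axial_resistivity": {"ohm*m": 1.0, "ohm*cm": 1e-2},
    "membrane_resistance": {"ohm*m^2": 1.0, "ohm*cm^2": 1e-4, "kohm*cm^2": 0.1},
    "rate": {"1/s": 1.0, "1/ms": 1e3},
}


class UnitContext:
    """Per-document unit declarations, resolved to multiplicative SI factors."""

    def __init__(self, declarations: dict[str, str] | None = None):
        self._factors: dict[str, float] = {}
        for dim, unit in (declarations or {}).items():
            if dim not in UNIT_FACTORS:
                raise UnitError(f"unknown physical dimension {dim!r} in units block")
            try:
                self._factors[dim] = UNIT_FACTORS[dim][unit]
            except KeyError:
                known = ", ".join(sorted(UNIT_FACTORS[dim]))
                raise UnitError(
                    f"unknown unit {unit!r} for dimension {dim!r} (known: {known})"
                ) from None

    def factor(self, dimension: str) -> float:
        if dimension not in UNIT_FACTORS:
            raise UnitError(f"unknown physical dimension {dimension!r}")
        return self._factors.get(dimension, 1.0)

    def convert(self, value, dimension: str):
        """Convert ``value`` (number, or None) in declared units to SI."""
        if value is None:
            return None
        return float(value) * self.factor(dimension)
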