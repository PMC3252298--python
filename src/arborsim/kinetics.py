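"""Voltage-dependent rate-law families for channel gate kinetics.

A gate variable x obeys dx/dt = alpha(V) (1 - x) - beta(V) x, with alpha and
beta drawn from one of a small set of parametric families.  All quantities are
SI: voltages in volts, rates in 1/s.  This module is a leaf: it has no
dependencies inside the package, so both the biological layer (validation) and
the numerical layer (tabulation) may use it without coupling to each other.

Families
--------
``exp_linear``  A * (V - V0) / (1 - exp(-(V - V0) / K))
    The classic "linoid" form; the removable singularity at V = V0 is filled
    with its limit A * K.  Params: (A [1/(V s)], V0 [V], K [V]).
``exponential`` A * exp((V - V0) / K).  Params: (A [1/s], V0 [V], K [V]).
``sigmoid``     A / (1 + exp(-(V - V0) / K)).  Params: (A [1/s], V0 [V], K [V]).
``constant``    A.  Params: (A [1/s],).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RateLaw", "FAMILIES", "KineticsError"]

FAMILIES = {
    "exp_linear": ("A", "V0", "K"),
    "exponential": ("A", "V0", "K"),
    "sigmoid": ("A", "V0", "K"),
    "constant": ("A",),
}

# exp() argument clip; generous for physiological voltages but prevents
# overflow on pathological parameter sets during validation sweeps.
_EXP_CLIP = 500.0


class KineticsError(ValueError):
    """Invalid rate-law family or parameters."""


@dataclass(frozen=True)
class RateLaw:
    """A parameterized voltage-dependent rate function, rate(V) in 1/s."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise KineticsError(f"unknown rate-law family {self.family!r}")
        expected = len(FAMILIES[self.family])
        if len(self.params) != expected:
            raise KineticsError(
                f"family {self.family!r} takes {expected} parameters "
                f"{FAMILIES[self.family]}, got {len(self.params)}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def __call__(self, v):
        """Evaluate the rate at membrane voltage ``v`` (volts; scalar or array)."""
        v = np.asarray(v, dtype=float)
        if self.family == "constant":
            (a,) = self.params
            return np.full_like(v, a)
        a, v0, k = self.params
        if k == 0.0:
            raise KineticsError("rate-law slope parameter K must be nonzero")
        x = np.clip((v - v0) / k, -_EXP_CLIP, _EXP_CLIP)
        if self.family == "exponential":
            return a * np.exp(x)
        if self.family == "sigmoid":
            return a / (1.0 + np.exp(-x))
        # exp_linear: A*K * x / (1 - exp(-x)) with limit A*K at x = 0
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            denom = -np.expm1(-x)
            out = np.where(np.abs(x) < 1e-9, a * k * (1.0 + x / 2.0), a * k * x / denom)
        return out

    def key(self) -> tuple:
        """Canonical identity of this parameterization (for table dedup)."""
        return (self.family, self.params)
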