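"""Free-Ca2+ calculator for patch-clamp recording solutions.

Solves 1:1 complexation equilibria of Ca2+ (and optionally Mg2+) with one or
more buffers (EGTA, gluconate, ...) by mass balance:

    Ca_total = Ca_free * (1 + sum_i B_i,free / Kd_i)
    B_i,free = B_i,total / (1 + Ca_free/Kd_Ca,i + Mg_free/Kd_Mg,i)

with an analogous balance for Mg2+ where a buffer binds both ions.  All
concentrations and dissociation constants are in mM; Kd values are apparent
(pH-lumped) constants at the working pH — no proton-competition, ionic
strength, or temperature model is applied.

The shipped ``LITERATURE_KD`` values for EGTA are typical apparent constants
at the indicated pH from the buffer-calculator literature; the gluconate
Kd is back-computed from the ~88% bound fraction at 140 mM gluconate.  None
of these constants should be treated as authoritative for a specific lab
solution without calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.optimize import brentq

__all__ = [
    "BufferSpecies",
    "BufferSystem",
    "solve_free_ca",
    "total_ca_for_target",
    "bound_fractions",
    "LITERATURE_KD",
]

# Apparent 1:1 dissociation constants (mM). Non-authoritative convenience
# values; see module docstring.
LITERATURE_KD = {
    "egta_ph7.1": 4.9e-4,   # ~0.5 uM apparent Kd_Ca of EGTA near pH 7.1
    "egta_ph7.4": 1.0e-4,   # ~0.1 uM near pH 7.4
    "egta_mg_ph7.1": 9.0,   # EGTA binds Mg2+ only weakly at neutral pH
    "gluconate_ca": 19.1,   # from 88% of Ca2+ bound by 140 mM gluconate
}


@dataclass(frozen=True)
class BufferSpecies:
    """One chelator: total concentration and apparent Kd values (mM)."""

    name: str
    total: float  # mM
    kd_ca: float  # mM, apparent at working pH
    kd_mg: float | None = None  # mM, or None if Mg binding negligible

    def __post_init__(self):
        if self.total < 0:
            raise ValueError("buffer total must be >= 0")
        if self.kd_ca <= 0 or (self.kd_mg is not None and self.kd_mg <= 0):
            raise ValueError("Kd values must be > 0")


@dataclass(frozen=True)
class BufferSystem:
    """A recording solution: buffers plus total divalent content (mM)."""

    buffers: tuple[BufferSpecies, ...]
    ca_total: float
    mg_total: float = 0.0
    ph: float | None = None  # metadata only

    def __post_init__(self):
        object.__setattr__(self, "buffers", tuple(self.buffers))
        if self.ca_total < 0 or self.mg_total < 0:
            raise ValueError("totals must be >= 0")


def _free_buffer(buf: BufferSpecies, ca_free: float, mg_free: float) -> float:
    denom = 1.0 + ca_free / buf.kd_ca
    if buf.kd_mg is not None:
        denom += mg_free / buf.kd_mg
    return buf.total / denom


def _mg_free(system: BufferSystem, ca_free: float) -> float:
    """Free Mg2+ at the given free Ca2+, by bisection on the Mg balance."""
    if system.mg_total == 0.0:
        return 0.0

    def residual(mg):
        bound = sum(
            _free_buffer(b, ca_free, mg) * mg / b.kd_mg
            for b in system.buffers if b.kd_mg is not None
        )
        return mg + bound - system.mg_total

    if residual(system.mg_total) <= 0:  # no Mg-binding buffers
        return system.mg_total
    return brentq(residual, 0.0, system.mg_total, xtol=1e-15, rtol=8.9e-16)


def _ca_residual(system: BufferSystem, ca_free: float) -> float:
    mg = _mg_free(system, ca_free)
    bound = sum(
        _free_buffer(b, ca_free, mg) * ca_free / b.kd_ca for b in system.buffers
    )
    return ca_free + bound - system.ca_total


def solve_free_ca(system: BufferSystem) -> float:
    """Free [Ca2+] (mM) of the buffer system.

    Bisection on Ca_free over [0, Ca_total]; the mass-balance residual at the
    returned root is < 1e-9 of Ca_total.
    """
    if system.ca_total == 0.0:
        return 0.0
    if not system.buffers:
        return system.ca_total
    ca = brentq(lambda c: _ca_residual(system, c), 0.0, system.ca_total,
                xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return float(ca)


def bound_fractions(system: BufferSystem, ca_free: float | None = None) -> dict[str, float]:
    """Fraction of total Ca2+ bound by each buffer (keyed by buffer name)."""
    if ca_free is None:
        ca_free = solve_free_ca(system)
    if system.ca_total == 0:
        return {b.name: 0.0 for b in system.buffers}
    mg = _mg_free(system, ca_free)
    return {
        b.name: _free_buffer(b, ca_free, mg) * ca_free / b.kd_ca / system.ca_total
        for b in system.buffers
    }


def total_ca_for_target(system: BufferSystem, target_free: float) -> float:
    """Total Ca2+ (mM) needed to reach ``target_free`` free Ca2+ (mM).

    Direct evaluation of the mass balance at the target free concentration
    (the buffer occupancies are determined by the free concentrations, so no
    iteration over Ca_total is needed beyond the inner Mg solve).
    """
    if target_free <= 0:
        raise ValueError("target_free must be > 0")
    probe = BufferSystem(system.buffers, ca_total=target_free,
                         mg_total=system.mg_total, ph=system.ph)
    # Mg_free depends (weakly) on Ca_free only; evaluate at the target.
    mg = _mg_free(probe, target_free)
    bound = sum(
        _free_buffer(b, target_free, mg) * target_free / b.kd_ca
        for b in system.buffers
    )
    return float(target_free + bound)
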