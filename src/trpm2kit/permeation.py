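"""Ion-permeation analysis: GHK equations, bi-ionic permeability, reversal
potentials, conductance, and flux/geometry bookkeeping.

The central quantity is the Ca2+:Na+ permeability ratio of a Ca2+-permeable
cation channel measured under bi-ionic conditions (external divalent vs
internal monovalent).  With a divalent ion X2+ outside and a monovalent ion
M+ inside, the zero-current (reversal) potential E of the GHK current
equation satisfies the Fatt-Ginsborg relation

    P_X / P_M = ([M]_in / (4 [X]_out)) * exp(EF/RT) * (1 + exp(EF/RT))

which this module implements in both directions, together with a full
least-squares GHK i-V fit, a quadratic reversal-potential extrapolation
(used when the single-channel i-V is not GHK-shaped), slope conductance,
and the small flux / patch-geometry calculations that put unitary currents
into physical context (ions per microsecond, channel spacing, wash time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .constants import (
    DEFAULT_TEMPERATURE,
    ELEMENTARY_CHARGE,
    thermal_voltage_mv,
)

__all__ = [
    "IonSpecies",
    "IVCurve",
    "ReversalEstimate",
    "PermeabilityResult",
    "FitFailure",
    "biionic_permeability_ratio",
    "erev_from_permeability_ratio",
    "fit_ghk_iv",
    "quadratic_reversal",
    "slope_conductance",
    "flux_accounting",
    "charge_partition",
    "patch_microenvironment",
    "ghk_current",
]


class FitFailure(RuntimeError):
    """A least-squares fit failed; carries diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class IonSpecies:
    """A permeant ion with its valence and bath/pipette concentrations (mM)."""

    name: str
    valence: int
    conc_in: float
    conc_out: float

    def __post_init__(self):
        if self.valence == 0:
            raise ValueError("valence must be nonzero")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class IVCurve:
    """Unitary (or macroscopic) current-voltage relation.

    ``voltages_mv`` must be strictly increasing.  ``junction_potential_mv``
    is subtracted from the recorded voltages before any fit (0 if the
    recording was already corrected off-line).
    """

    voltages_mv: np.ndarray
    currents_pa: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    junction_potential_mv: float = 0.0

    def __post_init__(self):
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if self.voltages_mv.ndim != 1 or self.voltages_mv.shape != self.currents_pa.shape:
            raise ValueError("voltages and currents must be matching 1-D arrays")
        if np.any(np.diff(self.voltages_mv) <= 0):
            raise ValueError("voltages must be strictly increasing and unique")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def corrected_voltages_mv(self) -> np.ndarray:
        return self.voltages_mv - self.junction_potential_mv


@dataclass(frozen=True)
class ReversalEstimate:
    e_rev_mv: float
    method: str  # "ghk_fit" | "quadratic" | "linear"
    fit_residual: float = 0.0
    extrapolated: bool = False
    coefficients: tuple = ()

    def __post_init__(self):
        if not math.isfinite(self.e_rev_mv):
            raise ValueError("reversal potential must be finite")


@dataclass(frozen=True)
class PermeabilityResult:
    p_ratio: float  # P_divalent / P_monovalent
    e_rev_used_mv: float
    conditions: tuple = ()  # (inside IonSpecies, outside IonSpecies) when known

    def __post_init__(self):
        if self.p_ratio <= 0:
            raise ValueError("permeability ratio must be > 0")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


def biionic_permeability_ratio(
    e_rev_mv: float,
    ca_out_mm: float,
    na_in_mm: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PermeabilityResult:
    """P_Ca/P_Na from the bi-ionic reversal potential (Fatt-Ginsborg).

    ``e_rev_mv`` is the corrected reversal potential under bi-ionic
    conditions with Ca2+ as the only external and Na+ as the only internal
    permeant cation.
    """
    _check_positive(ca_out_mm=ca_out_mm, na_in_mm=na_in_mm, temperature=temperature)
    x = math.exp(e_rev_mv / thermal_voltage_mv(temperature))
    ratio = (na_in_mm / (4.0 * ca_out_mm)) * x * (1.0 + x)
    inside = IonSpecies("Na", 1, na_in_mm, 0.0)
    outside = IonSpecies("Ca", 2, 0.0, ca_out_mm)
    return PermeabilityResult(ratio, e_rev_mv, (inside, outside))


def erev_from_permeability_ratio(
    p_ratio: float,
    ca_out_mm: float,
    na_in_mm: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Inverse of :func:`biionic_permeability_ratio` (closed form, in mV).

    Solving ratio = (Na/(4 Ca)) x (1+x) for x = exp(EF/RT) gives the unique
    positive root of x^2 + x - 4 Ca ratio / Na; the result is monotone
    increasing in ``p_ratio``.
    """
    _check_positive(p_ratio=p_ratio, ca_out_mm=ca_out_mm, na_in_mm=na_in_mm,
                    temperature=temperature)
    c = 4.0 * ca_out_mm * p_ratio / na_in_mm
    x = 0.5 * (-1.0 + math.sqrt(1.0 + 4.0 * c))
    return thermal_voltage_mv(temperature) * math.log(x)


def _ghk_flux_term(u: np.ndarray, z: int, c_in: float, c_out: float) -> np.ndarray:
    """z^2 * u * (c_in - c_out e^{-zu}) / (1 - e^{-zu}) with the u->0 limit."""
    zu = z * u
    out = np.empty_like(np.asarray(zu, dtype=float))
    small = np.abs(zu) < 1e-8
    with np.errstate(over="ignore"):
        e = np.exp(-zu)
    nz = ~small
    out[nz] = z * z * u[nz] * (c_in - c_out * e[nz]) / (1.0 - e[nz])
    # series: u/(1-e^{-zu}) -> 1/z as u->0
    out[small] = z * (c_in - c_out) + 0.5 * z * zu[small] * (c_in + c_out)
    return out


def ghk_current(
    v_mv: np.ndarray,
    scale: float,
    p_ratio: float,
    monovalent: IonSpecies,
    divalent: IonSpecies,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """GHK current (arbitrary scale): monovalent term + p_ratio * divalent term."""
    u = np.asarray(v_mv, dtype=float) / thermal_voltage_mv(temperature)
    j = _ghk_flux_term(u, monovalent.valence, monovalent.conc_in, monovalent.conc_out)
    j = j + p_ratio * _ghk_flux_term(u, divalent.valence, divalent.conc_in,
                                     divalent.conc_out)
    return scale * j


def fit_ghk_iv(
    iv: IVCurve,
    inside: IonSpecies,
    outside: IonSpecies,
) -> tuple[PermeabilityResult, ReversalEstimate]:
    """Least-squares GHK fit of an i-V relation.

    ``inside``/``outside`` name the dominant monovalent and divalent species;
    the one with |valence| == 1 is taken as the reference permeability.  Free
    parameters are an overall scale and the divalent:monovalent permeability
    ratio.  Returns the fitted ratio and the zero-current voltage of the
    fitted curve.
    """
    if len(iv.voltages_mv) < 4:
        raise ValueError("need at least 4 i-V points for a GHK fit")
    species = sorted([inside, outside], key=lambda s: abs(s.valence))
    mono, di = species
    if abs(mono.valence) != 1 or abs(di.valence) != 2:
        raise ValueError("GHK fit expects one monovalent and one divalent species")

    v = iv.corrected_voltages_mv
    i_obs = iv.currents_pa

    if di.conc_in == 0 and di.conc_out == 0:
        # monovalent-only data: the ratio is unidentifiable; fit the scale
        # alone and report a unit ratio
        def model1(vv, scale):
            return ghk_current(vv, scale, 0.0, mono, di, iv.temperature)
        popt, _ = optimize.curve_fit(model1, v, i_obs, p0=[1e-3], maxfev=20000)
        resid = float(np.sum((model1(v, *popt) - i_obs) ** 2))
        e_rev = optimize.brentq(lambda vv: model1(np.array([vv]), *popt)[0],
                                v.min() - 200.0, v.max() + 200.0)
        perm = PermeabilityResult(1.0, float(e_rev), (inside, outside))
        rev = ReversalEstimate(float(e_rev), "ghk_fit", resid,
                               not (v.min() <= e_rev <= v.max()),
                               coefficients=(float(popt[0]), 1.0))
        return perm, rev

    def model(vv, scale, ratio):
        return ghk_current(vv, scale, ratio, mono, di, iv.temperature)

    # scale sign from the data slope; ratio started at 1
    slope0 = np.polyfit(v, i_obs, 1)[0]
    ref = model(v, 1.0, 1.0)
    s0 = slope0 / max(np.polyfit(v, ref, 1)[0], 1e-30)
    try:
        popt, pcov = optimize.curve_fit(
            model, v, i_obs, p0=[s0 if s0 != 0 else 1e-3, 1.0],
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailure("GHK i-V fit did not converge", error=str(exc)) from exc
    scale, ratio = popt
    resid = float(np.sum((model(v, *popt) - i_obs) ** 2))
    if not np.isfinite(pcov).all() or scale == 0:
        raise FitFailure("degenerate GHK fit", residual=resid, params=tuple(popt))

    lo, hi = v.min() - 200.0, v.max() + 200.0
    try:
        e_rev = optimize.brentq(lambda vv: model(np.array([vv]), *popt)[0], lo, hi)
    except ValueError as exc:
        raise FitFailure("fitted GHK curve does not reverse in range",
                         residual=resid, params=tuple(popt)) from exc
    extrap = not (v.min() <= e_rev <= v.max())
    perm = PermeabilityResult(float(ratio), float(e_rev), (inside, outside))
    rev = ReversalEstimate(float(e_rev), "ghk_fit", resid, extrap,
                           coefficients=tuple(popt))
    return perm, rev


def quadratic_reversal(
    iv: IVCurve,
    v_window: tuple[float, float] | None = None,
) -> ReversalEstimate:
    """Reversal potential by quadratic extrapolation of the i-V plot.

    Fits i = aV^2 + bV + c over the window and returns the real root nearest
    the sampled voltage range (ties broken toward 0 mV).  Roots outside the
    data range are flagged as extrapolated.  Used when single-channel
    currents cannot be resolved near the reversal potential.
    """
    v = iv.corrected_voltages_mv
    i = iv.currents_pa
    if v_window is not None:
        lo, hi = v_window
        mask = (v >= lo) & (v <= hi)
        v, i = v[mask], i[mask]
    if len(v) < 3:
        raise ValueError("need at least 3 points in the window")

    a, b, c = np.polyfit(v, i, 2)
    resid = float(np.sum((np.polyval([a, b, c], v) - i) ** 2))
    # near-degenerate quadratic -> linear root
    if abs(a) * max(np.abs(v)) ** 2 < 1e-9 * max(abs(b) * np.abs(v).max(), abs(c), 1e-30):
        if b == 0:
            raise FitFailure("flat i-V: no root", coefficients=(a, b, c))
        root = -c / b
        extrap = not (v.min() <= root <= v.max())
        return ReversalEstimate(float(root), "linear", resid, extrap, (a, b, c))

    disc = b * b - 4 * a * c
    if disc < 0:
        raise FitFailure("quadratic has no real root", coefficients=(a, b, c),
                         residual=resid)
    r1 = (-b + math.sqrt(disc)) / (2 * a)
    r2 = (-b - math.sqrt(disc)) / (2 * a)

    def dist(root):
        if v.min() <= root <= v.max():
            return 0.0
        return min(abs(root - v.min()), abs(root - v.max()))

    d1, d2 = dist(r1), dist(r2)
    if math.isclose(d1, d2, rel_tol=1e-12, abs_tol=1e-12):
        root = min(r1, r2, key=abs)  # tie toward 0 mV
    else:
        root = r1 if d1 < d2 else r2
    extrap = not (v.min() <= root <= v.max())
    return ReversalEstimate(float(root), "quadratic", resid, extrap, (a, b, c))


def slope_conductance(
    iv: IVCurve,
    v_window: tuple[float, float] | None = None,
) -> float:
    """Least-squares slope conductance in pS over the voltage window."""
    v = iv.corrected_voltages_mv
    i = iv.currents_pa
    if v_window is not None:
        lo, hi = v_window
        mask = (v >= lo) & (v <= hi)
        v, i = v[mask], i[mask]
    if len(v) < 2:
        raise ValueError("need at least 2 points in the window")
    slope = np.polyfit(v, i, 1)[0]  # pA/mV = nS
    return float(slope * 1000.0)


def flux_accounting(current_pa: float, valence: int, duration_s: float) -> float:
    """Number of ions moved by ``current_pa`` over ``duration_s``.

    count = |I| * t / (|z| * e).  0.6 pA of Ca2+ current over 1 μs moves
    ~1.9 (≈2) ions.
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    return abs(current_pa) * 1e-12 * duration_s / (abs(valence) * ELEMENTARY_CHARGE)


def charge_partition(
    count_fractions: Mapping[str, float],
    valences: Mapping[str, int],
) -> dict[str, float]:
    """Convert ion-count fractions into charge(current)-carried fractions.

    charge fraction of s = f_s |z_s| / sum_k f_k |z_k|.  E.g. if 85% of
    entering cations are Na+ and 15% Ca2+, Na+ carries ~74% of the current.
    """
    total = sum(count_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"count fractions must sum to 1, got {total}")
    weights = {}
    for name, f in count_fractions.items():
        z = valences[name]
        if z == 0:
            raise ValueError(f"valence of {name} must be nonzero")
        if f < 0:
            raise ValueError("fractions must be >= 0")
        weights[name] = f * abs(z)
    norm = sum(weights.values())
    return {name: w / norm for name, w in weights.items()}


def patch_microenvironment(
    flow_speed_m_s: float | None = None,
    channel_footprint_m: float | None = None,
    density_per_um2: float | None = None,
) -> dict[str, float]:
    """Back-of-envelope patch microenvironment numbers.

    * ``wash_time_s`` = footprint / flow speed: time for the superfusing bath
      to replace the solution in contact with one channel.
    * ``spacing_nm`` = 1/sqrt(density) on a square lattice: mean pore-to-pore
      distance at the given channel density (channels/μm²).

    Only the quantities whose inputs were supplied are returned.
    """
    out: dict[str, float] = {}
    if flow_speed_m_s is not None and channel_footprint_m is not None:
        _check_positive(flow_speed_m_s=flow_speed_m_s,
                        channel_footprint_m=channel_footprint_m)
        out["wash_time_s"] = channel_footprint_m / flow_speed_m_s
    if density_per_um2 is not None:
        _check_positive(density_per_um2=density_per_um2)
        out["spacing_nm"] = 1000.0 / math.sqrt(density_per_um2)
    if not out:
        raise ValueError("no inputs supplied")
    return out
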