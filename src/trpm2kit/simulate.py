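"""Stochastic simulator of ADPR + Ca2+ co-gated, Ca2+-permeable channels.

Each channel is a two-state (closed <-> open) continuous-time Markov chain:

* opening rate   k_o = gate_ADPR * f_PIP2 * (k_spont + k_open_max * H([Ca]_site))
  with the Hill occupancy H(c) = c^n / (K_act^n + c^n),
* closing rate   k_c = k_close0 * exp(-z_gate * V * F / RT)
  (mild intrinsic voltage dependence of closure).

[Ca]_site, the Ca2+ concentration at the cytosolic activating site, is the
bulk cytosolic free Ca2+ plus a per-channel local component fed by Ca2+
influx through the channel's own open pore: while the pore is open (and
external Ca2+ is present at voltages below the Ca2+ reversal potential) the
local component relaxes toward a driving-force-scaled flood level; after
closure it decays with time constant ``tau_clear``.  This lumped relaxation
reproduces the hallmark feedback phenomenology of highly Ca2+-permeable
channels: currents that survive removal of bulk cytosolic Ca2+ at negative
voltages (steady open probability well above zero), prolongation of
deactivation time constants by external Ca2+ at moderately positive
voltages, and delayed self-activation by ADPR alone.

The unitary current is ohmic, g*(V - E_rev), reduced by cytosolic Ca2+ pore
block with a simple 1:1 inhibition curve K_block/(K_block + [Ca]_cyto).

Event times are sampled exactly (Gillespie with thinning for the
time-varying opening rate) and the summed channel current is sampled-and-
held onto the output grid with additive Gaussian noise.  Identical
parameters + protocol + seed give bit-identical traces.

Simulator rates are not measured quantities; the named presets are chosen
so that the observable behavior (K1/2 of the open-probability dose-response,
deactivation time constants of tens of milliseconds, a feedback plateau
near open probability 0.2) lands in physiologically reported ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_voltage_mv
from .gating import CurrentTrace, Epoch

__all__ = [
    "GatingParams",
    "SimProtocol",
    "SimResult",
    "simulate_patch",
    "dose_response_dataset",
    "deactivation_protocol",
    "k_open",
    "k_close",
    "equilibrium_po",
    "PRESETS",
    "preset",
]

REFERENCE_VOLTAGE = -20.0  # mV; presets are calibrated at this potential


@dataclass(frozen=True)
class GatingParams:
    """Two-state gating model parameters.

    ``k_half`` is the observable half-activating cytosolic [Ca2+] of the
    equilibrium open probability at the -20 mV reference voltage; the
    rate-law constant K_act is derived from it (for a two-state channel the
    equilibrium dose-response is itself Hill-shaped with
    K_eff = K_act / (1 + k_open_max/k_close)^(1/n)).
    """

    k_open_max: float = 40.0  # s^-1, fully Ca2+-liganded opening rate
    k_close0: float = 20.0  # s^-1 at 0 mV
    z_gate: float = 0.15  # effective gating charge of closure
    k_half: float = 2.0  # μM, half-activation of equilibrium P_o at -20 mV
    n_act: float = 1.0  # Hill coefficient of activation
    g_unitary: float = 150.0  # pS
    e_rev: float = 0.0  # mV
    k_block: float = 1000.0  # μM, cytosolic Ca2+ block of unitary current
    ca_local_open: float = 7.0  # μM, open-pore site Ca2+ at -20 mV, 1 mM ext Ca2+
    tau_clear: float = 0.3  # s, local Ca2+ relaxation time constant
    e_rev_ca: float = 60.0  # mV, zero-driving-force voltage for Ca2+ influx
    k_spont: float = 0.05  # s^-1, Ca2+-independent opening of ADPR-bound channels
    pip2_open_factor: float = 1.15  # opening-rate multiplier with PIP2 present
    requires_adpr: bool = True
    n_channels: int = 4
    noise_sd: float = 0.3  # pA
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        for name in ("k_open_max", "k_close0", "k_half", "g_unitary",
                     "k_block", "tau_clear"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_act < 1:
            raise ValueError("n_act must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd < 0 or self.k_spont < 0 or self.ca_local_open < 0:
            raise ValueError("noise_sd, k_spont, ca_local_open must be >= 0")

    @property
    def K_act(self) -> float:
        """Rate-law Hill constant (μM) implied by ``k_half`` at -20 mV."""
        r = self.k_open_max / k_close(self, REFERENCE_VOLTAGE)
        return self.k_half * (1.0 + r) ** (1.0 / self.n_act)


@dataclass(frozen=True)
class SimProtocol:
    """Epoch sequence plus sampling and pipette (extracellular) conditions."""

    epochs: tuple[Epoch, ...]
    sampling_rate: float = 5000.0  # Hz
    seed: int = 0
    ca_ext_mm: float = 0.0  # pipette free Ca2+, mM

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.ca_ext_mm < 0:
            raise ValueError("ca_ext_mm must be >= 0")
        t = 0.0
        for ep in self.epochs:
            if abs(ep.start - t) > 1e-9:
                raise ValueError("epochs must be contiguous from t=0")
            t = ep.end

    @property
    def duration(self) -> float:
        return self.epochs[-1].end


@dataclass
class SimResult:
    trace: CurrentTrace
    true_po_per_epoch: list[float]
    event_log: list[tuple[float, int, int]]  # (time, channel, new occupancy 0/1)
    params_echo: GatingParams
    protocol_echo: SimProtocol

    @property
    def unitary_current_pa(self) -> dict[int, float]:
        """Blocked unitary current (pA) per epoch index."""
        out = {}
        for idx, ep in enumerate(self.protocol_echo.epochs):
            out[idx] = unitary_current(self.params_echo, ep.voltage,
                                       ep.ca_cyto_free)
        return out


# ---------------------------------------------------------------------------
# rate laws

def k_close(params: GatingParams, voltage_mv: float) -> float:
    """Closing rate (s^-1) at the given membrane potential."""
    vt = thermal_voltage_mv(params.temperature)
    return params.k_close0 * math.exp(-params.z_gate * voltage_mv / vt)


def k_open(params: GatingParams, ca_site_um: float, adpr_um: float = 100.0,
           pip2_um: float = 0.0) -> float:
    """Opening rate (s^-1) at the given site Ca2+ and ligand conditions."""
    if params.requires_adpr and adpr_um <= 0:
        return 0.0
    h = ca_site_um ** params.n_act / (
        params.K_act ** params.n_act + ca_site_um ** params.n_act
    ) if ca_site_um > 0 else 0.0
    f = params.pip2_open_factor if pip2_um > 0 else 1.0
    return f * (params.k_spont + params.k_open_max * h)


def equilibrium_po(params: GatingParams, ca_um: float, voltage_mv: float,
                   adpr_um: float = 100.0, pip2_um: float = 0.0) -> float:
    """Equilibrium open probability without influx feedback."""
    ko = k_open(params, ca_um, adpr_um, pip2_um)
    if ko == 0.0:
        return 0.0
    return ko / (ko + k_close(params, voltage_mv))


def unitary_current(params: GatingParams, voltage_mv: float,
                    ca_cyto_um: float = 0.0) -> float:
    """Unitary current (pA) including cytosolic Ca2+ pore block."""
    block = params.k_block / (params.k_block + ca_cyto_um)
    return params.g_unitary * (voltage_mv - params.e_rev) * 1e-3 * block


def _flood_level(params: GatingParams, voltage_mv: float, ca_ext_mm: float) -> float:
    """Open-pore local site Ca2+ (μM) sustained by influx."""
    if ca_ext_mm <= 0 or voltage_mv >= params.e_rev_ca:
        return 0.0
    drive = (params.e_rev_ca - voltage_mv) / (params.e_rev_ca - REFERENCE_VOLTAGE)
    return params.ca_local_open * drive * ca_ext_mm


# ---------------------------------------------------------------------------
# core simulation

def _simulate_channel(params: GatingParams, protocol: SimProtocol,
                      rng: np.random.Generator):
    """Exact event times for one channel; returns (events, open_time_per_epoch).

    The opening hazard decays monotonically within a closed interval (the
    local Ca2+ only decreases while the pore is closed and bulk conditions
    are constant within an epoch), so thinning with the interval-start
    hazard as the bound samples the next opening exactly.
    """
    tau = params.tau_clear
    is_open = False
    ca_local = 0.0
    events: list[tuple[float, int]] = []  # (time, new occupancy)
    open_time = np.zeros(len(protocol.epochs))

    t = 0.0
    for ep_idx, ep in enumerate(protocol.epochs):
        kc = k_close(params, ep.voltage)
        flood = _flood_level(params, ep.voltage, protocol.ca_ext_mm)
        while t < ep.end:
            if is_open:
                dwell = rng.exponential(1.0 / kc)
                t_next = t + dwell
                if t_next >= ep.end:
                    open_time[ep_idx] += ep.end - t
                    ca_local = flood + (ca_local - flood) * math.exp(-(ep.end - t) / tau)
                    t = ep.end
                    break
                open_time[ep_idx] += dwell
                ca_local = flood + (ca_local - flood) * math.exp(-dwell / tau)
                t = t_next
                is_open = False
                events.append((t, 0))
            else:
                t_evt, ca_local = _next_opening(params, ep, t, ca_local, rng)
                if t_evt >= ep.end:
                    ca_local = ca_local * math.exp(-(ep.end - t) / tau)
                    t = ep.end
                    break
                ca_local = ca_local * math.exp(-(t_evt - t) / tau)
                t = t_evt
                is_open = True
                events.append((t, 1))
    return events, open_time


def _next_opening(params, ep: Epoch, t: float, ca_local: float,
                  rng: np.random.Generator):
    """Thinning sampler for the next opening; returns (event time, ca_local at t).

    ``ca_local`` returned unchanged (decay is applied by the caller)."""
    tau = params.tau_clear
    t_cur = t
    ca_cur = ca_local
    while t_cur < ep.end:
        bound = k_open(params, ep.ca_cyto_free + ca_cur, ep.adpr, ep.pip2)
        if bound <= 0.0:
            return math.inf, ca_local
        dt = rng.exponential(1.0 / bound)
        t_cur = t_cur + dt
        if t_cur >= ep.end:
            return math.inf, ca_local
        ca_cur = ca_cur * math.exp(-dt / tau)
        hazard = k_open(params, ep.ca_cyto_free + ca_cur, ep.adpr, ep.pip2)
        if rng.uniform() * bound <= hazard:
            return t_cur, ca_local
    return math.inf, ca_local


def simulate_patch(params: GatingParams, protocol: SimProtocol) -> SimResult:
    """Simulate a multi-channel patch; fully reproducible from the seed."""
    rng = np.random.default_rng(protocol.seed)
    n_samples = int(round(protocol.duration * protocol.sampling_rate))
    occupancy_delta = np.zeros(n_samples + 1)
    event_log: list[tuple[float, int, int]] = []
    open_time = np.zeros(len(protocol.epochs))

    fs = protocol.sampling_rate
    for ch in range(params.n_channels):
        events, ot = _simulate_channel(params, protocol, rng)
        open_time += ot
        for t_evt, state in events:
            event_log.append((t_evt, ch, state))
            if state == 1:
                i0 = min(int(math.ceil(t_evt * fs - 1e-9)), n_samples)
                occupancy_delta[i0] += 1
            else:
                i1 = min(int(math.ceil(t_evt * fs - 1e-9)), n_samples)
                occupancy_delta[i1] -= 1
    occupancy = np.cumsum(occupancy_delta[:-1])

    current = np.zeros(n_samples)
    for idx, ep in enumerate(protocol.epochs):
        i0 = int(round(ep.start * fs))
        i1 = int(round(ep.end * fs))
        i_unit = unitary_current(params, ep.voltage, ep.ca_cyto_free)
        current[i0:i1] = occupancy[i0:i1] * i_unit
    current = current + rng.normal(0.0, params.noise_sd, n_samples)

    durations = np.array([ep.duration for ep in protocol.epochs])
    true_po = open_time / (params.n_channels * durations)
    event_log.sort(key=lambda e: e[0])
    trace = CurrentTrace(current, fs, protocol.epochs)
    return SimResult(trace, [float(p) for p in true_po], event_log, params, protocol)


# ---------------------------------------------------------------------------
# canned protocols

def dose_response_dataset(
    params: GatingParams,
    conc_list_um: Sequence[float],
    duration_s: float = 60.0,
    seed: int = 0,
    voltage_mv: float = REFERENCE_VOLTAGE,
    adpr_um: float = 100.0,
    sampling_rate: float = 5000.0,
) -> list[SimResult]:
    """One simulation per cytosolic [Ca2+], at a fixed voltage.

    Child seeds are spawned deterministically from ``seed``; ground-truth
    open probabilities travel with each result.
    """
    if len(conc_list_um) == 0:
        raise ValueError("conc_list_um must be non-empty")
    seeds = np.random.SeedSequence(seed).generate_state(len(conc_list_um)) % (2 ** 31)
    results = []
    for conc, s in zip(conc_list_um, seeds):
        ep = Epoch(0.0, duration_s, adpr=adpr_um, ca_cyto_free=conc,
                   voltage=voltage_mv, label=f"ca_{conc:g}uM")
        protocol = SimProtocol((ep,), sampling_rate=sampling_rate, seed=int(s))
        results.append(simulate_patch(params, protocol))
    return results


def deactivation_protocol(
    params: GatingParams,
    voltages_mv: Sequence[float],
    ca_ext_mm: float = 0.0,
    seed: int = 0,
    t_activate_s: float = 1.0,
    t_decay_s: float = 2.0,
    ca_cyto_um: float = 125.0,
    adpr_um: float = 100.0,
    sampling_rate: float = 5000.0,
) -> list[SimResult]:
    """Cytosolic Ca2+ removal mid-trace at each voltage.

    With no external Ca2+ the ensemble decay after removal is a single
    exponential with tau = 1/k_close(V); with external Ca2+ at voltages
    below the Ca2+ reversal potential the decay is slowed and incomplete
    (influx feedback).
    """
    if len(voltages_mv) == 0:
        raise ValueError("voltages_mv must be non-empty")
    seeds = np.random.SeedSequence(seed).generate_state(len(voltages_mv)) % (2 ** 31)
    results = []
    for v, s in zip(voltages_mv, seeds):
        epochs = (
            Epoch(0.0, t_activate_s, adpr=adpr_um, ca_cyto_free=ca_cyto_um,
                  voltage=v, label="activate"),
            Epoch(t_activate_s, t_activate_s + t_decay_s, adpr=adpr_um,
                  ca_cyto_free=0.0, voltage=v, label="ca_removed"),
        )
        protocol = SimProtocol(epochs, sampling_rate=sampling_rate,
                               seed=int(s), ca_ext_mm=ca_ext_mm)
        results.append(simulate_patch(params, protocol))
    return results


# ---------------------------------------------------------------------------
# presets (non-measured convenience parameter sets; see module docstring)

PRESETS: dict[str, GatingParams] = {
    # wild-type-like: K1/2 ~2 μM, ~150 pS, robust influx feedback
    "WT": GatingParams(),
    # Ca2+-site mutants: right-shifted K1/2, strong PIP2 stimulation
    "Q896A": GatingParams(k_half=40.0, pip2_open_factor=20.0),
    "E1110A": GatingParams(k_half=12.0, pip2_open_factor=20.0),
    "N918A": GatingParams(k_half=1500.0, pip2_open_factor=20.0),
    # D921A-like: very low maximal P_o, dwell-time NPo territory
    "D921A": GatingParams(k_half=2000.0, k_open_max=4.0, pip2_open_factor=20.0),
    # human-ortholog-like: smaller conductance, intermediate Ca2+ affinity
    "hTRPM2-like": GatingParams(k_half=20.0, g_unitary=50.0,
                                ca_local_open=1.0),
}


def preset(name: str, **overrides) -> GatingParams:
    """Fetch a named preset, optionally overriding fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base
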