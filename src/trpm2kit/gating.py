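"""Gating analysis of patch-clamp current traces.

The pipeline implemented here mirrors standard inside-out-patch practice for
ligand-gated channels:

1. digital Gaussian low-pass filtering (default -3 dB at 200 Hz),
2. unitary current amplitudes from sums-of-Gaussians fits to all-points
   histograms,
3. open probability normalized to a reference ligand condition, with the
   pore-block correction  P_o/P_o;ref = (I/I_ref)/(i/i_ref)  that separates
   gating from the concentration-dependent reduction of unitary current,
4. Hill fits of dose-response relations,
5. single-exponential fits of macroscopic deactivation time courses,
6. half-amplitude threshold idealization and dwell-time NPo for patches with
   very low open probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

from .permeation import FitFailure

__all__ = [
    "Epoch",
    "CurrentTrace",
    "AmplitudeFit",
    "PoEstimate",
    "HillFit",
    "RelaxationFit",
    "DwellRecord",
    "filter_trace",
    "fit_all_points_histogram",
    "normalized_po",
    "rescale_to_pip2_reference",
    "low_po_fraction",
    "fit_hill",
    "fit_deactivation",
    "idealize_and_npo",
]


@dataclass(frozen=True)
class Epoch:
    """A stretch of recording with constant solutions and voltage."""

    start: float  # s
    end: float  # s
    adpr: float = 0.0  # μM
    ca_cyto_free: float = 0.0  # μM
    pip2: float = 0.0  # μM
    voltage: float = -20.0  # mV
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("epoch end must be after start")
        if min(self.adpr, self.ca_cyto_free, self.pip2) < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CurrentTrace:
    """Sampled current (pA) with epoch annotations."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    epochs: tuple[Epoch, ...] = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.epochs = tuple(self.epochs)
        t_end = len(self.samples) / self.sampling_rate
        prev_end = -math.inf
        for ep in sorted(self.epochs, key=lambda e: e.start):
            if ep.start < prev_end - 1e-12:
                raise ValueError("epochs overlap")
            if ep.end > t_end + 1e-9:
                raise ValueError("epoch extends beyond trace")
            prev_end = ep.end

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def segment(self, start: float, end: float) -> np.ndarray:
        i0 = int(round(start * self.sampling_rate))
        i1 = int(round(end * self.sampling_rate))
        return self.samples[i0:i1]

    def epoch_samples(self, epoch: Epoch) -> np.ndarray:
        return self.segment(epoch.start, epoch.end)


@dataclass(frozen=True)
class AmplitudeFit:
    """Sum-of-Gaussians decomposition of an all-points histogram."""

    level_means: tuple[float, ...]  # pA, ordered from baseline outward
    level_sds: tuple[float, ...]
    level_weights: tuple[float, ...]  # sum to 1
    unitary_i: float  # pA; NaN when only one level was resolved
    n_levels: int  # number of conducting levels (components - 1)
    residual: float = 0.0
    flags: tuple[str, ...] = ()

    @property
    def single_level(self) -> bool:
        return self.n_levels == 0


@dataclass(frozen=True)
class PoEstimate:
    value: float
    reference: str  # "ca125" | "ca125_pip2"
    inputs_used: tuple = ()

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("open probability estimate must be >= 0")


@dataclass(frozen=True)
class HillFit:
    k_half: float  # μM
    n_hill: float
    p_max: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self):
        if self.k_half <= 0 or self.n_hill <= 0:
            raise ValueError("Hill parameters must be > 0")

    def __call__(self, conc):
        c = np.asarray(conc, dtype=float)
        cn = c ** self.n_hill
        return self.p_max * cn / (cn + self.k_half ** self.n_hill)


@dataclass(frozen=True)
class RelaxationFit:
    tau: float  # ms
    amplitude: float  # pA
    offset: float  # pA
    t0: float  # s
    plateau_flagged: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class DwellRecord:
    """Idealized events (occupancy level, duration) and the resulting NPo."""

    events: tuple[tuple[int, float], ...]
    n_po: float

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.events)


# ---------------------------------------------------------------------------
# filtering

def gaussian_sigma_samples(cutoff_hz: float, sampling_rate: float) -> float:
    """Gaussian-kernel sigma (in samples) whose -3 dB point is ``cutoff_hz``."""
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)  # ~0.1325/fc
    return sigma_t * sampling_rate


def filter_trace(trace: CurrentTrace, cutoff_hz: float = 200.0) -> CurrentTrace:
    """Zero-phase Gaussian low-pass filter (-3 dB at ``cutoff_hz``)."""
    if cutoff_hz >= trace.sampling_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sigma = gaussian_sigma_samples(cutoff_hz, trace.sampling_rate)
    filtered = gaussian_filter1d(trace.samples, sigma, mode="nearest")
    return CurrentTrace(filtered, trace.sampling_rate, trace.epochs)


# ---------------------------------------------------------------------------
# all-points histograms

def _noise_sd_estimate(segment: np.ndarray) -> float:
    """Baseline noise sd, robust to gating transitions and to low-pass
    filtering (which correlates neighboring samples, so first differences
    would underestimate it): MAD of the residual around a short running
    median that tracks the occupancy level but not the noise."""
    from scipy.ndimage import median_filter

    win = max(min(len(segment) // 50, 31), 5)
    resid = segment - median_filter(segment, size=win, mode="nearest")
    sd = np.median(np.abs(resid)) / 0.6745
    return max(float(sd), 1e-6)


def _gauss_sum(x, *params):
    # params: interleaved (amplitude, mean, sd) triplets
    y = np.zeros_like(x)
    for k in range(0, len(params), 3):
        a, m, s = params[k:k + 3]
        y = y + a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return y


def _fit_k_gaussians(centers, counts, k, anchor, spacing, sigma0):
    """Least-squares fit of k Gaussian components to binned counts.

    Initial means form a ladder anchor + j*spacing, j = 0..k-1."""
    p0, lo, hi = [], [], []
    span = counts.max()
    width = centers[-1] - centers[0]
    for j in range(k):
        m0 = anchor + j * spacing
        idx = np.argmin(np.abs(centers - m0))
        p0 += [max(counts[idx], 1.0), m0, sigma0]
        lo += [0.0, centers[0] - abs(spacing), 0.05 * sigma0]
        hi += [10.0 * span, centers[-1] + abs(spacing), width]
    popt, _ = optimize.curve_fit(
        _gauss_sum, centers, counts, p0=p0, bounds=(lo, hi), maxfev=50000,
    )
    resid = float(np.sum((_gauss_sum(centers, *popt) - counts) ** 2))
    return popt, resid


def fit_all_points_histogram(
    segment: np.ndarray,
    max_levels: int = 5,
    bin_width: float | None = None,
) -> AmplitudeFit:
    """Unitary current from a sum-of-Gaussians fit to the all-points histogram.

    The histogram of every sample in ``segment`` is fit by sums of 1 to
    ``max_levels``+1 Gaussians (least squares on binned counts); the number of
    components is chosen by a BIC-style penalty on the binned residuals.  The
    unitary current is the mean spacing of adjacent fitted level means,
    signed from the baseline (the component containing the histogram mode)
    outward.  A single resolved component (all-closed patch) yields
    ``unitary_i`` = NaN with a ``"single_level"`` flag.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 1000:
        raise ValueError("need at least 1000 samples for an all-points histogram")

    noise_sd = _noise_sd_estimate(segment)
    if bin_width is None:
        bin_width = 0.1 * noise_sd

    lo = segment.min() - 3 * noise_sd
    hi = segment.max() + 3 * noise_sd
    nbins = max(int(math.ceil((hi - lo) / bin_width)), 16)
    nbins = min(nbins, 800)  # resolution beyond ~0.1 sd per bin buys nothing
    counts, edges = np.histogram(segment, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = counts.astype(float)

    anchor, spacing = _level_ladder_guess(centers, counts, noise_sd, max_levels)

    best = None
    n = float(counts.size)
    for k in range(1, max_levels + 2):
        try:
            popt, resid = _fit_k_gaussians(centers, counts, k, anchor,
                                           spacing, noise_sd)
        except (RuntimeError, ValueError):
            continue
        bic = n * math.log(max(resid, 1e-12) / n) + (3 * k) * math.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, popt, resid, k)
    if best is None:
        raise FitFailure("all-points histogram fit did not converge",
                         n_samples=int(segment.size))
    _, popt, resid, k = best

    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    weights = amps * sds  # component mass ∝ amplitude * sd
    weights = weights / weights.sum()

    # drop components with negligible mass (spurious BIC survivors)
    keep = weights > 1e-3
    if keep.sum() == 0:
        keep[:] = True
    amps, means, sds, weights = amps[keep], means[keep], sds[keep], weights[keep]
    weights = weights / weights.sum()

    # merge components closer than the noise sd (duplicated levels)
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    merged_m, merged_s, merged_w = [means[0]], [sds[0]], [weights[0]]
    for m, s, w in zip(means[1:], sds[1:], weights[1:]):
        if abs(m - merged_m[-1]) < noise_sd:
            tot = merged_w[-1] + w
            merged_m[-1] = (merged_m[-1] * merged_w[-1] + m * w) / tot
            merged_s[-1] = max(merged_s[-1], s)
            merged_w[-1] = tot
        else:
            merged_m.append(m)
            merged_s.append(s)
            merged_w.append(w)
    means = np.array(merged_m)
    sds = np.array(merged_s)
    weights = np.array(merged_w)

    # order from the baseline (the level nearest zero current) outward, so
    # the unitary current carries the sign of the conducting levels
    if abs(means[0]) > abs(means[-1]):
        means, sds, weights = means[::-1], sds[::-1], weights[::-1]

    flags: list[str] = []
    if len(means) < 2:
        unitary = math.nan
        flags.append("single_level")
    else:
        unitary = float(np.mean(np.diff(means)))
    return AmplitudeFit(
        tuple(float(m) for m in means),
        tuple(float(s) for s in sds),
        tuple(float(w) for w in weights),
        unitary,
        n_levels=len(means) - 1,
        residual=resid,
        flags=tuple(flags),
    )


def _level_ladder_guess(centers, counts, noise_sd, max_levels):
    """(anchor, spacing) for the initial ladder of component means.

    The anchor is the histogram peak nearest zero current (the closed
    level); the spacing is the smallest inter-peak distance above the noise
    width, signed from the anchor toward the far end of the data."""
    from scipy.signal import find_peaks

    smooth = gaussian_filter1d(counts, max(noise_sd / (centers[1] - centers[0]), 1.0))
    peaks, _ = find_peaks(smooth, prominence=0.02 * smooth.max())
    mode = centers[np.argmax(counts)]
    if len(peaks) >= 2:
        peak_pos = np.sort(centers[peaks])
        anchor = peak_pos[np.argmin(np.abs(peak_pos))]
        diffs = np.diff(peak_pos)
        diffs = diffs[diffs > 2 * noise_sd]
        if len(diffs):
            spacing = float(np.min(diffs))
            far = peak_pos[np.argmax(np.abs(peak_pos - anchor))]
            side = np.sign(far - anchor) or 1.0
            return float(anchor), side * spacing
    # single-peak fallback: anchor at the mode, spread toward the far tail
    lo_gap = mode - centers[0]
    hi_gap = centers[-1] - mode
    sign = 1.0 if hi_gap >= lo_gap else -1.0
    return float(mode), sign * max(max(lo_gap, hi_gap) / max(max_levels, 1),
                                   4 * noise_sd)


# ---------------------------------------------------------------------------
# normalized open probability

def normalized_po(I: float, I_ref: float, i: float, i_ref: float,
                  reference: str = "ca125") -> PoEstimate:
    """Block-corrected normalized open probability.

    P_o/P_o;ref = (I/I_ref) / (i/i_ref): dividing the macroscopic current
    ratio by the unitary current ratio cancels any change in unitary
    amplitude (e.g. pore block by cytosolic Ca2+), leaving pure gating.
    """
    if I_ref == 0 or i_ref == 0 or i == 0:
        raise ValueError("reference and unitary currents must be nonzero")
    value = (I / I_ref) / (i / i_ref)
    return PoEstimate(value, reference, inputs_used=(I, I_ref, i, i_ref))


def rescale_to_pip2_reference(po_rel: PoEstimate, ref_ratio: float) -> PoEstimate:
    """Re-reference P_o/P_o;125 to the 125 μM Ca2+ + PIP2 condition.

    ``ref_ratio`` is P_o;125+PIP2 / P_o;125 (equivalently I_125+PIP2/I_125)
    measured in the same patch.
    """
    if ref_ratio <= 0:
        raise ValueError("ref_ratio must be > 0")
    return PoEstimate(po_rel.value / ref_ratio, "ca125_pip2",
                      inputs_used=po_rel.inputs_used + (ref_ratio,))


def low_po_fraction(i: float, n_po: float, I_ref: float) -> PoEstimate:
    """Fractional P_o from dwell-time NPo: (i * NPo) / I_ref.

    Used when macroscopic currents are too small for cursor measurement and
    i and NPo come from single-channel dwell-time analysis instead.
    """
    if I_ref == 0:
        raise ValueError("reference current must be nonzero")
    return PoEstimate((i * n_po) / I_ref, "ca125_pip2",
                      inputs_used=(i, n_po, I_ref))


# ---------------------------------------------------------------------------
# dose-response

def fit_hill(
    concs: Sequence[float],
    po_values: Sequence[float],
    fix_pmax: bool = False,
    sigma: Sequence[float] | None = None,
) -> HillFit:
    """Least-squares Hill fit P(c) = P_max c^n / (c^n + K^n)."""
    c = np.asarray(concs, dtype=float)
    p = np.asarray(po_values, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(p) < 1e-12:
        raise FitFailure("dose-response data are flat", values=tuple(p))

    k0 = float(np.interp(0.5 * p.max(), np.sort(p) / p.max(),
                         c[np.argsort(p)])) if p.max() > 0 else np.median(c)
    k0 = min(max(k0, c[c > 0].min()), c.max())

    if fix_pmax:
        def model(cc, k, n):
            cn = cc ** n
            return cn / (cn + k ** n)
        p0 = [k0, 1.0]
        bounds = ([1e-9, 0.05], [1e9, 20.0])
    else:
        def model(cc, k, n, pmax):
            cn = cc ** n
            return pmax * cn / (cn + k ** n)
        p0 = [k0, 1.0, max(p.max(), 1e-6)]
        bounds = ([1e-9, 0.05, 1e-9], [1e9, 20.0, 1e9])
    try:
        popt, pcov = optimize.curve_fit(model, c, p, p0=p0, bounds=bounds,
                                        sigma=sigma, maxfev=50000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailure("Hill fit did not converge", error=str(exc)) from exc
    if fix_pmax:
        k, n = popt
        pmax = 1.0
    else:
        k, n, pmax = popt
    return HillFit(float(k), float(n), float(pmax), covariance=pcov)


# ---------------------------------------------------------------------------
# relaxation kinetics

def fit_deactivation(
    trace: CurrentTrace,
    t0: float,
    window: float,
    plateau_fraction: float = 0.1,
    require_closing_rate: bool = False,
) -> RelaxationFit:
    """Single-exponential fit I(t) = A exp(-(t-t0)/tau) + C of a decay.

    When ``require_closing_rate`` is set, a terminal current that differs
    from zero by more than ``plateau_fraction`` of the fitted amplitude is
    flagged: such decays (e.g. with sustained Ca2+ influx re-opening
    channels) do not report the channel closing rate and should not be
    interpreted as 1/k_close.
    """
    i0 = int(round(t0 * trace.sampling_rate))
    i1 = int(round((t0 + window) * trace.sampling_rate))
    seg = trace.samples[i0:i1]
    if seg.size < 20:
        raise ValueError("window must contain at least 20 samples")
    t = np.arange(seg.size) / trace.sampling_rate

    a0 = seg[0] - seg[-1]
    c0 = seg[-1]
    # crude tau from the 1/e crossing of the normalized decay
    norm = (seg - c0) / a0 if a0 != 0 else np.zeros_like(seg)
    below = np.nonzero(norm < math.exp(-1))[0]
    tau0 = t[below[0]] if len(below) else t[-1] / 3
    tau0 = max(tau0, 2.0 / trace.sampling_rate)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, seg, p0=[a0, tau0, c0],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailure("relaxation fit did not converge", error=str(exc)) from exc
    a, tau, c = popt
    flagged = bool(require_closing_rate and abs(c) > plateau_fraction * abs(a))
    return RelaxationFit(tau=float(tau * 1e3), amplitude=float(a),
                         offset=float(c), t0=t0, plateau_flagged=flagged)


# ---------------------------------------------------------------------------
# idealization / dwell-time NPo

def idealize_and_npo(
    segment: np.ndarray,
    unitary_i: float,
    threshold_frac: float = 0.5,
    sampling_rate: float = 1.0,
    dead_time: float = 0.0,
    max_level: int | None = None,
) -> DwellRecord:
    """Half-amplitude threshold idealization into integer occupancy levels.

    Samples are assigned to the nearest multiple of ``unitary_i`` (a 50%
    threshold between levels for the default ``threshold_frac``); runs
    shorter than ``dead_time`` (the filter dead time) are merged into the
    preceding event.  NPo is the time-weighted mean occupancy level.
    """
    if unitary_i == 0:
        raise ValueError("unitary current must be nonzero")
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    raw = seg / unitary_i + (0.5 - threshold_frac)
    levels = np.floor(raw + 0.5).astype(int)
    levels = np.clip(levels, 0, max_level if max_level is not None else None)

    dt = 1.0 / sampling_rate
    # run-length encode
    change = np.nonzero(np.diff(levels))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    events: list[list[float]] = [[int(levels[s]), (e - s) * dt]
                                 for s, e in zip(starts, ends)]

    if dead_time > 0:
        merged: list[list[float]] = []
        for lvl, dur in events:
            if merged and dur < dead_time:
                merged[-1][1] += dur  # absorb into the previous event
            elif merged and merged[-1][0] == lvl:
                merged[-1][1] += dur
            else:
                merged.append([lvl, dur])
        events = merged

    total = sum(d for _, d in events)
    n_po = sum(l * d for l, d in events) / total
    return DwellRecord(tuple((int(l), float(d)) for l, d in events), float(n_po))
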