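# Methods

This note documents the models and procedures implemented in trpm2kit, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions behind each module.

## Conventions and constants

Voltages are membrane potentials in mV (cytosolic side relative to the
pipette), corrected for liquid junction potential before any fit — the
correction is a pure voltage offset stored on the i–V container. Currents
are in pA with inward current negative; conductance in pS (pA/mV = nS).
Cytosolic ligand concentrations are in μM, solution compositions and
dissociation constants in mM. Temperature defaults to 298.15 K (25 °C
recording temperature) and is configurable everywhere it enters an
exponent. Physical constants (F, R, e) are CODATA 2018 values centralized
in `trpm2kit.constants`. Concentrations are treated as activities
(activity coefficients of 1); no surface-charge or ionic-strength
corrections are applied anywhere.

## Permeation

The bi-ionic permeability ratio uses the Fatt–Ginsborg form of the GHK
reversal condition for an external divalent against an internal monovalent:
P_X/P_M = ([M]ᵢ/(4[X]ₒ))·x·(1+x) with x = exp(EF/RT). The inverse is
closed-form: x is the positive root of x² + x − 4[X]ₒ·ratio/[M]ᵢ, so the
reversal potential is unique and strictly increasing in the ratio. A test
cross-checks this against a numerical root solve of the full GHK current
equation.

The GHK i–V fit uses the standard current equation with a valence-1 and a
valence-2 flux term (the divalent term carries the z² = 4 prefactor and
the e^(−2u) exponent), with an overall scale and the permeability ratio as
the only free parameters; the u → 0 singularity is handled by series
expansion. When the divalent species is absent on both sides the ratio is
unidentifiable; the fit then estimates the scale alone and reports a unit
ratio. Reversal potentials are read off the fitted curve by bracketed root
finding and flagged when extrapolated beyond the sampled voltages.

Quadratic reversal extrapolation exists because strongly rectifying
single-channel i–V relations are often not GHK-shaped: i = aV² + bV + c is
fit over a voltage window and the real root nearest the sampled range is
returned (tie broken toward 0 mV), with an `extrapolated` flag when the
root lies outside the data. Near-degenerate curvature falls back to the
linear root.

Flux accounting (N = |I|·t/(|z|e)), count→charge partitioning
(fᵢ|zᵢ|/Σfₖ|zₖ|) and the patch-microenvironment estimates (wash time =
footprint/flow speed; spacing = density^(−1/2) on a square lattice) are
deliberate back-of-envelope operations; the count fractions fed to the
charge partition are inputs, not derived from conductances, because the
concentration scaling between conductance measurements and mixed-ion
conditions is not modeled here.

## Gating analysis

Filtering is a zero-phase Gaussian low-pass whose kernel σ is set from the
−3 dB cutoff (σ_t = √(ln 2)/(2π f_c) ≈ 0.1325/f_c); a test verifies the
closed-form equivalent-noise-bandwidth variance reduction on white noise.

All-points histograms are fit by sums of Gaussians by least squares on the
binned counts (not sample-level EM), with the component count chosen by a
BIC-style penalty n·ln(RSS/n) + 3k·ln(n) over k = 1 … max_levels+1. The
default bin width is 0.1× the noise σ, capped at 800 bins. The noise σ is
estimated as the MAD of the residual around a short running median — first
differences would underestimate it badly on filtered (correlated) traces.
Initial component means form a ladder anchored at the histogram peak
nearest zero current (the closed level) extending toward the far end of
the data, which keeps high-P_o multi-channel histograms from losing their
outermost level. Fitted components closer than the noise σ are merged;
levels are reported from the baseline outward so the unitary current (the
mean adjacent-level spacing) carries the sign of the conducting levels. A
single resolved component returns NaN unitary current with a
`single_level` flag rather than guessing.

The normalized open probability (I/I_ref)/(i/i_ref) is exact algebra, not
an estimate; its value is that it cancels any pure unitary-current change
(pore block) between test and reference conditions. The PIP₂ re-reference
divides by the measured P_o;125+PIP2/P_o;125 ratio, and the dwell-time
route (i·N·P_o)/I_ref covers mutants whose macroscopic currents are too
small for cursor measurement.

Hill fits use least squares with K¹ᐟ², n_H (and optionally P_max) free;
P_max can be fixed at 1 for data normalized to a saturating reference.
With 6 concentrations and 5% noise a single draw with all three parameters
free recovers K¹ᐟ² to ~10–15% typically; the tests assert the median over
replicate draws.

Deactivation fits are single exponentials A·e^(−(t−t0)/τ) + C starting at
the solution-exchange midpoint (exchange kinetics are not deconvolved).
When the caller requests a closing-rate interpretation, a terminal offset
exceeding 10% (configurable) of the amplitude flags the fit: decays with
sustained reopening (e.g. Ca²⁺-influx feedback) do not report 1/k_close.

Idealization uses a half-amplitude threshold (samples assigned to the
nearest integer multiple of the unitary current; 50% threshold by
default), with events shorter than the filter dead time merged into their
predecessor. No missed-event correction is applied. N·P_o is the
time-weighted mean occupancy.

## Buffer equilibria

Each buffer binds Ca²⁺ (and optionally Mg²⁺) 1:1 with apparent, pH-lumped
dissociation constants supplied by the user; there is no proton-speciation,
ionic-strength or temperature model. The solver bisects on free Ca²⁺ over
[0, Ca_total] (machine-precision tolerance; mass-balance residual < 10⁻⁹
of total), with a nested bisection for free Mg²⁺ where Mg-binding buffers
are present. The inverse problem is direct: at a given free concentration
all buffer occupancies are determined, so the required total is a single
evaluation. The shipped constants (`LITERATURE_KD`) are labelled
convenience values: EGTA apparent Kds are literature-typical for the
indicated pH, and the gluconate Kd of 19.1 mM is back-computed from the
~88% bound fraction of Ca²⁺ in 140 mM gluconate. They are not calibrated
measurements.

## Pore profiling

Van der Waals radii come from a Bondi-style element table shipped with the
package (configurable); hydrogens absent from typical deposited models are
simply absent — united-atom radii are not applied. Because radius tables
differ at the 0.1–0.2 Å level between implementations, absolute profile
values should only be compared across tools to ~0.2 Å.

The C4 axis is found by Kabsch superposition of each chain onto its
neighbor (atoms matched by residue number and element, in order), taking
the rotation axis of the fitted ~90° rotation and averaging over the four
neighbor pairs; a mismatch (wrong chain count, non-rotational ordering)
falls back to the principal axis with a warning. The principal mode uses
the largest-variance eigenvector of the atom cloud, appropriate for
elongated channel assemblies (note: for flat toy geometries the
largest-variance axis lies in the plane — use explicit waypoints there).

Radius profiling maximizes, at each station, the clearance
min_a(‖c−x_a‖ − r_a) over sphere centers c in the plane normal to the
local tangent, within a configurable in-plane wander bound (default 5 Å).
The optimizer is a deterministic 9-point start lattice followed by
Nelder-Mead (tight tolerances), so profiles are reproducible to better
than 10⁻⁶ Å under rigid motion of the inputs; a brute-force 0.05 Å grid
search serves as the oracle in tests. The default station step is 0.25 Å.
Stations with no atoms within reach are capped at the configured maximum
radius and flagged rather than reported as infinite. Curved tunnels use a
uniform Catmull-Rom spline through user waypoints, arc-length
parametrized; straight waypoints reproduce the line profiler exactly, and
tangent reversals raise a geometry error. Stations are classified against
the water radius: < 1.15 Å (too tight for water), 1.15–2.30 Å (single-file
water), > 2.30 Å.

The profile convention puts the extracellular side at positive arc length
when the axis direction is chosen accordingly; the axis finder does not
itself disambiguate the two orientations.

## The simulator (synthetic-data generator)

Each channel is an independent two-state (C↔O) continuous-time Markov
chain. Opening: k_o = gate_ADPR · f_PIP2 · (k_spont + k_open_max ·
H([Ca]_site)) with H the Hill function; ADPR is a binary gate (its binding
kinetics are not modeled) and PIP₂ multiplies the opening rate (×1.15 for
the wild-type-like preset, ×20 for binding-site-mutant presets, matching
the observed order of stimulation). Closing: k_c = k_close0 ·
e^(−z_gate·V·F/RT), a mild intrinsic voltage dependence (z_gate = 0.15
puts deactivation τ between ~30 ms at −80 mV and ~80 ms at +80 mV,
within the experimentally observed tens-of-milliseconds range). Event
times are exact: closed→open uses thinning with the interval-start hazard
as the bound (valid because the local Ca²⁺, and hence the hazard, only
decays while closed under constant bulk conditions); open→closed is a
plain exponential. Occupancy is sampled-and-held onto the output grid and
summed over channels with additive white Gaussian noise (σ default
0.3 pA); no 1/f or seal-leak noise is modeled.

For a two-state channel this rate law makes the equilibrium dose–response
itself exactly Hill-shaped, with half-point K_eff = K_act/(1 +
k_open_max/k_close)^(1/n). Presets therefore specify the *observable*
half-activation (`k_half`, e.g. 2 μM for the wild-type-like preset, 40 μM
for Q896A-like) and derive the rate-law constant K_act from it at the
−20 mV reference voltage; the small Ca²⁺-independent spontaneous rate
shifts the realized half-point by < 2%.

Local-Ca²⁺ feedback is a per-channel deterministic relaxation, not a
spatial diffusion model: a local site concentration relaxes toward a flood
level while the pore is open (with external Ca²⁺ present and voltage below
the Ca²⁺ reversal parameter, the flood level scaling linearly with driving
force and external Ca²⁺) and decays toward zero with time constant
tau_clear (0.3 s) after closure. The site Ca²⁺ seen by the opening rate is
bulk cytosolic free Ca²⁺ plus this local component. All presets use a
Hill coefficient of 1 for activation: with steeper activation the
closed-loop feedback (flood level linear in open probability feeding a
sigmoid opening rate) is bistable and has no stable steady state at
intermediate open probability, whereas with n = 1 a unique stable fixed
point exists. The flood amplitude (7 μM at the −20 mV reference with 1 mM
external Ca²⁺) and tau_clear were chosen by mean-field fixed-point
analysis and one verification simulation so that the steady open
probability sustained at −80 mV lands near 0.2, inside the observed
0.15–0.3 band; they are phenomenological parameters, not measurements.
This lumped model reproduces the feedback phenomenology — plateau currents
surviving cytosolic Ca²⁺ removal at negative voltages, deactivation τ
prolonged by external Ca²⁺ at moderately positive voltages and approaching
the Ca²⁺-free value at strongly positive voltages, and delayed
self-activation by ADPR alone (seeded by k_spont = 0.05 s⁻¹) — but not
channel cross-talk, spatially resolved Ca²⁺ gradients, buffer kinetics at
the patch surface, or rundown.

Pore block of the unitary current by cytosolic Ca²⁺ is a 1:1 inhibition
curve K_block/(K_block + [Ca]) with K_block = 1 mM, applied to an ohmic
unitary current g·(V − E_rev); the wild-type-like conductance is 150 pS
(−3 pA at −20 mV in symmetric Na⁺). Block is what the normalized-P_o
correction must cancel, so the dose–response pipeline tests exercise it
explicitly.

What passing tests show — and do not. The simulator produces idealized
patches: stationary gating within epochs, instantaneous solution exchange,
white noise, no drift, no leak, identical channels. Pipeline-recovery
results (e.g. Hill K¹ᐟ² within 15% from 60 s per concentration) therefore
demonstrate correctness of the analysis chain, not robustness to baseline
drift, slow rundown, heterogeneous channel populations, or finite exchange
kinetics, none of which are emulated.

## Problem sizes used in the shipped checks

Dose–response recovery runs 6 concentrations × 60 s at 5 kHz with 4
channels per patch, for a wild-type-like and a right-shifted mutant-like
preset; deactivation checks use 800-channel ensembles over 3 s at five
voltages (sampling error on a fitted τ at this size is a few percent,
comfortably inside the 10% comparison); the feedback plateau uses 300
channels over 7 s. Profiler-oracle comparisons use toy ring geometries
with a 0.05 Å exhaustive grid as reference. These sizes were chosen so the
statistical error of each check sits well below the tolerance it asserts.

## Known limitations

- No Nernst–Planck/Poisson electrodiffusion, Gouy–Chapman surface-charge
  or activity-coefficient corrections in the permeation module.
- No hidden-Markov idealization or multi-exponential dwell-time fitting;
  no missed-event correction.
- Buffer constants are apparent and uncorrected; recipes near pH extremes
  or high ionic strength need externally calibrated Kds.
- The profiler does not expand crystallographic/EM symmetry and does not
  compute cavity volumes or electrostatics.
- Simulator rates are presets, not fitted constants; only the observables
  they generate (K¹ᐟ², τ ranges, plateau band, conductance) are anchored
  to reported ranges.
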