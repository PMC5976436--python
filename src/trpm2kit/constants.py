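"""Physical constants (CODATA 2018) and unit helpers used across the package.

All electrophysiology code in this package uses the conventions
documented in :mod:`trpm2kit`:

* voltages in mV (membrane potential, cytosolic side relative to pipette),
* currents in pA, inward current negative,
* conductances in pS,
* concentrations in mM unless a function documents μM,
* temperature in K (default 298.15 K, i.e. 25 °C recording temperature).
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
ELEMENTARY_CHARGE = 1.602176634e-19  # C

DEFAULT_TEMPERATURE = 298.15  # K


def thermal_voltage_mv(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT/F in millivolts (≈25.69 mV at 25 °C)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY
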