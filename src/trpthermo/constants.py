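"""Physical constants and unit conventions.

All thermodynamic quantities in this package follow the conventions of the
thermoTRP electrophysiology literature: enthalpies in kcal/mol, entropies in
cal/(mol·K), and the gas constant in cal/(mol·K).  The kcal↔cal factor of
1000 is applied exactly once, at the enthalpy boundary, inside the closed-form
gating functions — never by callers.

Temperatures are Kelvin everywhere inside the package; Celsius appears only
at user-facing boundaries (presets, protocols, reports).
"""

#: Gas constant, cal/(mol·K).
GAS_CONSTANT = 1.987

#: Offset between the Celsius and Kelvin scales, K.
CELSIUS_OFFSET = 273.15

#: kcal → cal conversion, applied once at the enthalpy boundary.
KCAL_TO_CAL = 1000.0


def celsius_to_kelvin(t_celsius):
    """Convert a temperature (scalar or array) from °C to K."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    """Convert a temperature (scalar or array) from K to °C."""
    return t_kelvin - CELSIUS_OFFSET
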