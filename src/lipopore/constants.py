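"""Physical constants and unit conventions.

Units are fixed package-wide: current in pA, voltage in mV, conductance in
pS, time in s, temperature in K, concentration in M (bath) or uM (dosing).
The pS*mV -> pA conversion factor is 1e-3.
"""

BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Default bath temperature ("room temperature"), K.
ROOM_TEMPERATURE_K = 298.15

#: pS * mV -> pA
PS_MV_TO_PA = 1e-3


def thermal_voltage_mv(temperature_k: float = ROOM_TEMPERATURE_K) -> float:
    """kT/e in millivolts (25.69 mV at 298.15 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature_k must be positive, got {temperature_k}")
    return BOLTZMANN_J_PER_K * temperature_k / ELEMENTARY_CHARGE_C * 1e3


def dimensionless_voltage(voltage_mv, temperature_k: float = ROOM_TEMPERATURE_K):
    """Reduced transmembrane potential u = eV/kT for V in mV."""
    return voltage_mv / thermal_voltage_mv(temperature_k)
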