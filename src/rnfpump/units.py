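"""Physical constants and energy-unit conversion.

All redox potentials are handled in millivolts, free energies in kcal/mol
unless a unit tag says otherwise.  The Faraday constant is fixed at
23.061 kcal mol⁻¹ V⁻¹ so that the classic back-of-the-envelope identities
(1 kcal/mol ≈ 43.36 meV, 130 mV × 2e⁻ ≈ 6 kcal/mol) reproduce exactly.
"""

from __future__ import annotations

FARADAY_KCAL_PER_V = 23.061
"""Faraday constant in kcal mol⁻¹ V⁻¹."""

KJ_PER_KCAL = 4.184
"""Thermochemical calorie definition."""

MEV_PER_KCAL = 1000.0 / FARADAY_KCAL_PER_V
"""1 kcal/mol expressed as meV per elementary charge (≈ 43.36)."""

GAS_CONSTANT_KCAL = 1.987204e-3
"""Gas constant R in kcal mol⁻¹ K⁻¹."""

BOLTZMANN_OVER_PLANCK = 2.0836619e10
"""k_B / h in s⁻¹ K⁻¹ (Eyring prefactor per kelvin)."""

DEFAULT_TEMPERATURE_K = 310.0
"""Physiological simulation temperature."""

# conversion factors *to* the internal base unit (kcal/mol)
_TO_KCAL = {
    "kcal/mol": 1.0,
    "kJ/mol": 1.0 / KJ_PER_KCAL,
    "meV": 1.0 / MEV_PER_KCAL,
}

ENERGY_UNITS = tuple(_TO_KCAL)


def convert_energy(value: float, from_units: str, to_units: str) -> float:
    """Convert a signed energy between kcal/mol, kJ/mol and meV (per charge).

    Conversion goes through a single base unit, so any chain of
    conversions is self-consistent and round trips are exact.
    """
    for u in (from_units, to_units):
        if u not in _TO_KCAL:
            raise ValueError(
                f"unknown energy unit {u!r}; expected one of {ENERGY_UNITS}"
            )
    return value * _TO_KCAL[from_units] / _TO_KCAL[to_units]


def rt_kcal(temperature_K: float) -> float:
    """Thermal energy RT in kcal/mol."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature_K
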