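"""Redox thermodynamics of the Rnf reaction.

The Rnf complex oxidises reduced ferredoxin (E₀′ ≈ −450 mV, printed range
−430 to −500 mV) and reduces NAD⁺ (E₀′ = −320 mV), a small driving force of
about −6 kcal/mol for two electrons (−130 mV per electron) that is spent
pumping up to two Na⁺ against the sodium-motive force (SMF).  This module
does the unit-safe accounting: reaction free energies from midpoint
potentials, the break-even SMF at which pumping stalls, and the
thermodynamic cycle that couples Na⁺ binding to the midpoint potential of
the membrane-embedded AE1 [2Fe2S] cluster.

Sign conventions: ΔG < 0 is exergonic; SMF ≥ 0 opposes outward Na⁺
pumping; a positive donor→acceptor potential difference means downhill
electron transfer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .units import (
    DEFAULT_TEMPERATURE_K,
    FARADAY_KCAL_PER_V,
    convert_energy,
)

__all__ = [
    "RedoxCouple",
    "PumpThermodynamics",
    "NaBindingThermo",
    "FERREDOXIN",
    "FERREDOXIN_LOW",
    "NAD",
    "UBIQUINONE",
    "reaction_free_energy",
    "per_electron_driving_force",
    "breakeven_smf",
    "binding_redox_shift",
]


@dataclass(frozen=True)
class RedoxCouple:
    """A half reaction: label, midpoint potential E₀′ (mV), electron count."""

    name: str
    midpoint_mV: float
    n_electrons: int = 1

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")
        if not math.isfinite(self.midpoint_mV):
            raise ValueError("midpoint potential must be finite")


#: Canonical couples of the Rnf/Nqr reactions.
FERREDOXIN = RedoxCouple("Fd(ox/red)", -450.0, 1)
FERREDOXIN_LOW = RedoxCouple("Fd(ox/red, low)", -500.0, 1)
NAD = RedoxCouple("NAD+/NADH", -320.0, 2)
UBIQUINONE = RedoxCouple("UQ/UQH2", +90.0, 2)


@dataclass
class PumpThermodynamics:
    """Thermodynamic frame of the pump: SMF, temperature, stoichiometry."""

    smf_mV: float = 0.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    na_per_electron: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.na_per_electron < 0:
            raise ValueError("na_per_electron must be >= 0")


@dataclass
class NaBindingThermo:
    """Na⁺ binding free energies (kcal/mol) for oxidized vs reduced AE1.

    Binding is weakly exergonic (ca. −1 kcal/mol) with AE1 oxidized and
    strengthens to about −3 kcal/mol upon reduction — the electrostatic
    coupling that makes the cluster's redox state gate ion uptake.
    """

    dG_bind_oxidized_kcal: float = -1.0
    dG_bind_reduced_kcal: float = -3.0

    def __post_init__(self) -> None:
        for v in (self.dG_bind_oxidized_kcal, self.dG_bind_reduced_kcal):
            if not math.isfinite(v):
                raise ValueError("binding free energies must be finite")
        if self.dG_bind_reduced_kcal > self.dG_bind_oxidized_kcal:
            warnings.warn(
                "Na+ binding is weaker to the reduced cluster than to the "
                "oxidized one; redox-coupled uptake would run backwards",
                stacklevel=2,
            )


def reaction_free_energy(
    donor: RedoxCouple,
    acceptor: RedoxCouple,
    n: int = 2,
    units: str = "kcal/mol",
) -> float:
    """ΔG₀′ = −n·F·(E_acceptor − E_donor) for n electrons, in `units`.

    Negative means exergonic.  Fd(−450) → NAD⁺(−320) with n=2 gives
    ≈ −6.0 kcal/mol (−25 kJ/mol, −260 meV).
    """
    if n < 1:
        raise ValueError("electron count n must be >= 1")
    delta_e_V = (acceptor.midpoint_mV - donor.midpoint_mV) / 1000.0
    dG_kcal = -n * FARADAY_KCAL_PER_V * delta_e_V
    return convert_energy(dG_kcal, "kcal/mol", units)


def per_electron_driving_force(donor: RedoxCouple, acceptor: RedoxCouple) -> float:
    """E_acceptor − E_donor in mV; positive means downhill electron transfer."""
    return acceptor.midpoint_mV - donor.midpoint_mV


def breakeven_smf(driving_per_electron_mV: float, na_per_electron: float) -> float:
    """SMF (mV) at which redox driving exactly pays for Na⁺ translocation.

    Energy balance per electron: driving = na_per_electron × SMF, hence the
    break-even SMF is driving/na_per_electron.  For the Rnf stoichiometry
    of 1 Na⁺ per electron (2 Na⁺ / 2 e⁻) and −130 mV per electron this is
    the printed 130 mV ceiling.
    """
    if na_per_electron <= 0:
        raise ValueError("na_per_electron must be > 0 (break-even undefined)")
    return driving_per_electron_mV / na_per_electron


def binding_redox_shift(binding: NaBindingThermo) -> float:
    """Midpoint-potential shift (mV) of AE1 caused by Na⁺ binding.

    Closes the thermodynamic square (ox, apo) → (red, apo) → (red, Na⁺)
    versus (ox, apo) → (ox, Na⁺) → (red, Na⁺):

        ΔE_m = (ΔG_bind^ox − ΔG_bind^red) / F

    Positive means Na⁺ binding raises the midpoint potential (and Na⁺
    release lowers it by the same amount, favouring the onward electron
    transfer to FMN^G).  The printed −1/−3 kcal/mol pair gives ≈ +87 mV.
    """
    dG_diff = binding.dG_bind_oxidized_kcal - binding.dG_bind_reduced_kcal
    return dG_diff / FARADAY_KCAL_PER_V * 1000.0
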