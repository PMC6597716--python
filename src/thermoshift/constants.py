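"""Physical constants and unit helpers.

All energies inside the package are kJ/mol; temperatures are Kelvin
internally and degrees Celsius at user-facing interfaces.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-level constants used by the Eyring and van't Hoff machinery.

    Overridable only by constructing a new instance (reproducibility
    studies); every function takes an optional ``constants`` argument.
    """

    R: float = 8.314  # gas constant, J K^-1 mol^-1
    h: float = 6.626e-34  # Planck constant, J s
    k_B: float = 1.381e-23  # Boltzmann constant, J K^-1
    c_standard: float = 1.0  # standard-state concentration, mol L^-1


CONST = PhysicalConstants()

ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + ZERO_CELSIUS_K


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - ZERO_CELSIUS_K
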