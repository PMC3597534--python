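"""Unit conventions and conversions.

Coordinates are stored internally in angstroms (PDB native).  Membrane and
free-energy results are reported in nanometres; every Å↔nm crossing goes
through the two converters below so no silent unit drift can occur.

Energy bookkeeping uses pN·nm; thermal energy kBT(T) is computed from the
CODATA Boltzmann constant (k_B = 1.380649e-2 pN·nm/K, exact by definition).
At the simulation temperature of 310 K, kBT ≈ 4.28 pN·nm.
"""

from __future__ import annotations

ANGSTROM_PER_NM: float = 10.0

#: Boltzmann constant in pN·nm/K (CODATA, exact: 1.380649e-23 J/K).
K_B_PN_NM_PER_K: float = 1.380649e-2

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE_K: float = 310.0


def ang_to_nm(x):
    """Convert angstroms to nanometres (scalar or array)."""
    return x / ANGSTROM_PER_NM


def nm_to_ang(x):
    """Convert nanometres to angstroms (scalar or array)."""
    return x * ANGSTROM_PER_NM


def kbt_pn_nm(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B·T in pN·nm at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return K_B_PN_NM_PER_K * temperature_k


def beta_per_pn_nm(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse thermal energy β = 1/(k_B·T) in 1/(pN·nm)."""
    return 1.0 / kbt_pn_nm(temperature_k)
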