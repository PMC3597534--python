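"""Closed-form diffusion and force-feasibility arithmetic.

A membrane protein undergoing a free 2-D random walk with diffusion
coefficient D has position variance σ² = 4·D·t after time t (the 2-D
Green's function of diffusion), so with D = 0.25 nm²/µs over a 2 ns
simulation window the molecule strays only σ ≈ 0.045 nm from its origin.
Dividing the 99.7% band 3σ by t gives the characteristic drift speed,
while the central-limit-theorem decomposition of the walk into steps of
the integration time step dt gives the much larger instantaneous step
speed V = sqrt(4·D/dt).  A steering velocity should stay roughly an
order of magnitude below V so the pull never out-runs what the molecule's
surroundings mechanically sense.

The same module converts an association free-energy barrier into the
cytoskeletal displacement needed to supply it at a given sustained force,
and turns centre-of-mass contact distances into effective monomer and
lipid-shell radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import DEFAULT_TEMPERATURE_K, kbt_pn_nm

__all__ = [
    "DiffusionParams",
    "BarrierAssessment",
    "GeometricRadii",
    "position_std",
    "characteristic_speed",
    "instantaneous_speed",
    "recommended_pull_speed",
    "required_stretch",
    "geometric_radii",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Free in-membrane diffusion inputs.

    d_nm2_per_us: diffusion coefficient (nm²/µs); t_ns: simulated time
    window (ns); dt_fs: integration time step (fs).
    """

    d_nm2_per_us: float = 0.25
    t_ns: float = 2.0
    dt_fs: float = 2.0

    def __post_init__(self) -> None:
        if self.d_nm2_per_us < 0 or self.t_ns <= 0 or self.dt_fs <= 0:
            raise ValueError("diffusion parameters must be positive (D may be 0)")


@dataclass(frozen=True)
class GeometricRadii:
    """Radii inferred from centre-of-mass contact distances (nm)."""

    envelope_radius_nm: float       # half the lipid-mediated contact distance
    monomer_radius_nm: float        # half the bare (no-membrane) contact distance
    shell_thickness_nm: float       # envelope minus monomer radius


@dataclass(frozen=True)
class BarrierAssessment:
    """A free-energy barrier converted to mechanical requirements."""

    barrier_kbt: float
    temperature_k: float
    applied_force_pn: float
    required_displacement_nm: float


def position_std(p: DiffusionParams) -> float:
    """Standard deviation σ = sqrt(4·D·t) of the 2-D walk, in nm."""
    d_nm2_per_ns = p.d_nm2_per_us * 1e-3
    return math.sqrt(4.0 * d_nm2_per_ns * p.t_ns)


def characteristic_speed(p: DiffusionParams) -> float:
    """Average drift speed 3σ/t of the diffusing molecule, in nm/ns.

    3σ bounds the displacement from the origin with 99.7% certainty for a
    Gaussian walk; dividing by the time window gives the speed scale of
    the net motion.
    """
    return 3.0 * position_std(p) / p.t_ns


def instantaneous_speed(p: DiffusionParams) -> float:
    """Per-time-step speed V = sqrt(4·D/dt), in nm/ns.

    By the central limit theorem the walk's variance is the sum of
    per-step variances, so a step of duration dt covers sqrt(4·D·dt) and
    the instantaneous speed greatly exceeds the characteristic speed.
    """
    d_nm2_per_ns = p.d_nm2_per_us * 1e-3
    dt_ns = p.dt_fs * 1e-6
    return math.sqrt(4.0 * d_nm2_per_ns / dt_ns)


def recommended_pull_speed(p: DiffusionParams, margin: float = 10.0) -> float:
    """Steering speed an order of magnitude below V, in nm/ns.

    This is a recommendation (V/margin), keeping the pull from imposing a
    significant impulse on unconstrained neighbours.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    return instantaneous_speed(p) / margin


def required_stretch(barrier_kbt: float,
                     temperature_k: float = DEFAULT_TEMPERATURE_K,
                     force_pn: float = 50.0) -> BarrierAssessment:
    """Displacement a constant force must act over to supply a barrier.

    With the ~50 pN average load an actin filament sustains, a 400 kBT
    association barrier at 310 K needs a stretch of ≈34 nm.
    """
    if force_pn <= 0:
        raise ValueError("force must be positive")
    if barrier_kbt < 0:
        raise ValueError("barrier must be non-negative")
    disp = barrier_kbt * kbt_pn_nm(temperature_k) / force_pn
    return BarrierAssessment(barrier_kbt=barrier_kbt,
                             temperature_k=temperature_k,
                             applied_force_pn=force_pn,
                             required_displacement_nm=disp)


def geometric_radii(final_com_distance_nm: float,
                    bare_contact_distance_nm: float) -> GeometricRadii:
    """Envelope, monomer and lipid-shell radii from contact distances.

    In a geometrically symmetric pair, the membrane-mediated final
    centre-of-mass distance splits into one lipid-cylinder envelope per
    monomer (radius final/2, e.g. 2.55 nm at a 5.1 nm stand-off), while
    the contact distance without a membrane gives the effective monomer
    radius (bare/2, ≈1 nm); the difference is the lipid shell thickness.
    """
    if bare_contact_distance_nm <= 0:
        raise ValueError("bare contact distance must be positive")
    if final_com_distance_nm < bare_contact_distance_nm:
        raise ValueError("final distance cannot be smaller than bare contact")
    return GeometricRadii(
        envelope_radius_nm=final_com_distance_nm / 2.0,
        monomer_radius_nm=bare_contact_distance_nm / 2.0,
        shell_thickness_nm=(final_com_distance_nm - bare_contact_distance_nm) / 2.0)
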