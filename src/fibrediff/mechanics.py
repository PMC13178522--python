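"""Structural-interpretation arithmetic: from lattice geometry and muscle
stress to per-filament and per-motor mechanics, and √intensity state
fractions.

The hexagonal filament lattice assigns each thick filament a cross-section
of (2/√3)·d10² and each sarcomere a lattice volume (2/√3)·d10²·SL.  Dividing
the myofibrillar stress through the lattice gives the force per thick
filament; dividing by the number of actin-attached motors gives the unitary
motor force, stiffness (force/strain), work per stroke and thermodynamic
efficiency against the free energy of ATP hydrolysis.  Because diffracted
intensity scales with the square of the number of coherently diffracting
units, number fractions follow √(relative intensity): a reflection retaining
50% of its resting intensity implies 1 − √0.5 ≈ 30% of the motors have left
the helically ordered OFF state.

Unit bookkeeping: 1 kPa = 10^-3 pN nm^-2, so stress (kPa) × area (nm²)
× 10^-3 = force (pN).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["MechanicsResult", "csa_from_mass", "lattice_volume",
           "delta_volume", "area_per_filament", "motor_mechanics",
           "released_fraction", "attached_ratio",
           "KPA_NM2_TO_PN", "MOTORS_PER_HALF_FILAMENT", "ATP_FREE_ENERGY"]

#: 1 kPa × 1 nm² in pN (1 kPa = 10^-3 pN/nm²)
KPA_NM2_TO_PN = 1e-3
#: myosin motors per half thick filament (294 = 49 crowns × 6 motors)
MOTORS_PER_HALF_FILAMENT = 294
#: free energy of ATP hydrolysis in muscle, pN·nm per molecule
ATP_FREE_ENERGY = 100.0


@dataclass
class MechanicsResult:
    myofibrillar_stress: float       # kPa
    area_per_filament: float         # nm^2
    force_per_filament: float        # pN
    motors_per_half_filament: float
    attached_fraction: float
    attached_count: float
    force_per_motor: float           # pN
    motor_strain: float              # nm
    motor_stiffness: float           # pN/nm
    working_stroke: float            # nm
    work_per_motor: float            # pN nm
    atp_free_energy: float           # pN nm
    efficiency: float
    notes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def csa_from_mass(wet_weight: float, density: float = 1.06,
                  muscle_length: float = 24.6,
                  fibre_fraction: float = 0.69) -> float:
    """Muscle cross-sectional area (mm²) from wet weight.

    CSA = W / (ρ × L × fibre_fraction) with W in mg, ρ in g·cm⁻³, L in mm;
    fibre length is taken as ``fibre_fraction`` (0.69) of muscle length.
    """
    if min(wet_weight, density, muscle_length, fibre_fraction) <= 0:
        raise ValueError("all inputs must be positive")
    # mg/(g cm^-3 · cm) = 1e-3 cm^2 = 0.1 mm^2
    return wet_weight / (density * (muscle_length / 10.0) * fibre_fraction) / 1000.0 * 100.0


def lattice_volume(d10: float, sl: float) -> float:
    """Filament-lattice volume per sarcomere: V = (2/√3)·d10²·SL (nm³)."""
    if d10 <= 0 or sl <= 0:
        raise ValueError("d10 and SL must be positive")
    return (2.0 / math.sqrt(3.0)) * d10 ** 2 * sl


def delta_volume(rest: tuple[float, float], active: tuple[float, float]) -> float:
    """Fractional lattice-volume change: V_active/V_rest − 1."""
    return lattice_volume(*active) / lattice_volume(*rest) - 1.0


def area_per_filament(d10: float) -> float:
    """Cross-sectional area per thick filament: (2/√3)·d10² (nm²)."""
    if d10 <= 0:
        raise ValueError("d10 must be positive")
    return (2.0 / math.sqrt(3.0)) * d10 ** 2


def motor_mechanics(stress: float, myofibril_fraction: float = 0.8,
                    area_per_fil: float = 1667.0,
                    motors_per_half: float = MOTORS_PER_HALF_FILAMENT,
                    attached_fraction: float = 0.10,
                    strain: float = 4.5, stroke: float = 6.0,
                    atp_energy: float = ATP_FREE_ENERGY) -> MechanicsResult:
    """Chain from muscle stress to unitary motor mechanics.

    stress/myofibril_fraction → myofibrillar stress (kPa); × area per
    filament (nm², ×10⁻³) → force per thick filament (pN); attached_fraction
    × motors per half filament → attached motors; force/attached →
    force per motor (pN); /strain → stiffness (pN/nm); × working stroke →
    work per interaction (pN·nm); /ATP free energy → efficiency.
    """
    if min(stress, myofibril_fraction, area_per_fil, motors_per_half,
           strain, stroke, atp_energy) <= 0:
        raise ValueError("all inputs must be positive")
    if not 0.0 < attached_fraction <= 1.0:
        raise ValueError("attached_fraction must be in (0, 1]")
    notes = []
    stress_myof = stress / myofibril_fraction
    force_fil = stress_myof * area_per_fil * KPA_NM2_TO_PN
    attached = attached_fraction * motors_per_half
    if attached < 1:
        warnings.warn("fewer than one attached motor per half filament")
        notes.append("sub-single-motor regime")
    force_motor = force_fil / attached
    stiffness = force_motor / strain
    work = force_motor * stroke
    return MechanicsResult(
        myofibrillar_stress=stress_myof, area_per_filament=area_per_fil,
        force_per_filament=force_fil, motors_per_half_filament=motors_per_half,
        attached_fraction=attached_fraction, attached_count=attached,
        force_per_motor=force_motor, motor_strain=strain,
        motor_stiffness=stiffness, working_stroke=stroke,
        work_per_motor=work, atp_free_energy=atp_energy,
        efficiency=work / atp_energy, notes=notes)


def released_fraction(I_rel: float) -> float:
    """Fraction of motors released from the OFF array: 1 − √(I/I_rest).

    ``I_rel`` is the retained OFF-state (helical) reflection intensity
    relative to rest.  Values above 1 (more helical order than rest) are
    clipped to 1 with a warning.
    """
    if I_rel < 0:
        raise ValueError("relative intensity must be non-negative")
    if I_rel > 1:
        warnings.warn("relative intensity > 1 clipped (more order than rest)")
        I_rel = 1.0
    return 1.0 - math.sqrt(I_rel)


def attached_ratio(I_rel: float) -> float:
    """Number-fraction ratio from an attachment-sensitive intensity: √I."""
    if I_rel < 0:
        raise ValueError("relative intensity must be non-negative")
    return math.sqrt(I_rel)
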