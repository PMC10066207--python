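"""Mechanochemical energetics of forced rotor rotation.

Closed-form conversions between stall torque, rotation angle, chemical work
and the proton-motive-force voltage needed to reverse the F1 motor. A torque
of ~40 pN nm (typical of F1-ATPases) applied over the ~200 deg of clockwise
rotation required to eject the inhibitor corresponds to ~140 pN nm of work
(~84 kJ/mol); with 8 protons translocated per turn the minimum pmf to
reverse F1 is ~196 mV.
"""

from __future__ import annotations

import math

from scipy.constants import Avogadro, elementary_charge

__all__ = [
    "stall_work",
    "work_per_mole",
    "min_pmf_voltage",
    "round_sig",
    "energetics_report",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (reporting helper only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def stall_work(torque: float, angle: float) -> float:
    """Mechanical work (pN nm) of rotating against ``torque`` by ``angle`` deg.

    W = torque * angle_in_radians. Stored values are never rounded; use
    :func:`round_sig` for 2-s.f. reporting.
    """
    if not math.isfinite(torque) or torque < 0:
        raise ValueError("torque must be a finite non-negative pN nm value")
    return torque * math.radians(angle)


def work_per_mole(work: float) -> float:
    """Convert a single-molecule work (pN nm) to kJ/mol.

    1 pN nm = 1e-21 J, so W_molar = work * 1e-21 * N_A / 1000 kJ/mol.
    """
    return work * 1e-21 * Avogadro / 1e3


def min_pmf_voltage(torque: float, protons_per_turn: int) -> float:
    """Minimum proton-motive force (mV) to reverse F1 against ``torque``.

    One full turn against torque tau costs 2*pi*tau; dividing by the charge
    of ``protons_per_turn`` protons gives the voltage equivalent:
    V = 2*pi*tau*1e-21 J / (n * e), reported in mV.
    """
    if not (isinstance(protons_per_turn, (int,)) or float(protons_per_turn).is_integer()):
        raise ValueError("protons_per_turn must be a positive integer")
    n = int(protons_per_turn)
    if n <= 0:
        raise ValueError("protons_per_turn must be a positive integer")
    if not math.isfinite(torque) or torque <= 0:
        raise ValueError("torque must be positive")
    joules_per_turn = 2.0 * math.pi * torque * 1e-21
    return joules_per_turn / (n * elementary_charge) * 1e3


def energetics_report(
    torque: float, protons_per_turn: int, threshold_angle: float
) -> dict:
    """Labelled summary of the three conversions for a parameter set.

    ``threshold_angle`` is the clockwise rotation (deg) needed for inhibitor
    ejection; it must lie in (0, 360].
    """
    if not (0 < threshold_angle <= 360):
        raise ValueError("threshold_angle must be in (0, 360] deg")
    w = stall_work(torque, threshold_angle)
    return {
        "torque_pn_nm": torque,
        "protons_per_turn": int(protons_per_turn),
        "threshold_angle_deg": threshold_angle,
        "stall_work_pn_nm": w,
        "work_per_mole_kj": work_per_mole(w),
        "min_pmf_voltage_mv": min_pmf_voltage(torque, protons_per_turn),
    }
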