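"""Spine neck electrical resistance under Ohm's law.

The neck is modeled as a cytosolic resistor: R = rho * L / A with cytosolic
resistivity rho (default 109 Ohm cm), neck length L and cross-sectional area
A.  The headline figure uses the per-spine *mean* neck area; a minimum-area
variant and a discretized series integral (sum of rho * dl / A(l) over
stations) are also provided for sensitivity analysis — the series form is
always >= the mean-area form (Cauchy-Schwarz) and is the better model when
organelles locally constrict the neck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import CrossSectionProfile

__all__ = ["ResistivityModel", "neck_resistance", "neck_resistance_integral",
           "voltage_drop"]

OHM_CM_TO_OHM_UM = 1.0e4      # 1 Ohm cm = 10^4 Ohm um
OHM_TO_MOHM = 1.0e-6


@dataclass(frozen=True)
class ResistivityModel:
    """Cytosolic resistivity, stored in Ohm cm."""

    rho_ohm_cm: float = 109.0

    def __post_init__(self) -> None:
        if self.rho_ohm_cm <= 0:
            raise ValueError("resistivity must be positive")

    @property
    def rho_ohm_um(self) -> float:
        return self.rho_ohm_cm * OHM_CM_TO_OHM_UM


def neck_resistance(neck_length_um: float, neck_area_um2: float,
                    model: ResistivityModel | None = None) -> float:
    """R = rho L / A in megaohms (L in um, A in um^2).

    With rho = 109 Ohm cm: R(L=1 um, A=1 um^2) = 1.09 MOhm.
    """
    model = model or ResistivityModel()
    if neck_length_um <= 0 or neck_area_um2 <= 0:
        raise ValueError("neck length and area must be positive")
    r_ohm = model.rho_ohm_um * neck_length_um / neck_area_um2
    return r_ohm * OHM_TO_MOHM


def neck_resistance_integral(profile: CrossSectionProfile,
                             model: ResistivityModel | None = None) -> float:
    """Series resistance sum(rho dl / A) over neck stations, in megaohms.

    Each of the n neck stations represents an equal share dl = L/n of the
    neck length (L between the refined boundaries).  For a uniform neck this
    equals the mean-area formula; for any varying profile it exceeds it
    (AM-HM inequality on the station areas).
    """
    model = model or ResistivityModel()
    sl = profile.neck_slice
    a = profile.area[sl]
    if len(a) < 1:
        raise ValueError("need at least one neck station")
    if np.any(a <= 0):
        raise ValueError("non-positive cross-section area in the neck")
    length = profile.neck_s_end - profile.neck_s_start
    if length <= 0:
        raise ValueError("invalid neck boundaries")
    r_ohm = model.rho_ohm_um * (length / len(a)) * float((1.0 / a).sum())
    return r_ohm * OHM_TO_MOHM


def voltage_drop(resistance_ohm: float, current_a: float) -> float:
    """Ohmic potential difference V = R I, in volts.

    1 GOhm x 1 pA = 1 mV: the scale at which neck geometry starts to matter
    for synaptic signaling.
    """
    if resistance_ohm < 0:
        raise ValueError("resistance must be non-negative")
    return resistance_ohm * current_a
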