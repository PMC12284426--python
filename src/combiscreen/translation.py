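"""In-vitro → in-vivo → human dose translation.

The screen's synergy output feeds a simple dose-reduction argument: if a
combination achieves the target effect with each drug at 1/DRI of its
single-agent dose, the murine in-vivo dose of each drug can be scaled down
from its maximum tolerated dose (MTD) by the combination's averaged DRI,
spread over the planned number of administrations n:

    in-vivo dose per administration = (MTD / averaged DRI) · n

Murine doses are translated to human-equivalent doses (HED) by FDA
body-surface-area scaling; for the mouse the standard divisor is 12.3
(equivalently ×3/37 with km factors 3 and 37):

    HED [mg/kg] = mouse dose [mg/kg] / 12.3

Clinical reference doses printed in mg/m² convert to mg/kg with the human
km factor 37. Display rounding is 2 significant figures; all arithmetic and
comparisons use raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

#: FDA body-surface-area divisor for mouse → human dose conversion
MOUSE_HED_DIVISOR = 12.3

#: FDA km factor for the adult human (mg/m² → mg/kg)
HUMAN_KM = 37.0


@dataclass
class DrugSchedule:
    """Murine dosing constraint for one drug: MTD and administration count."""

    drug_id: str
    mtd: float  # mg/kg
    n_admin: int

    def __post_init__(self):
        if self.mtd <= 0:
            raise DomainError(f"{self.drug_id}: MTD must be positive, got {self.mtd}")
        if self.n_admin < 1:
            raise DomainError(
                f"{self.drug_id}: n_admin must be >= 1, got {self.n_admin}"
            )


@dataclass
class DosePlan:
    """Translated doses for one drug, raw and display-rounded."""

    drug_id: str
    averaged_dri: float
    in_vivo_dose: float  # mg/kg per administration, raw
    hed: float  # mg/kg, raw
    in_vivo_dose_rounded: float = 0.0
    hed_rounded: float = 0.0
    pct_of_clinical: float | None = None

    def __post_init__(self):
        if not self.in_vivo_dose_rounded:
            self.in_vivo_dose_rounded = round_sig(self.in_vivo_dose)
        if not self.hed_rounded:
            self.hed_rounded = round_sig(self.hed)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def average_dri(dri_values) -> float:
    """Arithmetic mean of per-drug Dose-Reduction Indices."""
    values = [float(v) for v in dri_values]
    if not values:
        raise InsufficientDataError("average_dri needs at least one value")
    for v in values:
        if v <= 0:
            raise DomainError(f"DRI values must be positive, got {v}")
    return float(np.mean(values))


def in_vivo_dose(schedule: DrugSchedule, averaged_dri: float) -> float:
    """Murine dose per administration: (MTD / averaged DRI) × n_admin, mg/kg.

    The grouping is (MTD/DRI)·n — n multiplies, it does not divide: e.g.
    MTD 300 mg/kg, averaged DRI 49.8, n=2 gives 300/49.8×2 ≈ 12 mg/kg.
    """
    if averaged_dri <= 0:
        raise DomainError(f"averaged DRI must be positive, got {averaged_dri}")
    return schedule.mtd / averaged_dri * schedule.n_admin


def mouse_to_hed(mouse_dose: float) -> float:
    """Human-equivalent dose (mg/kg) from a murine dose via the 12.3 divisor."""
    if mouse_dose < 0:
        raise DomainError(f"dose must be >= 0, got {mouse_dose}")
    return mouse_dose / MOUSE_HED_DIVISOR


def pct_of_clinical(hed: float, clinical_dose: float) -> float:
    """HED as a percentage of a clinical reference dose (both mg/kg)."""
    if clinical_dose <= 0:
        raise DomainError(f"clinical dose must be positive, got {clinical_dose}")
    if hed < 0:
        raise DomainError(f"HED must be >= 0, got {hed}")
    return 100.0 * hed / clinical_dose


def mg_per_m2_to_mg_per_kg(dose: float, species_factor: float = HUMAN_KM) -> float:
    """Convert a body-surface-area dose (mg/m²) to mg/kg via a km factor."""
    if dose < 0:
        raise DomainError(f"dose must be >= 0, got {dose}")
    if species_factor <= 0:
        raise DomainError(f"species factor must be positive, got {species_factor}")
    return dose / species_factor


def build_dose_plans(
    schedules: list[DrugSchedule],
    dri_by_drug: dict[str, float],
    clinical_doses: dict[str, float] | None = None,
) -> list[DosePlan]:
    """Run the full translation chain for a drug panel.

    The DRI values of all drugs in the panel are averaged once (the
    combination-wide averaged DRI), then each drug's schedule is scaled by
    it. ``clinical_doses`` maps drug_id → clinical reference in mg/kg; drugs
    without a reference get ``pct_of_clinical=None``.
    """
    avg = average_dri([dri_by_drug[s.drug_id] for s in schedules])
    clinical_doses = clinical_doses or {}
    plans = []
    for s in schedules:
        dose = in_vivo_dose(s, avg)
        hed = mouse_to_hed(dose)
        clin = clinical_doses.get(s.drug_id)
        plans.append(
            DosePlan(
                drug_id=s.drug_id,
                averaged_dri=avg,
                in_vivo_dose=dose,
                hed=hed,
                pct_of_clinical=None if clin is None else pct_of_clinical(hed, clin),
            )
        )
    return plans
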