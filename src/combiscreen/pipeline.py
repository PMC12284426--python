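"""One-call screen analysis: wells → viability → fits → ranked synergy.

This is the in-memory composition of the workflow the CLI runs from files:
normalize a plate, fit a median-effect model per drug from its single-drug
conditions, then score every multi-drug condition for CI/DRI. Units are the
canonical per-drug units of the condition keys throughout, so doses entered
as 2 µg/mL and fits built from mg/mL grids compose correctly.
"""

from __future__ import annotations

from .dose_response import DosePoint, MedianEffectFit, fit_median_effect
from .errors import InsufficientDataError
from .screen_data import WellRecord, summarize_conditions
from .synergy import DEFAULT_CI_DELTA, ComboObservation, SynergyResult, screen_combinations


def fits_from_conditions(records) -> dict[str, MedianEffectFit]:
    """Fit one median-effect model per drug from single-drug conditions."""
    points: dict[str, list[DosePoint]] = {}
    units: dict[str, str] = {}
    for r in records:
        if len(r.condition) != 1:
            continue
        drug, conc, unit = r.condition[0]
        points.setdefault(drug, []).append(
            DosePoint.from_viability(conc, r.viability_pct)
        )
        units[drug] = unit
    return {
        drug: fit_median_effect(pts, drug_id=drug, unit=units[drug])
        for drug, pts in points.items()
    }


def score_screen(
    wells: list[WellRecord], delta: float = DEFAULT_CI_DELTA
) -> tuple[dict[str, MedianEffectFit], list[SynergyResult]]:
    """Run the full screen analysis on raw wells.

    Returns the per-drug median-effect fits and the ranked synergy results
    of every multi-drug condition.

    Raises
    ------
    InsufficientDataError
        If the plate holds no multi-drug conditions to score.
    """
    records = summarize_conditions(wells)
    fits = fits_from_conditions(records)
    combos = [
        ComboObservation(
            doses={drug: (conc, unit) for drug, conc, unit in r.condition},
            viability_pct=r.viability_pct,
        )
        for r in records
        if len(r.condition) > 1
    ]
    if not combos:
        raise InsufficientDataError("plate has no multi-drug conditions to score")
    return fits, screen_combinations(fits, combos, delta)
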