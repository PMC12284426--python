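"""Combination Index, Dose-Reduction Index and interaction classification.

For a combination observed to produce a fraction affected ``fa``, each
constituent drug's median-effect fit gives ``Dx_j``, the dose of drug *j*
*alone* that would produce the same ``fa``. The (non-constant-ratio, general
n-drug) Combination Index is

    CI = Σ_j  D_j / Dx_j

where ``D_j`` is the dose actually used in the combination, and the per-drug
Dose-Reduction Index is ``DRI_j = Dx_j / D_j`` — the fold-reduction in drug
*j*'s dose the combination buys at equal effect. CI and DRI are reciprocal
views of the same ratios: ``CI = Σ 1/DRI_j``.

CI < 1 indicates synergy (the combination needs less total "dose equivalent"
than additivity predicts), CI ≈ 1 additivity, CI > 1 antagonism. Because an
experimentally estimated CI is never exactly 1, classification uses an
additive band ``|CI − 1| ≤ δ`` with δ = 0.05 by default.

Each ratio is computed within a single drug, so no cross-drug unit
conversion ever occurs; combination doses are converted to the drug's own
fit unit before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dose_response import FA_EPS, MedianEffectFit, dose_for_fa
from .errors import ConfigurationError, DomainError, UnitError
from .units import canonical_dose, compatible, convert_dose

#: half-width of the additive CI band used by classify_ci
DEFAULT_CI_DELTA = 0.05

LABELS = ("synergistic", "additive", "antagonistic")


@dataclass
class ComboObservation:
    """One combination condition: per-drug doses and the observed effect.

    ``fa`` may be given directly; otherwise it is derived from
    ``viability_pct`` clamped to [0, 100] and nudged into the open interval
    (FA_EPS, 1−FA_EPS) so the median-effect inverse stays defined.
    """

    doses: dict[str, tuple[float, str]]
    viability_pct: float | None = None
    fa: float | None = None

    def __post_init__(self):
        if not self.doses:
            raise DomainError("a combination needs at least one dosed drug")
        for drug, (dose, _unit) in self.doses.items():
            if dose <= 0:
                raise DomainError(f"{drug}: combination dose must be positive")
        if self.fa is None:
            if self.viability_pct is None:
                raise DomainError("provide either fa or viability_pct")
            v = min(max(self.viability_pct, 0.0), 100.0)
            self.fa = min(max(1.0 - v / 100.0, FA_EPS), 1.0 - FA_EPS)
        if not 0.0 < self.fa < 1.0:
            raise DomainError(f"fa must lie strictly in (0, 1), got {self.fa}")

    def key(self) -> tuple:
        parts = []
        for drug in sorted(self.doses):
            dose, unit = self.doses[drug]
            value, canon = canonical_dose(dose, unit)
            parts.append((drug, float(f"{value:.12g}"), canon))
        return tuple(parts)

    def total_dose(self) -> float:
        """Sum of unit-normalized dose values (tie-break metric only)."""
        return sum(canonical_dose(d, u)[0] for d, u in self.doses.values())


@dataclass
class SynergyResult:
    """Scored combination: Dx and DRI per drug, CI and its class label."""

    combo: ComboObservation
    dx: dict[str, float]
    dri: dict[str, float]
    ci: float
    label: str


def classify_ci(ci: float, delta: float = DEFAULT_CI_DELTA) -> str:
    """Map a CI value to synergistic / additive / antagonistic.

    Values within ``delta`` of 1 are called additive; below, synergistic;
    above, antagonistic.
    """
    if ci <= 0:
        raise DomainError(f"CI must be positive, got {ci}")
    if ci < 1.0 - delta:
        return "synergistic"
    if ci > 1.0 + delta:
        return "antagonistic"
    return "additive"


def combination_index(
    fits: dict[str, MedianEffectFit],
    combo: ComboObservation,
    delta: float = DEFAULT_CI_DELTA,
) -> SynergyResult:
    """Score one combination against single-drug median-effect fits.

    Raises
    ------
    ConfigurationError
        A combination drug has no median-effect fit.
    UnitError
        A combination dose's unit cannot be converted to its fit's unit.
    """
    dx: dict[str, float] = {}
    dri: dict[str, float] = {}
    ci = 0.0
    for drug, (dose, unit) in combo.doses.items():
        fit = fits.get(drug)
        if fit is None:
            raise ConfigurationError(f"no median-effect fit for drug {drug!r}")
        if not compatible(unit, fit.unit):
            raise UnitError(
                f"{drug}: combination dose unit {unit!r} incompatible with "
                f"fit unit {fit.unit!r}"
            )
        dose_native = convert_dose(dose, unit, fit.unit)
        dx_j = dose_for_fa(fit, combo.fa)
        dx[drug] = dx_j
        dri[drug] = dx_j / dose_native
        ci += dose_native / dx_j
    return SynergyResult(combo=combo, dx=dx, dri=dri, ci=ci, label=classify_ci(ci, delta))


def screen_combinations(
    fits: dict[str, MedianEffectFit],
    combos: list[ComboObservation],
    delta: float = DEFAULT_CI_DELTA,
) -> list[SynergyResult]:
    """Score and rank combinations.

    Results are sorted by observed viability ascending (most cytotoxic
    first), then CI ascending, then total unit-normalized dose ascending;
    the sort is stable, so fully tied combinations keep input order.

    Per-combination errors are re-raised annotated with the combination key.
    """
    if not combos:
        raise ConfigurationError("screen_combinations needs at least one combination")
    results = []
    for combo in combos:
        try:
            results.append(combination_index(fits, combo, delta))
        except (ConfigurationError, UnitError, DomainError) as err:
            raise type(err)(f"combination {combo.key()}: {err}") from err
    viab = lambda r: (
        r.combo.viability_pct
        if r.combo.viability_pct is not None
        else 100.0 * (1.0 - r.combo.fa)
    )
    return sorted(results, key=lambda r: (viab(r), r.ci, r.combo.total_dose()))
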