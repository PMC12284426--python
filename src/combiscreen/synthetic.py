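"""Seeded simulators for screen plates and mouse cohorts.

The screen simulator emulates the nanodroplet assay's statistical structure:
wells of three roles (untreated control, cell-free background, treated),
~100 cells in 200 nL per well, three replicates per condition, and a
dispensing coefficient of variation of 0.8%. Single-drug conditions draw
their true viability from median-effect curves; combination conditions are
planted with a *known* Combination Index — the generating fraction affected
is the unique solution of

    Σ_j  dose_j / Dx_j(fa)  =  CI_target

(the left side is strictly decreasing in fa, so bisection is well posed).
This makes CI estimation a parameter-recovery problem with known ground
truth rather than relying on any mechanistic interaction model.

Noise is multiplicative lognormal parameterized to the target CV (mean 1),
because luminescence is positive and the platform's precision is quoted as
a CV. Poisson cell-count variation (CV ≈ 1/√cells) can be folded in as an
extra variance term; it is off by default since the platform quotes only
the composite 0.8% figure.

The cohort simulator emulates the trial: exponential tumor growth
V(t) = V₀·e^{g·t} until the 5 mm treatment trigger, then growth damped by a
per-arm regression rate (net rate g − r), optional stochastic relapse after
a delay, twice-weekly noisy 3-axis scans, and euthanasia at the 15 mm
endpoint. Default calibration: vehicle tumors grow 15-fold in 2 weeks,
single-drug arms 6-fold in 2 weeks, the combination arm regresses to
undetectable within ~2 weeks and relapses with probability 0.4 about three
weeks after treatment, over a 12-week follow-up of 5 animals per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dose_response import MedianEffectFit, dose_for_fa, fa_at_dose
from .errors import ConfigurationError, DomainError
from .invivo import (
    ENDPOINT_MM,
    TRIGGER_MM,
    TumorMeasurement,
    TumorTrack,
    endpoint_check,
)
from .screen_data import Dose, WellRecord

_FA_LO = 1e-6
_FA_HI = 1.0 - 1e-6


@dataclass(frozen=True)
class DrugModel:
    """Ground-truth median-effect parameters of one simulated drug."""

    drug_id: str
    dm: float
    m: float
    unit: str

    def fit(self) -> MedianEffectFit:
        return MedianEffectFit(
            drug_id=self.drug_id, dm=self.dm, m=self.m, r=1.0, n_points=0, unit=self.unit
        )


@dataclass(frozen=True)
class ComboSpec:
    """A planted combination: per-drug doses and its target CI."""

    doses: dict[str, float]  # in each drug's native unit
    target_ci: float


@dataclass
class ScreenSimConfig:
    """Study conditions for one simulated screen plate."""

    seed: int
    drugs: list[DrugModel]
    dose_grids: dict[str, list[float]]
    combos: list[ComboSpec] = field(default_factory=list)
    alpha_signal: float = 20000.0
    beta_signal: float = 400.0
    cv: float = 0.008
    cells_per_well: int = 100
    replicates: int = 3
    cell_count_noise: bool = False
    plate_id: str = "SIM-01"

    def __post_init__(self):
        if self.alpha_signal <= self.beta_signal:
            raise ConfigurationError("alpha_signal must exceed beta_signal")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        for d in self.drugs:
            if d.dm <= 0 or d.m <= 0:
                raise ConfigurationError(f"{d.drug_id}: dm and m must be positive")
        known = {d.drug_id for d in self.drugs}
        for drug in self.dose_grids:
            if drug not in known:
                raise ConfigurationError(f"dose grid for unknown drug {drug!r}")
        for combo in self.combos:
            for drug in combo.doses:
                if drug not in known:
                    raise ConfigurationError(f"combo doses unknown drug {drug!r}")

    def effective_cv(self) -> float:
        """Composite CV: dispensing CV, plus Poisson cell-count term if enabled."""
        if not self.cell_count_noise:
            return self.cv
        return math.sqrt(self.cv**2 + 1.0 / self.cells_per_well)


def solve_fa_for_ci(
    fits: dict[str, MedianEffectFit], doses: dict[str, float], target_ci: float
) -> float:
    """Solve Σ_j dose_j / Dx_j(fa) = target_ci for fa by bisection.

    CI(fa) is strictly decreasing in fa (each Dx_j grows with fa), so there
    is at most one root on (0, 1).

    Raises
    ------
    ConfigurationError
        If the target CI is outside the attainable range on
        fa ∈ (1e-6, 1−1e-6) for these doses.
    """
    if target_ci <= 0:
        raise DomainError(f"target CI must be positive, got {target_ci}")

    def ci_at(fa: float) -> float:
        return sum(d / dose_for_fa(fits[drug], fa) for drug, d in doses.items())

    lo, hi = ci_at(_FA_HI), ci_at(_FA_LO)  # CI decreasing: lo at high fa
    if not lo <= target_ci <= hi:
        raise ConfigurationError(
            f"target CI {target_ci} unattainable for doses {doses}: "
            f"CI range on fa∈({_FA_LO}, {_FA_HI}) is [{lo:.4g}, {hi:.4g}]"
        )
    return float(brentq(lambda fa: ci_at(fa) - target_ci, _FA_LO, _FA_HI, xtol=1e-14))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_screen(config: ScreenSimConfig) -> list[WellRecord]:
    """Generate one plate of wells under the configured study conditions.

    Emits, per replicate: one control and one background well, one treated
    well per single-drug grid dose, and one per combination. A well's noise-
    free luminescence is ``β + (α − β) · viability/100``; lognormal noise at
    the effective CV multiplies it. Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    fits = {d.drug_id: d.fit() for d in config.drugs}
    models = {d.drug_id: d for d in config.drugs}
    cv = config.effective_cv()

    conditions: list[tuple[list[Dose], float]] = []  # (doses, true viability %)
    for drug_id, grid in config.dose_grids.items():
        model = models[drug_id]
        for dose in grid:
            fa = fa_at_dose(fits[drug_id], dose)
            conditions.append(
                ([Dose(drug_id, dose, model.unit)], 100.0 * (1.0 - fa))
            )
    for combo in config.combos:
        fa = solve_fa_for_ci(fits, combo.doses, combo.target_ci)
        doses = [
            Dose(drug, combo.doses[drug], models[drug].unit)
            for drug in sorted(combo.doses)
        ]
        conditions.append((doses, 100.0 * (1.0 - fa)))

    alpha, beta = config.alpha_signal, config.beta_signal
    wells: list[WellRecord] = []
    counter = 0

    def emit(role: str, doses: list[Dose], clean_signal: float, replicate: int):
        nonlocal counter
        counter += 1
        noise = _lognormal_factors(rng, cv, 1)[0]
        wells.append(
            WellRecord(
                plate_id=config.plate_id,
                well_id=f"W{counter:04d}",
                role=role,
                doses=doses,
                luminescence=float(clean_signal * noise),
                replicate=replicate,
            )
        )

    for rep in range(1, config.replicates + 1):
        emit("control", [], alpha, rep)
        emit("background", [], beta, rep)
        for doses, viability in conditions:
            emit("treated", doses, beta + (alpha - beta) * viability / 100.0, rep)
    return wells


def default_screen_config(seed: int, **overrides) -> ScreenSimConfig:
    """Screen conditions mirroring the primary-cell panel.

    Median-effect doses sit at the measured primary-cell IC50s — CP 3.38
    mg/mL, DOX 4.55 µg/mL, VCR 13.27 µg/mL — with sigmoidicity 1.5; each
    drug gets a 7-point geometric dose grid spanning dm/8 … 8·dm, and the
    optimal screen combination (2 mg/mL CP + 4 µg/mL DOX + 2 µg/mL VCR) is
    planted with target CI 0.5.
    """
    drugs = [
        DrugModel("CP", dm=3.38, m=1.5, unit="mg/mL"),
        DrugModel("DOX", dm=4.55, m=1.5, unit="ug/mL"),
        DrugModel("VCR", dm=13.27, m=1.5, unit="ug/mL"),
    ]
    grids = {
        d.drug_id: [float(f"{x:.6g}") for x in d.dm * np.geomspace(1 / 8, 8, 7)]
        for d in drugs
    }
    combos = [ComboSpec(doses={"CP": 2.0, "DOX": 4.0, "VCR": 2.0}, target_ci=0.5)]
    params = dict(
        seed=seed, drugs=drugs, dose_grids=grids, combos=combos
    )
    params.update(overrides)
    return ScreenSimConfig(**params)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class ArmEffect:
    """Post-treatment dynamics of one arm.

    ``regression_rate`` (per day) is subtracted from the intrinsic growth
    rate after treatment: 0 leaves vehicle-like growth, values above the
    growth rate shrink the tumor. Relapsed tumors regrow at the intrinsic
    rate from the relapse day onward.
    """

    regression_rate: float
    relapse_prob: float = 0.0
    relapse_delay_days: float = 21.0


@dataclass
class CohortSimConfig:
    """Study conditions for one simulated preclinical trial."""

    seed: int
    arm_effects: dict[str, ArmEffect]
    n_per_arm: int = 5
    baseline_volume_mm3: float = 30.0
    growth_rate_per_day: float = math.log(15.0) / 14.0
    measurement_cv: float = 0.05
    max_followup_days: int = 84
    scan_interval_days: tuple[int, ...] = (3, 4)  # twice weekly

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ConfigurationError("n_per_arm must be >= 1")
        if self.max_followup_days < 1:
            raise ConfigurationError("max_followup_days must be >= 1")
        if self.baseline_volume_mm3 <= 0:
            raise ConfigurationError("baseline_volume_mm3 must be positive")


def default_cohort_config(seed: int, **overrides) -> CohortSimConfig:
    """Five-arm trial conditions: vehicle, three single drugs, combination.

    Vehicle tumors grow 15-fold in two weeks (g = ln 15 / 14 ≈ 0.193/day);
    single-drug arms still grow ~6-fold in two weeks (net ln 6 / 14);
    the combination regresses tumors below detectability within ~2 weeks and
    relapses with probability 0.4 after a 21-day delay.
    """
    g = math.log(15.0) / 14.0
    single = ArmEffect(regression_rate=g - math.log(6.0) / 14.0)
    params = dict(
        seed=seed,
        arm_effects={
            "vehicle": ArmEffect(regression_rate=0.0),
            "CP": single,
            "DOX": single,
            "VCR": single,
            "combination": ArmEffect(
                regression_rate=g + 0.35, relapse_prob=0.4, relapse_delay_days=21.0
            ),
        },
    )
    params.update(overrides)
    return CohortSimConfig(**params)


def _true_volume(
    t: float,
    trigger_day: float,
    v_trigger: float,
    g: float,
    effect: ArmEffect,
    relapse_day: float | None,
    v0: float,
) -> float:
    """Noise-free volume at absolute time t for one subject."""
    if t <= trigger_day:
        return v0 * math.exp(g * t)
    if relapse_day is not None and t > relapse_day:
        v_rel = max(
            _true_volume(relapse_day, trigger_day, v_trigger, g, effect, None, v0),
            1.0,
        )
        return v_rel * math.exp(g * (t - relapse_day))
    return v_trigger * math.exp((g - effect.regression_rate) * (t - trigger_day))


def simulate_cohort(config: CohortSimConfig) -> tuple[list[TumorTrack], list[tuple]]:
    """Generate tumor tracks and survival events for each arm.

    Each subject grows exponentially from ``baseline_volume_mm3`` until a
    scheduled scan first meets the treatment trigger; that scan becomes its
    day 0 (earlier scans get negative days). Scans occur twice weekly with
    lognormal per-axis noise at ``measurement_cv``; axes are reported as the
    equal-axis diameter (2V)^{1/3}. A subject is euthanized at the first
    scan whose measured maximal diameter meets the endpoint; survivors are
    censored at ``max_followup_days`` past their trigger.

    Returns ``(tracks, events)`` with events as
    ``(subject_id, arm, event_day, status)`` (days relative to trigger).
    """
    rng = np.random.default_rng(config.seed)
    g = config.growth_rate_per_day
    v0 = config.baseline_volume_mm3
    v_trigger_threshold = 0.5 * TRIGGER_MM**3

    # absolute scan times: 0, 3, 7, 10, 14, ... (twice weekly)
    scan_times = [0.0]
    horizon = config.max_followup_days + 4 * math.ceil(
        max(0.0, math.log(max(v_trigger_threshold / v0, 1.0)) / g) if g > 0 else 0
    )
    i = 0
    while scan_times[-1] < horizon + config.max_followup_days:
        scan_times.append(scan_times[-1] + config.scan_interval_days[i % 2])
        i += 1

    tracks: list[TumorTrack] = []
    events: list[tuple] = []
    for arm, effect in config.arm_effects.items():
        for k in range(config.n_per_arm):
            sid = f"{arm}-{k + 1:02d}"
            relapses = rng.random() < effect.relapse_prob
            # locate the trigger scan on the noise-free trajectory
            trigger_day = None
            for t in scan_times:
                if v0 * math.exp(g * t) >= v_trigger_threshold:
                    trigger_day = t
                    break
            if trigger_day is None:
                raise ConfigurationError(
                    "tumors never reach the treatment trigger within the horizon"
                )
            v_trigger = v0 * math.exp(g * trigger_day)
            relapse_day = (
                trigger_day + effect.relapse_delay_days if relapses else None
            )

            track = TumorTrack(subject_id=sid, arm=arm)
            event = None
            for t in scan_times:
                day = int(round(t - trigger_day))
                if day > config.max_followup_days:
                    break
                v = _true_volume(
                    t, trigger_day, v_trigger, g, effect, relapse_day, v0
                )
                axis = (2.0 * v) ** (1.0 / 3.0)
                noisy = axis * _lognormal_factors(rng, config.measurement_cv, 3)
                m = TumorMeasurement(
                    subject_id=sid,
                    day=day,
                    width=float(noisy[0]),
                    depth=float(noisy[1]),
                    height=float(noisy[2]),
                )
                track.measurements.append(m)
                if day >= 0 and endpoint_check(m):
                    event = (day, "euthanized")
                    break
            if event is None:
                event = (config.max_followup_days, "censored")
            track.event = event
            track.measurements.sort(key=lambda m: m.day)
            tracks.append(track)
            events.append((sid, arm, event[0], event[1]))
    return tracks, events
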