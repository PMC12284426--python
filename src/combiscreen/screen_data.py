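"""Plate data model, I/O, viability normalization and dispensing QC.

A screen plate (nanodroplet chip or 384-well plate) carries wells of three
roles:

* ``control`` — cells, no drug: its luminescence is the 100%-viability anchor α;
* ``background`` — no cells: the 0% anchor β;
* ``treated`` — cells plus one or more drugs at known concentrations (signal γ).

Viability of a treated well is the affine rescaling
``100 · (γ − β) / (α − β)``, with α and β taken as per-plate replicate means
(each chip is sealed and read separately, so anchors are not pooled across
plates). Values outside [0, 100] are reported as computed and flagged, never
clamped — out-of-range viabilities are an assay-failure signal.

Dispensing precision is summarized as the coefficient of variation of
replicate signals, ``CV% = 100 · sd / mean`` with the sample (n−1) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    DegenerateSignalError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)
from .units import canonical_dose

ROLES = ("control", "background", "treated")

#: maximum drug/dose/unit triplets in the plate CSV layout
MAX_DRUGS = 3

_BASE_COLUMNS = ["plate_id", "well_id", "role", "replicate", "luminescence"]


@dataclass(frozen=True)
class Dose:
    """One drug's dose in a well: identifier, concentration and unit string."""

    drug_id: str
    concentration: float
    unit: str

    def __post_init__(self):
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} for {self.drug_id}"
            )


@dataclass
class WellRecord:
    """A single well: role, dose list and raw luminescence signal."""

    plate_id: str
    well_id: str
    role: str
    doses: list[Dose]
    luminescence: float
    replicate: int = 1

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(
                f"well {self.well_id}: role {self.role!r} not in {ROLES}"
            )
        if self.role in ("control", "background") and self.doses:
            raise ValidationError(
                f"well {self.well_id}: {self.role} wells must carry no doses"
            )
        if self.role == "treated" and not self.doses:
            raise ValidationError(
                f"well {self.well_id}: treated wells need at least one dose"
            )
        if self.luminescence < 0:
            raise ValidationError(
                f"well {self.well_id}: negative luminescence {self.luminescence}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"well {self.well_id}: replicate must be >= 1, got {self.replicate}"
            )

    def condition_key(self) -> tuple:
        """Canonical dose-combination key (unit-normalized, order-free).

        Concentrations are rounded to 12 significant digits after unit
        normalization so that 2 µg/mL and 0.002 mg/mL hash identically.
        """
        parts = []
        for d in sorted(self.doses, key=lambda d: d.drug_id):
            value, unit = canonical_dose(d.concentration, d.unit)
            parts.append((d.drug_id, float(f"{value:.12g}"), unit))
        return tuple(parts)


@dataclass
class ViabilityRecord:
    """Replicate-mean viability of one dose combination on a plate."""

    condition: tuple
    viability_pct: float
    sd_pct: float
    n_wells: int
    qc_flag: str = ""

    def __post_init__(self):
        if self.n_wells < 1:
            raise ValidationError("n_wells must be >= 1")
        if self.n_wells == 1 and self.sd_pct != 0:
            raise ValidationError("sd_pct must be 0 for a single well")


@dataclass
class PlateQC:
    """Dispensing-precision summary of one plate's replicate signals."""

    plate_id: str
    signal_mean: float
    signal_sd: float
    cv_pct: float


def normalize_viability(gamma: float, alpha: float, beta: float) -> float:
    """Viability % of a treated signal γ against control α and background β.

    Returns ``100 · (γ − β) / (α − β)`` without clamping; callers flag values
    outside [0, 100] downstream.

    Raises
    ------
    DegenerateControlError
        If α ≤ β (controls do not exceed background; the assay is broken).
    """
    if alpha <= beta:
        raise DegenerateControlError(
            f"control signal {alpha} does not exceed background {beta}"
        )
    return 100.0 * (gamma - beta) / (alpha - beta)


def plate_cv(signals) -> float:
    """Coefficient of variation (%) of replicate signals, 100·sd/mean.

    Uses the sample standard deviation (n−1 denominator); replicate counts on
    these chips are small, so the unbiased form is conventional.
    """
    x = np.asarray(list(signals), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 signals, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise DegenerateSignalError(f"mean signal must be positive, got {mean}")
    return 100.0 * x.std(ddof=1) / mean


def plate_qc(wells: list[WellRecord], role: str = "control") -> list[PlateQC]:
    """Per-plate CV summary over wells of one role (default: control wells)."""
    out = []
    for plate_id, group in _group_by_plate(wells).items():
        sig = [w.luminescence for w in group if w.role == role]
        if len(sig) < 2:
            raise InsufficientDataError(
                f"plate {plate_id}: need >= 2 {role} wells for QC, got {len(sig)}"
            )
        arr = np.asarray(sig, dtype=float)
        out.append(
            PlateQC(
                plate_id=plate_id,
                signal_mean=float(arr.mean()),
                signal_sd=float(arr.std(ddof=1)),
                cv_pct=plate_cv(arr),
            )
        )
    return out


def _group_by_plate(wells: list[WellRecord]) -> dict[str, list[WellRecord]]:
    groups: dict[str, list[WellRecord]] = {}
    for w in wells:
        groups.setdefault(w.plate_id, []).append(w)
    return groups


def summarize_conditions(wells: list[WellRecord]) -> list[ViabilityRecord]:
    """Normalize every treated well and aggregate per dose combination.

    α and β are the per-plate means of control and background wells; each
    treated well is normalized against its own plate's anchors, then wells
    sharing a canonical dose-combination key (possibly across plates) are
    averaged. Conditions whose mean viability falls outside [0, 100] get a
    ``qc_flag`` of ``"out_of_range"``.

    Raises
    ------
    DegenerateControlError
        If any plate holding treated wells lacks control or background wells.
    """
    per_condition: dict[tuple, list[float]] = {}
    order: list[tuple] = []
    for plate_id, group in _group_by_plate(wells).items():
        treated = [w for w in group if w.role == "treated"]
        if not treated:
            continue
        controls = [w.luminescence for w in group if w.role == "control"]
        backgrounds = [w.luminescence for w in group if w.role == "background"]
        if not controls or not backgrounds:
            raise DegenerateControlError(
                f"plate {plate_id}: normalization needs >= 1 control and "
                f">= 1 background well"
            )
        alpha = float(np.mean(controls))
        beta = float(np.mean(backgrounds))
        for w in treated:
            key = w.condition_key()
            if key not in per_condition:
                per_condition[key] = []
                order.append(key)
            per_condition[key].append(normalize_viability(w.luminescence, alpha, beta))

    records = []
    for key in order:
        vals = np.asarray(per_condition[key], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        flag = "" if 0.0 <= mean <= 100.0 else "out_of_range"
        records.append(
            ViabilityRecord(
                condition=key,
                viability_pct=mean,
                sd_pct=sd,
                n_wells=int(vals.size),
                qc_flag=flag,
            )
        )
    return records


# ---------------------------------------------------------------------------
# I/O


def read_plate(path, dialect: str = "standard") -> list[WellRecord]:
    """Read a plate CSV into validated :class:`WellRecord` objects.

    Expected columns: ``plate_id, well_id, role, replicate, luminescence``
    plus up to three ``drug_i, conc_i, unit_i`` triplets; empty drug cells
    mean "no i-th drug". ``dialect`` is reserved for future layout variants;
    only ``"standard"`` is defined.
    """
    if dialect != "standard":
        raise SchemaError(f"unknown plate layout dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"plate_id": str, "well_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    wells = []
    for idx, row in df.iterrows():
        lum = float(row["luminescence"])
        if lum < 0:
            raise ValidationError(
                f"{path.name} row {idx + 2}: negative luminescence {lum}"
            )
        doses = []
        for i in range(1, MAX_DRUGS + 1):
            drug_col = f"drug_{i}"
            if drug_col not in df.columns:
                continue
            drug = row.get(drug_col)
            if pd.isna(drug) or str(drug) == "":
                continue
            conc_col, unit_col = f"conc_{i}", f"unit_{i}"
            if conc_col not in df.columns or unit_col not in df.columns:
                raise SchemaError(
                    f"{path.name}: column {drug_col} present without "
                    f"{conc_col}/{unit_col}"
                )
            doses.append(
                Dose(
                    drug_id=str(drug),
                    concentration=float(row[conc_col]),
                    unit=str(row[unit_col]),
                )
            )
        try:
            wells.append(
                WellRecord(
                    plate_id=str(row["plate_id"]),
                    well_id=str(row["well_id"]),
                    role=str(row["role"]),
                    doses=doses,
                    luminescence=lum,
                    replicate=int(row["replicate"]),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path.name} row {idx + 2}: {err}") from err
    return wells


def write_plate(wells: list[WellRecord], path, header_lines: list[str] | None = None):
    """Write wells to the plate CSV layout (inverse of :func:`read_plate`)."""
    rows = []
    for w in wells:
        row = {
            "plate_id": w.plate_id,
            "well_id": w.well_id,
            "role": w.role,
            "replicate": w.replicate,
            "luminescence": repr(float(w.luminescence)),
        }
        for i, d in enumerate(w.doses, start=1):
            row[f"drug_{i}"] = d.drug_id
            row[f"conc_{i}"] = repr(float(d.concentration))
            row[f"unit_{i}"] = d.unit
        rows.append(row)
    columns = list(_BASE_COLUMNS)
    n_drugs = max((len(w.doses) for w in wells), default=0)
    for i in range(1, n_drugs + 1):
        columns += [f"drug_{i}", f"conc_{i}", f"unit_{i}"]
    df = pd.DataFrame(rows, columns=columns)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_viability_table(
    records: list[ViabilityRecord], path, header_lines: list[str] | None = None
):
    """Write condition summaries as TSV: dose columns + viability statistics."""
    n_drugs = max((len(r.condition) for r in records), default=0)
    rows = []
    for r in records:
        row = {}
        for i, (drug, conc, unit) in enumerate(r.condition, start=1):
            row[f"drug_{i}"] = drug
            row[f"conc_{i}"] = f"{conc:.10g}"
            row[f"unit_{i}"] = unit
        row.update(
            viability_pct=f"{r.viability_pct:.6f}",
            sd_pct=f"{r.sd_pct:.6f}",
            n_wells=r.n_wells,
            qc_flag=r.qc_flag,
        )
        rows.append(row)
    columns = []
    for i in range(1, n_drugs + 1):
        columns += [f"drug_{i}", f"conc_{i}", f"unit_{i}"]
    columns += ["viability_pct", "sd_pct", "n_wells", "qc_flag"]
    df = pd.DataFrame(rows, columns=columns)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, sep="\t")


def read_viability_table(path) -> list[ViabilityRecord]:
    """Read a TSV written by :func:`write_viability_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        cond = []
        for i in range(1, MAX_DRUGS + 1):
            col = f"drug_{i}"
            if col in df.columns and not pd.isna(row.get(col)):
                cond.append(
                    (str(row[col]), float(row[f"conc_{i}"]), str(row[f"unit_{i}"]))
                )
        records.append(
            ViabilityRecord(
                condition=tuple(cond),
                viability_pct=float(row["viability_pct"]),
                sd_pct=float(row["sd_pct"]),
                n_wells=int(row["n_wells"]),
                qc_flag="" if pd.isna(row.get("qc_flag")) else str(row["qc_flag"]),
            )
        )
    return records
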