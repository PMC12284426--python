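# combiscreen

Analysis toolkit for miniaturized drug-combination screens and their
translation to preclinical dosing. It was built around a nanodroplet
cytotoxicity platform (~100 cells in 200 nL per sealed well, CellTiter-Glo
luminescence readout, dispensing CV ≈ 0.8%) used to find low-dose synergistic
chemotherapy combinations — the motivating application is the CDV
(cyclophosphamide + doxorubicin + vincristine) induction backbone for
high-risk neuroblastoma — but every stage is generic:

1. **Normalization & QC** (`combiscreen.screen_data`) — plate CSVs to
   per-condition viability, `viability% = 100·(γ−β)/(α−β)` with per-plate
   untreated (α) and cell-free (β) anchors; dispensing CV as `100·sd/mean`.
2. **Dose–response** (`combiscreen.dose_response`) — variable-slope 4PL IC50
   fits, and Chou median-effect fits `fa/fu = (D/Dm)^m` via OLS on the
   linearized plot `log(fa/fu) = m·log D − m·log Dm`.
3. **Synergy** (`combiscreen.synergy`) — non-constant-ratio Combination Index
   `CI = Σ_j D_j/Dx_j` and per-drug Dose-Reduction Index `DRI_j = Dx_j/D_j`,
   with CI < 1 synergistic, ≈ 1 additive, > 1 antagonistic.
4. **Dose translation** (`combiscreen.translation`) — murine dose per
   administration `(MTD / averaged DRI) · n`, FDA body-surface-area HED
   conversion (mouse divisor 12.3), and percent-of-clinical comparisons.
5. **In-vivo analytics** (`combiscreen.invivo`) — ellipsoid tumor volumes
   `½·w·d·h`, 5 mm treatment trigger / 15 mm endpoint logic, spider-plot
   responses `100·(b_x−a)/a`, relapse detection, Kaplan–Meier curves and the
   Mantel–Cox log-rank test (via lifelines).
6. **Simulators** (`combiscreen.synthetic`) — seeded generators for screen
   plates (with combinations planted at a known CI) and animal cohorts, so
   the whole pipeline is testable end to end without external data.

## Worked example: from measured DRIs to a dose plan

The screen's optimal CDV combination gave per-drug DRIs of 3.16 (CP),
6.74 (DOX) and 139.50 (VCR). With murine MTDs of 300 / 10 / 1 mg/kg and
2 / 3 / 3 planned administrations:

```python
from combiscreen import DrugSchedule, build_dose_plans, round_sig

schedules = [
    DrugSchedule("CP", mtd=300.0, n_admin=2),
    DrugSchedule("DOX", mtd=10.0, n_admin=3),
    DrugSchedule("VCR", mtd=1.0, n_admin=3),
]
plans = build_dose_plans(
    schedules,
    {"CP": 3.16, "DOX": 6.74, "VCR": 139.50},
    clinical_doses={"DOX": 0.68},
)
for p in plans:
    print(p.drug_id, round_sig(p.averaged_dri, 3), p.in_vivo_dose_rounded,
          p.hed_rounded, p.pct_of_clinical)
```

prints

```
CP 49.8 12.0 0.98 None
DOX 49.8 0.6 0.049 7.202410790939942
VCR 49.8 0.06 0.0049 None
```

i.e. an averaged DRI of 49.8 turns the MTDs into 12, 0.6 and 0.06 mg/kg per
administration; the human-equivalent doses are ≈0.98, 0.049 and 0.0049
mg/kg, and the DOX dose is ≈7.2% of its 0.68 mg/kg clinical reference —
an order of magnitude below clinical intensity at equal in-vitro effect.

A full in-memory screen analysis is one call:

```python
from combiscreen import default_screen_config, simulate_screen, score_screen

wells = simulate_screen(default_screen_config(seed=1))
fits, ranked = score_screen(wells)
print(ranked[0].ci, ranked[0].label)   # 0.5025…, 'synergistic'
```

## Command line

```sh
combiscreen simulate screen --seed 1 --out plate.csv
combiscreen normalize plate.csv --out viability.tsv
combiscreen fit doseresponse.csv --out fits.json
combiscreen synergy combos.csv fits.json --out synergy.tsv
combiscreen translate synergy.tsv schedule.json --out doseplan.tsv
combiscreen simulate cohort --seed 1 --out-measurements m.csv --out-events e.csv
combiscreen invivo m.csv e.csv --outdir results/
```

All commands are deterministic given inputs and `--seed`, and stamp their
outputs with the tool version, seed and config hash.

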