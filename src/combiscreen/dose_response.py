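"""Single-drug concentration–effect models.

Two models are fitted per drug:

* the variable-slope four-parameter logistic (4PL), for IC50 reporting::

      viability(D) = bottom + (top - bottom) / (1 + (D / IC50)^h)

  in the decreasing form (h > 0 kills cells as D grows). IC50 is the
  inflection dose (relative IC50, the variable-slope convention).

* the Chou median-effect model, which powers all synergy arithmetic::

      fa / (1 - fa) = (D / Dm)^m

  where ``fa`` is the fraction affected (1 − viability/100), ``Dm`` the
  median-effect dose (fa = 0.5) and ``m`` the sigmoidicity. The model is
  linear in log space — ``log(fa/fu) = m·log D − m·log Dm`` — so the fit is a
  closed-form ordinary least squares on the median-effect plot, with ``r``
  the Pearson correlation of the plotted points.

Median-effect fits only use points whose fa lies strictly inside (0, 1):
viabilities are clamped to [0, 100] first and fa values within 1e-6 of the
boundaries are excluded, as is standard practice for this linearization.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError, NonConvergenceError

#: fa values within this distance of 0 or 1 are excluded from the linearized fit
FA_EPS = 1e-6

_SLOPE_SEEDS = (0.5, 1.0, 2.0, 4.0)
_N_IC50_SEEDS = 5
_BOTTOM_BOUNDS = (-10.0, 50.0)
_TOP_BOUNDS = (50.0, 120.0)
_HILL_BOUNDS = (0.05, 20.0)


@dataclass(frozen=True)
class DosePoint:
    """One concentration–effect observation: dose (native unit) and fa."""

    dose: float
    fa: float

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")
        if not 0.0 <= self.fa <= 1.0:
            raise DomainError(f"fa must lie in [0, 1], got {self.fa}")

    @classmethod
    def from_viability(cls, dose: float, viability_pct: float) -> "DosePoint":
        """Build a point from a viability %, clamping to [0, 100] first."""
        v = min(max(viability_pct, 0.0), 100.0)
        return cls(dose=dose, fa=1.0 - v / 100.0)


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic curve for one drug."""

    bottom: float
    top: float
    hill_slope: float
    ic50: float
    rss: float
    n_points: int
    unit: str = ""

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill_slope
        )


@dataclass
class MedianEffectFit:
    """Median-effect parameters (Dm, m) of one drug plus fit diagnostics."""

    drug_id: str
    dm: float
    m: float
    r: float
    n_points: int
    unit: str = ""

    def __post_init__(self):
        if self.dm <= 0:
            raise DomainError(f"{self.drug_id}: Dm must be positive, got {self.dm}")
        if self.m <= 0:
            raise DomainError(f"{self.drug_id}: m must be positive, got {self.m}")


def _four_pl(dose, bottom, top, hill, ic50):
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_four_pl(points, unit: str = "") -> FourPLFit:
    """Least-squares 4PL fit of (dose, viability %) pairs.

    Runs a deterministic multi-start — log-spaced IC50 seeds spanning the dose
    range crossed with slope seeds {0.5, 1, 2, 4} — and keeps the best
    residual sum of squares, so repeated fits of the same data are identical.

    Parameters
    ----------
    points : sequence of (dose, viability_pct)
        At least four distinct positive doses are required.

    Raises
    ------
    InsufficientDataError
        Fewer than four distinct positive doses.
    NonConvergenceError
        No decreasing dose–viability trend (e.g. flat 100% viability); the
        exception's ``details`` carry the trend diagnostics.
    """
    pts = [(float(d), float(v)) for d, v in points]
    doses = np.array([d for d, _ in pts])
    viab = np.array([v for _, v in pts])
    pos = doses > 0
    distinct = np.unique(doses[pos])
    if distinct.size < 4:
        raise InsufficientDataError(
            f"4PL fit needs >= 4 distinct positive doses, got {distinct.size}"
        )
    doses, viab = doses[pos], viab[pos]

    # require a decreasing trend on the log-dose axis before fitting
    logd = np.log(doses)
    if np.ptp(viab) == 0:
        raise NonConvergenceError(
            "no dose–response trend: viability is constant",
            details={"viability": float(viab[0])},
        )
    slope = float(np.polyfit(logd, viab, 1)[0])
    if slope >= 0:
        raise NonConvergenceError(
            "no decreasing dose–viability trend",
            details={"ols_slope_per_log_dose": slope},
        )

    lo = np.array([_BOTTOM_BOUNDS[0], _TOP_BOUNDS[0], _HILL_BOUNDS[0], distinct.min() / 1e3])
    hi = np.array([_BOTTOM_BOUNDS[1], _TOP_BOUNDS[1], _HILL_BOUNDS[1], distinct.max() * 1e3])

    def residuals(theta):
        return _four_pl(doses, *theta) - viab

    b0 = float(np.clip(viab.min(), *_BOTTOM_BOUNDS))
    t0 = float(np.clip(viab.max(), *_TOP_BOUNDS))
    best = None
    for ic50_seed in np.geomspace(distinct.min(), distinct.max(), _N_IC50_SEEDS):
        for h0 in _SLOPE_SEEDS:
            x0 = np.clip([b0, t0, h0, ic50_seed], lo, hi)
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol.x)
    rss, (bottom, top, hill, ic50) = best
    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        hill_slope=float(hill),
        ic50=float(ic50),
        rss=rss,
        n_points=int(doses.size),
        unit=unit,
    )


def usable_points(points) -> list[DosePoint]:
    """Filter points to those fit-eligible: dose > 0 and fa in (ε, 1−ε)."""
    out = []
    for p in points:
        if not isinstance(p, DosePoint):
            p = DosePoint(dose=float(p[0]), fa=float(p[1]))
        if p.dose > 0 and FA_EPS < p.fa < 1.0 - FA_EPS:
            out.append(p)
    return out


def fit_median_effect(points, drug_id: str = "", unit: str = "") -> MedianEffectFit:
    """Closed-form OLS fit of the median-effect plot.

    Regresses ``log10(fa/(1−fa))`` on ``log10(dose)``: the slope is ``m`` and
    the intercept ``−m·log10(Dm)``. Points with fa at (or within 1e-6 of) the
    boundaries are excluded first.

    Raises
    ------
    InsufficientDataError
        Fewer than two usable points, or no dose spread among them.
    """
    pts = usable_points(points)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"median-effect fit needs >= 2 points with fa in "
            f"({FA_EPS}, {1 - FA_EPS}), got {len(pts)}"
        )
    x = np.log10([p.dose for p in pts])
    y = np.log10([p.fa / (1.0 - p.fa) for p in pts])
    if np.ptp(x) == 0:
        raise InsufficientDataError("median-effect fit needs >= 2 distinct doses")
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise NonConvergenceError(
            "median-effect slope m is not positive: effect does not grow with dose",
            details={"m": float(m)},
        )
    dm = 10.0 ** (-intercept / m)
    if np.ptp(y) == 0:
        r = 0.0  # horizontal plot: correlation undefined, report 0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return MedianEffectFit(
        drug_id=drug_id, dm=float(dm), m=float(m), r=r, n_points=len(pts), unit=unit
    )


def fa_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Forward median-effect equation: fa = 1 / (1 + (Dm/D)^m)."""
    if dose <= 0:
        raise DomainError(f"dose must be positive, got {dose}")
    return 1.0 / (1.0 + (fit.dm / dose) ** fit.m)


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Inverse median-effect equation: Dx = Dm · (fa/(1−fa))^(1/m).

    ``Dx`` is the single-drug dose producing effect ``fa`` alone, in the
    fit's native unit.
    """
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
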