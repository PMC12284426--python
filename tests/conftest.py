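import numpy as np
import pytest

from combiscreen import (
    Dose,
    MedianEffectFit,
    WellRecord,
    default_screen_config,
    simulate_screen,
)


@pytest.fixture
def me_fit():
    """A reference median-effect fit: Dm=2, m=1.5 in µg/mL."""
    return MedianEffectFit(drug_id="drug", dm=2.0, m=1.5, r=1.0, n_points=5, unit="ug/mL")


def exact_me_points(dm, m, doses):
    """Noiseless (dose, fa) pairs on the median-effect curve fa/fu=(D/Dm)^m."""
    doses = np.asarray(doses, dtype=float)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    return list(zip(doses, fa))


def make_plate(
    plate_id="P1",
    alpha=10000.0,
    beta=200.0,
    treated=(),
    n_controls=3,
):
    """Hand-built noiseless plate: anchors plus (doses, viability%) conditions."""
    wells = []
    for rep in range(1, n_controls + 1):
        wells.append(WellRecord(plate_id, f"C{rep}", "control", [], alpha, rep))
        wells.append(WellRecord(plate_id, f"B{rep}", "background", [], beta, rep))
    for i, (doses, viability) in enumerate(treated):
        signal = beta + (alpha - beta) * viability / 100.0
        for rep in range(1, n_controls + 1):
            wells.append(
                WellRecord(
                    plate_id,
                    f"T{i}:{rep}",
                    "treated",
                    [Dose(*d) for d in doses],
                    signal,
                    rep,
                )
            )
    return wells


@pytest.fixture
def simulated_plate():
    """Default-condition simulated screen plate (seed 11)."""
    return simulate_screen(default_screen_config(seed=11))
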