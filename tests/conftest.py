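"""Shared fixtures and independent reference solvers.

The equilibrium oracles here deliberately avoid the package's closed-form /
1-D-reduction code paths so that agreement tests compare two independent
routes to the same physics.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq, fsolve

from fretscreen.plate_io import Channel, Plate, WellRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_bound(d: float, a: float, kd: float) -> float:
    """Two-species equilibrium by root finding on free donor (no quadratic)."""
    if d == 0 or a == 0:
        return 0.0
    if kd == 0:
        return min(d, a)

    def f(df):
        return df * (1.0 + a / (kd + df)) - d

    df = brentq(f, 0.0, d, xtol=1e-300, rtol=8.9e-16, maxiter=500)
    # complex from free donor via mass action (avoids d - df cancellation)
    return df * a / (kd + df)


def brute_force_competition(d, a, i, kd, ki):
    """Ternary equilibrium solved as a 3-unknown nonlinear system (fsolve)."""

    def eqs(x):
        df, af, inf = np.abs(x)
        da = df * af / kd
        di = df * inf / ki
        return [df + da + di - d, af + da - a, inf + di - i]

    x0 = np.array([d * 0.5, a * 0.5, max(i, 1e-12) * 0.5])
    sol = np.abs(fsolve(eqs, x0, xtol=1e-13))
    df, af, inf = sol
    return {"donor_free": df, "complex_da": df * af / kd, "complex_di": df * inf / ki}


@pytest.fixture
def toy_plate() -> Plate:
    """Minimal 96-well plate with one well of each role."""
    plate = Plate(plate_id="toy", format=96)
    reads_sample = {Channel(410, 477): 100.0, Channel(410, 527): 150.0}
    reads_neg = {Channel(410, 477): 110.0, Channel(410, 527): 160.0}
    reads_pos = {Channel(410, 477): 120.0, Channel(410, 527): 60.0}
    reads_blank = {Channel(410, 477): 10.0, Channel(410, 527): 12.0}
    plate.add_well(
        WellRecord("A1", "sample", compound_id="CMP1", compound_conc=1e-5,
                   donor_conc=1e-7, acceptor_conc=2e-7, reads=reads_sample)
    )
    plate.add_well(
        WellRecord("A2", "negative_control", donor_conc=1e-7, acceptor_conc=2e-7,
                   reads=reads_neg)
    )
    plate.add_well(
        WellRecord("A3", "positive_control", donor_conc=1e-7, acceptor_conc=2e-7,
                   reads=reads_pos)
    )
    plate.add_well(WellRecord("A4", "blank", reads=reads_blank))
    return plate
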