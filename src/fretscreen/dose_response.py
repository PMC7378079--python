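"""Dose-response analysis and IC50 -> Ki conversion.

IC50 values come from variable-slope sigmoidal (four-parameter logistic)
fits.  Because the probe concentrations used here (50 nM donor, 100 nM
acceptor) are comparable to the probe Kd (35 nM), ligand depletion matters
and the Cheng-Prusoff formula is biased; the primary conversion therefore
inverts the exact ternary mass-action equilibrium

    D + A <-> DA  (Kd_probe),   D + I <-> DI  (Ki)

for the Ki at which the donor-acceptor complex is halved at an inhibitor
total equal to the IC50.  The Cheng-Prusoff approximation
Ki = IC50 / (1 + [A]/Kd) is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Model
from scipy import optimize

from .errors import EquilibriumError, FitError, ValidationError
from .fret_model import bound_complex


@dataclass
class DoseResponseSeries:
    """Concentration ladder with responses (rFRET or percent inhibition).

    Optional anchor controls are the 0%- and 100%-effect reference wells the
    assay places two log-units below/above the tested range; they enter the
    fit as ordinary points at those pseudo-concentrations.
    """

    compound_id: str
    concentrations: np.ndarray  # molar, sorted ascending
    responses: np.ndarray
    anchor_low_response: Optional[float] = None  # at conc_min / 100
    anchor_high_response: Optional[float] = None  # at conc_max * 100

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValidationError("concentration and response vectors differ in length")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValidationError("concentrations must be sorted ascending")


@dataclass
class DoseResponseFit:
    ic50: float  # molar
    hill_slope: float
    top: float  # maximum-response asymptote
    bottom: float  # minimum-response asymptote
    ci_95: dict[str, tuple[float, float]]
    converged: bool
    ascending: bool  # True when response grows with concentration
    rss: float


@dataclass(frozen=True)
class CompetitionSystem:
    donor_total: float  # molar
    acceptor_total: float  # molar
    kd_probe: float  # molar
    ki: float  # molar

    def __post_init__(self) -> None:
        if min(self.donor_total, self.acceptor_total, self.kd_probe, self.ki) <= 0:
            raise ValidationError("all competition-system parameters must be > 0")


@dataclass(frozen=True)
class EquilibriumState:
    donor_free: float
    acceptor_free: float
    inhibitor_free: float
    complex_da: float
    complex_di: float


def _logistic4(x, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_ic50(series: DoseResponseSeries) -> DoseResponseFit:
    """Variable-slope sigmoidal fit, y = bottom + (top-bottom)/(1+(x/ic50)^h).

    Orientation (ascending percent-inhibition curve vs descending raw-signal
    curve) is auto-detected from the sign of the span and absorbed into the
    sign of the Hill slope; the reported fit always has ``top > bottom`` and
    the ``ascending`` flag records which end of the ladder sits at the top.
    """
    x = series.concentrations
    y = series.responses
    if series.anchor_low_response is not None:
        x = np.concatenate([[series.concentrations[0] / 100.0], x])
        y = np.concatenate([[series.anchor_low_response], y])
    if series.anchor_high_response is not None:
        x = np.concatenate([x, [series.concentrations[-1] * 100.0]])
        y = np.concatenate([y, [series.anchor_high_response]])
    order = np.argsort(x)
    x, y = x[order], y[order]

    if len(np.unique(series.concentrations)) < 5:
        raise ValidationError("need >= 5 concentrations for a dose-response fit")
    span_decades = np.log10(series.concentrations[-1] / series.concentrations[0])
    if span_decades < 2:
        raise ValidationError("concentrations must span >= 2 log units")

    lo = float(np.mean(y[x <= x[0]]))
    hi = float(np.mean(y[x >= x[-1]]))
    ascending = hi >= lo
    span = abs(hi - lo)
    scale = max(abs(hi), abs(lo), 1e-12)
    if span < 1e-9 * scale or np.ptp(y) == 0:
        return DoseResponseFit(
            ic50=float("nan"), hill_slope=float("nan"),
            top=max(hi, lo), bottom=min(hi, lo),
            ci_95={}, converged=False, ascending=ascending, rss=float("nan"),
        )

    # midpoint crossing as the IC50 initial guess
    mid = 0.5 * (hi + lo)
    crossings = np.where(np.diff(np.sign(y - mid)) != 0)[0]
    ic50_init = float(np.sqrt(x[crossings[0]] * x[crossings[0] + 1])) if crossings.size else float(
        np.sqrt(x[0] * x[-1])
    )
    hill_init = -1.0 if ascending else 1.0

    model = Model(_logistic4)
    params = model.make_params(
        top=max(lo, hi), bottom=min(lo, hi), ic50=ic50_init, hill=hill_init
    )
    params["ic50"].set(min=x[0] / 1e4, max=x[-1] * 1e4)
    result = model.fit(y, params, x=x)

    top = float(result.params["top"].value)
    bottom = float(result.params["bottom"].value)
    hill = float(result.params["hill"].value)
    ic50 = float(result.params["ic50"].value)
    # normalise so that top > bottom and the slope sign carries orientation
    if top < bottom:
        top, bottom = bottom, top

    ci = {}
    for name in ("top", "bottom", "ic50", "hill"):
        p = result.params[name]
        if p.stderr is not None:
            ci[name] = (p.value - 1.96 * p.stderr, p.value + 1.96 * p.stderr)

    converged = bool(result.success)
    tested_min, tested_max = series.concentrations[0], series.concentrations[-1]
    if not np.isfinite(ic50) or ic50 < tested_min / 100.0 or ic50 > tested_max * 100.0:
        converged = False

    return DoseResponseFit(
        ic50=ic50,
        hill_slope=hill,
        top=top,
        bottom=bottom,
        ci_95=ci,
        converged=converged,
        ascending=ascending,
        rss=float(np.sum(result.residual**2)),
    )


def competition_equilibrium(system: CompetitionSystem, inhibitor_total: float) -> EquilibriumState:
    """Exact three-species mass-action equilibrium by 1-D root finding.

    With free donor Df, the conservation equations reduce to the monotone
    scalar equation Df * (1 + A/(Kd+Df) + I/(Ki+Df)) = D, solved by Brent's
    method on [0, D].  Mass balance of every total is verified to 1e-10
    relative on every call.
    """
    if inhibitor_total < 0:
        raise ValidationError("inhibitor concentration must be >= 0")
    d, a, i = system.donor_total, system.acceptor_total, inhibitor_total
    kd, ki = system.kd_probe, system.ki
    if d == 0:
        return EquilibriumState(0.0, a, i, 0.0, 0.0)

    def f(df: float) -> float:
        return df * (1.0 + a / (kd + df) + i / (ki + df)) - d

    try:
        df = optimize.brentq(f, 0.0, d, xtol=1e-30, rtol=8.9e-16, maxiter=300)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise EquilibriumError(
            f"equilibrium solve failed for D={d:g}, A={a:g}, I={i:g}, "
            f"Kd={kd:g}, Ki={ki:g}: {exc}"
        ) from exc

    da = df * a / (kd + df)
    di = df * i / (ki + df)
    af = a - da
    i_free = i - di

    for total, parts in ((d, df + da + di), (a, af + da), (i, i_free + di)):
        if total > 0 and abs(parts - total) > 1e-10 * total:
            raise EquilibriumError(
                f"mass balance violated: total {total:g} vs {parts:g}"
            )
    return EquilibriumState(
        donor_free=df, acceptor_free=af, inhibitor_free=i_free,
        complex_da=da, complex_di=di,
    )


@dataclass(frozen=True)
class KiResult:
    ki: float  # exact ternary-equilibrium inversion, molar
    ki_cheng_prusoff: float  # dilute-probe approximation, molar
    ic50: float


KI_BRACKET = (1e-12, 1.0)  # molar


def ic50_to_ki(
    ic50: float,
    donor_total: float,
    acceptor_total: float,
    kd_probe: float,
    bracket: tuple[float, float] = KI_BRACKET,
) -> KiResult:
    """Ki for which the equilibrium predicts 50% complex loss at I = IC50."""
    if ic50 <= 0:
        raise ValidationError("ic50 must be > 0")
    da0 = bound_complex(donor_total, acceptor_total, kd_probe)
    target = 0.5 * da0

    def g(log_ki: float) -> float:
        system = CompetitionSystem(donor_total, acceptor_total, kd_probe, 10.0**log_ki)
        return competition_equilibrium(system, ic50).complex_da - target

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    if g(lo) * g(hi) > 0:
        raise FitError(
            f"no Ki in [{bracket[0]:g}, {bracket[1]:g}] M reproduces IC50={ic50:g} M"
        )
    log_ki = optimize.brentq(g, lo, hi, xtol=1e-12)
    ki_cp = ic50 / (1.0 + acceptor_total / kd_probe)
    return KiResult(ki=float(10.0**log_ki), ki_cheng_prusoff=float(ki_cp), ic50=float(ic50))
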