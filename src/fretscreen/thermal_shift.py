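"""Differential scanning fluorimetry (thermal shift) analysis.

SYPRO-orange-type melt curves rise through the unfolding transition and then
decline as aggregates sequester the dye; the decline breaks the Boltzmann
form, so curves are truncated at their global fluorescence maximum and
min-max normalised before fitting

    y(T) = b_low + (b_high - b_low) / (1 + exp((Tm - T)/slope)).

Tm is the inflection point.  Replicates are fitted independently and the
melting-temperature shift against a no-compound control is reported as
mean difference with the replicate SDs propagated in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

from .errors import FitError, NoTransitionError, ValidationError

MIN_POINTS = 15


@dataclass
class MeltCurve:
    temperatures: np.ndarray  # degrees C, monotone increasing
    fluorescence: np.ndarray  # RFU
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValidationError("temperature and fluorescence vectors differ in length")
        if self.temperatures.size < MIN_POINTS:
            raise ValidationError(f"melt curve needs >= {MIN_POINTS} points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm: float  # degrees C
    slope: float  # degrees C, transition width
    baseline_low: float
    baseline_high: float
    rss: float
    converged: bool


def normalize_and_truncate(curve: MeltCurve) -> MeltCurve:
    """Drop points after the global fluorescence maximum, then min-max
    normalise the retained segment to [0, 1].

    A maximum at the very first point means there is no rising transition to
    fit; a flat curve likewise.
    """
    f = curve.fluorescence
    if np.ptp(f) == 0:
        raise NoTransitionError(f"curve {curve.sample_id!r} is constant")
    peak = int(np.argmax(f))
    if peak == 0:
        raise NoTransitionError(
            f"curve {curve.sample_id!r} has its maximum at the first point"
        )
    t = curve.temperatures[: peak + 1]
    seg = f[: peak + 1]
    lo, hi = float(seg.min()), float(seg.max())
    norm = (seg - lo) / (hi - lo)
    return replace(curve, temperatures=t, fluorescence=norm)


def _boltzmann(T, b_low, b_high, tm, slope):
    return b_low + (b_high - b_low) / (1.0 + np.exp((tm - T) / slope))


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Boltzmann sigmoid fit of a normalised, truncated melt curve."""
    t, y = curve.temperatures, curve.fluorescence

    # initial Tm: first crossing of the half-height
    mid = 0.5 * (y.min() + y.max())
    above = np.where(y >= mid)[0]
    tm_init = float(t[above[0]]) if above.size else float(np.median(t))

    model = Model(_boltzmann)
    params = model.make_params(
        b_low=float(y[:3].mean()), b_high=float(y[-3:].mean()), tm=tm_init, slope=2.0
    )
    params["slope"].set(min=1e-3, max=(t[-1] - t[0]))
    params["tm"].set(min=t[0], max=t[-1])
    result = model.fit(y, params, T=t)
    if not result.success:
        raise FitError(f"melt fit failed for {curve.sample_id!r}: {result.message}")
    return MeltFit(
        tm=float(result.params["tm"].value),
        slope=float(result.params["slope"].value),
        baseline_low=float(result.params["b_low"].value),
        baseline_high=float(result.params["b_high"].value),
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
    )


def analyze_curve(curve: MeltCurve) -> MeltFit:
    """Convenience: truncate + normalise + fit one raw melt curve."""
    return fit_melt(normalize_and_truncate(curve))


@dataclass(frozen=True)
class DeltaTm:
    delta_tm: float  # degrees C, mean(sample) - mean(control)
    sd: Optional[float]  # quadrature-propagated replicate SD; None if n=1
    n_sample: int
    n_control: int


def delta_tm(sample_fits: Sequence[MeltFit], control_fits: Sequence[MeltFit]) -> DeltaTm:
    """Tm shift of a compound group against the no-compound control group."""
    if not sample_fits or not control_fits:
        raise ValidationError("both groups need at least one melt fit")
    tm_s = np.array([f.tm for f in sample_fits])
    tm_c = np.array([f.tm for f in control_fits])
    shift = float(tm_s.mean() - tm_c.mean())
    if tm_s.size > 1 and tm_c.size > 1:
        sd = float(np.sqrt(tm_s.std(ddof=1) ** 2 + tm_c.std(ddof=1) ** 2))
    else:
        sd = None
    return DeltaTm(delta_tm=shift, sd=sd, n_sample=int(tm_s.size), n_control=int(tm_c.size))
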