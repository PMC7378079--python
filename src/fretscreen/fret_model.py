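"""Core FRET mathematics.

Ratiometric FRET (rFRET) is the acceptor-emission / donor-emission intensity
ratio under donor excitation (527/477 nm at 410 nm excitation, with 430 nm as
a parallel readout for screening).  Sensitized emission (EmFRET) is obtained
by three-channel linear unmixing,

    EmFRET = I(430,527) - alpha * I(430,477) - beta * I(477,527),

where ``alpha`` (donor bleed-through into the acceptor emission channel) is
calibrated from donor-only wells and ``beta`` (acceptor direct excitation at
the donor excitation wavelength) from acceptor-only wells.

Binding is modelled as 1:1 complex formation with ligand depletion (the
quadratic "tight-binding" isotherm): donor and acceptor concentrations in
these assays (50 nM - 1.1 uM) are comparable to the dissociation constants,
so the dilute approximation would be badly biased.  The Kd fit profiles a
single nonlinear parameter (Kd) with the plateau amplitude solved analytically
at each candidate Kd, and reports a profile-likelihood 95% confidence
interval assuming iid Gaussian errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    CalibrationError,
    FitError,
    UndefinedRatioError,
    ValidationError,
)
from .plate_io import WellRecord

#: default rFRET excitation; 430 nm is the alternative screening readout
RFRET_EXCITATION_NM = 410
DONOR_EMISSION_NM = 477
ACCEPTOR_EMISSION_NM = 527

#: channel set used for EmFRET determination
EMFRET_CHANNELS = ((430, 477), (430, 527), (477, 527))


@dataclass(frozen=True)
class RatiometricFRET:
    """rFRET value together with the two blank-subtracted intensities."""

    rfret: float
    donor_intensity: float
    acceptor_intensity: float
    excitation_nm: float = RFRET_EXCITATION_NM


@dataclass(frozen=True)
class BleedthroughCoefficients:
    """Spectral cross-talk ratios for the three-channel EmFRET correction.

    alpha: donor emission leaking into the acceptor emission channel under
        donor excitation, I(430,527)/I(430,477) of donor-only wells.
    beta: acceptor direct excitation at the donor excitation wavelength,
        I(430,527)/I(477,527) of acceptor-only wells.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("bleed-through coefficients must be >= 0")


@dataclass
class TitrationSeries:
    """Fixed donor, acceptor ladder, per-point EmFRET values (pooled reps)."""

    donor_total: float  # molar
    acceptor_totals: np.ndarray  # molar
    emfret: np.ndarray  # RFU
    replicate_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.acceptor_totals = np.asarray(self.acceptor_totals, dtype=float)
        self.emfret = np.asarray(self.emfret, dtype=float)
        if self.acceptor_totals.shape != self.emfret.shape:
            raise ValidationError("acceptor and EmFRET vectors differ in length")
        if np.any(self.acceptor_totals < 0):
            raise ValidationError("acceptor concentrations must be >= 0")
        if self.donor_total <= 0:
            raise ValidationError("donor concentration must be > 0")


@dataclass
class BindingFit:
    """Result of the quadratic tight-binding Kd fit."""

    kd: float  # molar
    emfret_max: float  # RFU, donor-normalized plateau
    kd_ci_95: tuple[float, float]  # molar, profile likelihood
    residual_sum_squares: float
    n_points: int
    ci_unreliable: bool = False
    ci_lower_open: bool = False
    ci_upper_open: bool = False
    profile_kd: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    profile_rss: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def compute_rfret(well: WellRecord, excitation_nm: float = RFRET_EXCITATION_NM) -> RatiometricFRET:
    """Acceptor/donor emission ratio of a blank-subtracted well."""
    donor = well.intensity(excitation_nm, DONOR_EMISSION_NM)
    acceptor = well.intensity(excitation_nm, ACCEPTOR_EMISSION_NM)
    if donor <= 0:
        raise UndefinedRatioError(
            f"well {well.well_id}: donor-channel intensity {donor:g} <= 0"
        )
    return RatiometricFRET(
        rfret=acceptor / donor,
        donor_intensity=donor,
        acceptor_intensity=acceptor,
        excitation_nm=excitation_nm,
    )


def calibrate_bleedthrough(
    donor_only: Sequence[WellRecord], acceptor_only: Sequence[WellRecord]
) -> BleedthroughCoefficients:
    """Estimate cross-talk ratios from single-fluorophore calibration wells."""
    if not donor_only or not acceptor_only:
        raise CalibrationError("need at least one donor-only and one acceptor-only well")
    alphas = []
    for w in donor_only:
        denom = w.intensity(430, 477)
        if denom <= 0:
            raise CalibrationError(f"donor-only well {w.well_id}: I(430,477) <= 0")
        alphas.append(w.intensity(430, 527) / denom)
    betas = []
    for w in acceptor_only:
        denom = w.intensity(477, 527)
        if denom <= 0:
            raise CalibrationError(f"acceptor-only well {w.well_id}: I(477,527) <= 0")
        betas.append(w.intensity(430, 527) / denom)
    return BleedthroughCoefficients(
        alpha=float(np.mean(alphas)), beta=float(np.mean(betas))
    )


def compute_emfret(well: WellRecord, coeffs: BleedthroughCoefficients) -> float:
    """Sensitized acceptor emission after linear unmixing (may be <= 0)."""
    return (
        well.intensity(430, 527)
        - coeffs.alpha * well.intensity(430, 477)
        - coeffs.beta * well.intensity(477, 527)
    )


def bound_complex(donor_total, acceptor_total, kd):
    """Equilibrium donor-acceptor complex concentration, 1:1 with depletion.

    Solves DA^2 - (D + A + Kd) DA + D*A = 0 for the physical root, written in
    the numerically stable form 2*D*A / (S + sqrt(S^2 - 4*D*A)) with
    S = D + A + Kd, which avoids cancellation when D*A << S^2.  Accepts
    scalars or numpy arrays (broadcast).
    """
    d = np.asarray(donor_total, dtype=float)
    a = np.asarray(acceptor_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(d < 0) or np.any(a < 0) or np.any(k < 0):
        raise ValidationError("concentrations and Kd must be >= 0")
    s = d + a + k
    disc = s * s - 4.0 * d * a
    root = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(s + root > 0, 2.0 * d * a / (s + root), 0.0)
    if da.ndim == 0:
        return float(da)
    return da


def series_from_plate(plate, donor_total: Optional[float] = None) -> TitrationSeries:
    """Build a pooled-replicate titration series from a blank-subtracted plate.

    Calibration wells are recognised from the plate map: donor-only wells have
    ``acceptor_conc == 0``, acceptor-only wells ``donor_conc == 0``.  All
    remaining sample wells enter the series (replicates pooled, not averaged,
    to preserve the error structure for the confidence interval).
    """
    samples = plate.wells_by_role("sample")
    donor_only = [w for w in samples if w.acceptor_conc == 0 and w.donor_conc > 0]
    acceptor_only = [w for w in samples if w.donor_conc == 0 and w.acceptor_conc > 0]
    titration = [w for w in samples if w.donor_conc > 0 and w.acceptor_conc > 0]
    # the A=0 ladder anchor lives in donor_only wells flagged by compound_id
    ladder_zero = [w for w in donor_only if w.compound_id == "titration_point"]
    donor_only = [w for w in donor_only if w.compound_id != "titration_point"]
    if not titration and not ladder_zero:
        raise ValidationError("plate has no titration wells")
    coeffs = calibrate_bleedthrough(donor_only, acceptor_only)
    wells = sorted(ladder_zero + titration, key=lambda w: (w.acceptor_conc, w.well_id))
    acceptors = np.array([w.acceptor_conc for w in wells])
    emf = np.array([compute_emfret(w, coeffs) for w in wells])
    if donor_total is None:
        donors = {w.donor_conc for w in wells}
        if len(donors) != 1:
            raise ValidationError("titration wells carry inconsistent donor totals")
        donor_total = donors.pop()
    return TitrationSeries(donor_total=donor_total, acceptor_totals=acceptors, emfret=emf)


def _rss_profile(series: TitrationSeries, kd_values: np.ndarray):
    """Vectorized residual sum of squares with the plateau solved analytically.

    EmFRET(A) = emfret_max * DA(D, A, kd) / D is linear in emfret_max, so for
    each candidate kd the optimal plateau is sum(y*f)/sum(f*f).
    """
    d = series.donor_total
    a = series.acceptor_totals[None, :]
    y = series.emfret[None, :]
    kd = np.asarray(kd_values, dtype=float)[:, None]
    f = bound_complex(d, a, kd) / d
    ff = np.sum(f * f, axis=1)
    yf = np.sum(y * f, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        emax = np.where(ff > 0, yf / ff, 0.0)
    resid = y - emax[:, None] * f
    rss = np.sum(resid * resid, axis=1)
    return rss, emax


KD_SEARCH_BOUNDS = (1e-12, 1e-2)  # molar


def fit_kd(series: TitrationSeries, kd_bounds: tuple[float, float] = KD_SEARCH_BOUNDS) -> BindingFit:
    """Least-squares Kd and plateau from a titration, with profile-likelihood CI.

    Requires at least six distinct acceptor concentrations.  A monotonically
    decreasing EmFRET trend triggers a warning and the CI is flagged
    unreliable; an all-zero EmFRET vector is a fit error.
    """
    if len(np.unique(series.acceptor_totals)) < 6:
        raise ValidationError("need >= 6 distinct acceptor concentrations")
    y = series.emfret
    if np.allclose(y, 0.0):
        raise FitError("EmFRET vector is identically zero; Kd unidentifiable")

    unreliable = False
    pos = series.acceptor_totals > 0
    if np.sum(pos) >= 2:
        slope = np.polyfit(series.acceptor_totals[pos], y[pos], 1)[0]
        if slope < 0 and np.corrcoef(series.acceptor_totals[pos], y[pos])[0, 1] < -0.5:
            warnings.warn(
                "EmFRET decreases with acceptor concentration; fit unreliable",
                stacklevel=2,
            )
            unreliable = True

    lo, hi = np.log10(kd_bounds[0]), np.log10(kd_bounds[1])
    coarse = np.logspace(lo, hi, 161)
    rss_coarse, _ = _rss_profile(series, coarse)
    i = int(np.argmin(rss_coarse))
    blo = np.log10(coarse[max(i - 1, 0)])
    bhi = np.log10(coarse[min(i + 1, len(coarse) - 1)])

    def objective(logkd: float) -> float:
        return float(_rss_profile(series, np.array([10.0**logkd]))[0][0])

    res = optimize.minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-10}
    )
    if not res.success:
        raise FitError(f"Kd optimisation failed: {res.message}")
    kd_hat = float(10.0**res.x)
    rss_min, emax = _rss_profile(series, np.array([kd_hat]))
    rss_min = float(rss_min[0])
    emax = float(emax[0])
    if emax <= 0:
        unreliable = True

    fit = BindingFit(
        kd=kd_hat,
        emfret_max=emax,
        kd_ci_95=(kd_hat, kd_hat),
        residual_sum_squares=rss_min,
        n_points=len(y),
        ci_unreliable=unreliable,
    )
    ci = profile_likelihood_ci(series, fit)
    fit.kd_ci_95 = (ci.lower, ci.upper)
    fit.ci_lower_open = ci.lower_open
    fit.ci_upper_open = ci.upper_open
    fit.ci_unreliable = unreliable or ci.lower_open or ci.upper_open
    return fit


@dataclass(frozen=True)
class ProfileCI:
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False


def profile_likelihood_ci(
    series: TitrationSeries,
    fit: BindingFit,
    level: float = 0.95,
    grid_size: int = 201,
    span: float = 100.0,
    rel_tol: float = 1e-3,
) -> ProfileCI:
    """Profile-likelihood confidence interval for Kd.

    Kd is profiled over a log-spaced grid spanning ``span``-fold either side
    of the point estimate; at each grid value the plateau is re-optimised
    analytically.  With iid Gaussian errors and the variance at its maximum
    likelihood value RSS_min/n, the log-likelihood drop of chi2_1(level)/2
    (1.92 for 95%) translates to the RSS threshold

        RSS* = RSS_min * (1 + chi2_1(level) / n).

    Bounds are located by bisection between bracketing grid points; a bound
    that is not bracketed within the grid is returned open (flagged).
    """
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    kd_hat = fit.kd
    rss_min = fit.residual_sum_squares
    n = fit.n_points
    if rss_min <= 0:
        # zero-residual limit: the interval collapses onto the point estimate
        return ProfileCI(lower=kd_hat, upper=kd_hat)

    chi = stats.chi2.ppf(level, df=1)
    threshold = rss_min * (1.0 + chi / n)

    grid = np.logspace(np.log10(kd_hat / span), np.log10(kd_hat * span), grid_size)
    rss, _ = _rss_profile(series, grid)

    def crossing(lo_kd: float, hi_kd: float) -> float:
        # bisect on log kd for RSS(kd) == threshold
        f = lambda logk: float(_rss_profile(series, np.array([10.0**logk]))[0][0]) - threshold
        a, b = np.log10(lo_kd), np.log10(hi_kd)
        fa = f(a)
        for _ in range(200):
            m = 0.5 * (a + b)
            fm = f(m)
            if (fa < 0) == (fm < 0):
                a, fa = m, fm
            else:
                b = m
            if 10.0**b / 10.0**a - 1.0 < rel_tol:
                break
        return float(10.0 ** (0.5 * (a + b)))

    below = rss <= threshold
    i_hat = int(np.argmin(np.abs(np.log(grid / kd_hat))))
    below[i_hat] = True  # the optimum is inside by construction

    # lower bound: last grid point above the threshold left of the optimum
    lower_open = False
    left = np.where(~below[: i_hat + 1])[0]
    if left.size:
        j = left[-1]
        lower = crossing(grid[j], grid[j + 1])
    else:
        lower = float(grid[0])
        lower_open = True

    upper_open = False
    right = np.where(~below[i_hat:])[0]
    if right.size:
        j = right[0] + i_hat
        upper = crossing(grid[j - 1], grid[j])
    else:
        upper = float(grid[-1])
        upper_open = True

    return ProfileCI(lower=lower, upper=upper, lower_open=lower_open, upper_open=upper_open)
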