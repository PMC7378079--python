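"""Synthetic plate-data generator with seeded ground truth.

Every pipeline input — spectrally realistic FRET plates, Kd titrations,
two-assay screening libraries, dose-response series and melt curves — can be
generated here as a pure function of (config, seed).

Signal model (per well and channel, before noise):

    I = blank
        + q * [ (D - E*DA) * exD(lx) * emD(lm) * bD        donor, FRET-depleted
              +  A         * exA(lx) * emA(lm) * bA        direct excitation
              +  E*DA      * exD(lx) * emA(lm) * bA ]      sensitized emission
        + compound fluorescence(lx, lm)

with DA the equilibrium donor-acceptor complex (competitive displacement when
an inhibitor is present), E the apparent transfer efficiency, b* molecular
brightness (RFU/nM) and q a compound quench factor per emission channel.
Default fluorophore parameters are hand-set so a saturated bound pair shows
an rFRET roughly 2-3x its unbound control, the qualitative behaviour of
CFP/YFP fusion pairs; they are a plausible template, not fitted spectra.

Noise model: plate-reader well-to-well variability is dominated by dispensed
volume, which scales every protein-derived read of a well identically — so
the 2% CV multiplicative term is applied per well to the signal above
background (it cancels in ratiometric signals).  The plate background itself
is a property of the well, not the dispensed volume, and does not carry that
factor.  A smaller 0.5% CV per-read detection term and an additive floor of
0.5% of the negative control's donor-channel intensity do not cancel in
ratios and set the noise floor at low signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dose_response import CompetitionSystem, competition_equilibrium
from .errors import ConfigurationError, ValidationError
from .fret_model import TitrationSeries, bound_complex
from .plate_io import PLATE_DIMS, Channel, Plate, WellRecord, row_label
from .thermal_shift import MeltCurve


@dataclass(frozen=True)
class FluorophoreModel:
    """Relative excitation/emission responses at the assay wavelengths."""

    excitation_response: dict[int, float]
    emission_response: dict[int, float]
    brightness: float  # RFU per nM

    def __post_init__(self) -> None:
        for v in list(self.excitation_response.values()) + list(
            self.emission_response.values()
        ):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("spectral responses must lie in [0, 1]")

    def ex(self, wavelength: int) -> float:
        return self.excitation_response.get(wavelength, 0.0)

    def em(self, wavelength: int) -> float:
        return self.emission_response.get(wavelength, 0.0)


#: CFP-like donor: strong 410/430 nm excitation, emission peak at 477 nm with
#: a 0.25 bleed-through shoulder at 527 nm.
DONOR_CFP = FluorophoreModel(
    excitation_response={410: 1.0, 430: 0.8, 477: 0.0},
    emission_response={477: 1.0, 527: 0.25},
    brightness=1000.0,
)

#: YFP-like acceptor: weak direct excitation at 410/430 nm (0.05 / 0.08 of
#: its 477 nm response), emission at 527 nm only.
ACCEPTOR_YFP = FluorophoreModel(
    excitation_response={410: 0.05, 430: 0.08, 477: 1.0},
    emission_response={477: 0.0, 527: 1.0},
    brightness=1000.0,
)

RFRET_CHANNELS = (Channel(410, 477), Channel(410, 527))
RFRET_CHANNELS_430 = (Channel(430, 477), Channel(430, 527))
EMFRET_CHANNELS = (Channel(430, 477), Channel(430, 527), Channel(477, 527))

#: acceptor ladder used for Kd determination (molar): 0-1.6 uM in 100 nM
#: steps, then 2.0-4.0 uM in 400 nM steps (23 points)
DEFAULT_ACCEPTOR_LADDER_M = tuple(
    round(c, 12)
    for c in [i * 100e-9 for i in range(17)] + [2000e-9, 2400e-9, 2800e-9, 3200e-9, 3600e-9, 4000e-9]
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one FRET pair."""

    kd_pair: float = 35e-9  # molar
    donor_total: float = 100e-9  # molar
    acceptor_total: float = 200e-9  # molar
    transfer_efficiency: float = 0.35
    noise_cv: float = 0.02  # per-well multiplicative CV (dispensing)
    read_noise_cv: float = 0.005  # per-read multiplicative CV (detection)
    additive_noise_sd: Optional[float] = None  # RFU; None -> 0.5% of donor ref
    blank_rfu: float = 12000.0
    donor: FluorophoreModel = DONOR_CFP
    acceptor: FluorophoreModel = ACCEPTOR_YFP
    seed: int = 0
    plate_format: int = 1536
    assay_key: str = "A"
    assay_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_efficiency <= 1.0:
            raise ValidationError("transfer efficiency must lie in [0, 1]")
        for frac in (self.noise_cv, self.read_noise_cv):
            if frac < 0:
                raise ValidationError("noise CVs must be >= 0")
        if self.plate_format not in PLATE_DIMS:
            raise ValidationError(f"unknown plate format: {self.plate_format}")
        if min(self.kd_pair, self.donor_total, self.acceptor_total) < 0:
            raise ValidationError("concentrations and Kd must be >= 0")

    @property
    def additive_sd(self) -> float:
        """Additive read noise: 0.5% of the negative control's donor-channel
        intensity (the FRET-depleted donor signal at this configuration)."""
        if self.additive_noise_sd is not None:
            return self.additive_noise_sd
        da = bound_complex(self.donor_total, self.acceptor_total, self.kd_pair)
        donor_ref = (
            (self.donor_total - self.transfer_efficiency * da) * 1e9
            * self.donor.ex(410) * self.donor.em(477) * self.donor.brightness
        )
        return 0.005 * donor_ref

    def without_noise(self) -> "SimConfig":
        return replace(self, noise_cv=0.0, read_noise_cv=0.0, additive_noise_sd=0.0)


#: the two validatory-screen assay conditions.  Transfer efficiencies are
#: hand-set so each bound pair shows roughly twice its unbound control's
#: rFRET (the qualitative spectra behaviour) and the 680+680-control
#: Z'-factors land in the observed high-0.8 band.
ASSAY_A_CONFIG = SimConfig(
    kd_pair=35e-9, donor_total=100e-9, acceptor_total=200e-9,
    transfer_efficiency=0.35, assay_key="A", assay_label="ARC4-TBM",
)
ASSAY_B_CONFIG = SimConfig(
    kd_pair=230e-9, donor_total=150e-9, acceptor_total=300e-9,
    transfer_efficiency=0.45, assay_key="B", assay_label="SAM",
)

COMPOUND_CLASSES = (
    "inactive",
    "true_inhibitor_A",
    "true_inhibitor_B",
    "blue_fluor",
    "green_fluor",
    "excitation_shifted_fluor",
    "dual_quencher",
)


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth compound description for the screen simulator.

    ``fluorescence`` maps (excitation, emission) to the RFU the compound adds
    at ``reference_conc``; ``quench`` maps an emission wavelength to the
    factor applied to the protein signal at ``reference_conc`` (both scale
    linearly with the tested concentration).  ``ki`` maps an assay key to the
    inhibitor dissociation constant against that assay's donor.
    """

    compound_id: str
    compound_class: str
    variant: str = ""
    ki: dict[str, float] = field(default_factory=dict)
    fluorescence: dict[tuple[int, int], float] = field(default_factory=dict)
    quench: dict[int, float] = field(default_factory=dict)
    reference_conc: float = 100e-6  # molar
    expected_stage: dict[str, Optional[str]] = field(default_factory=dict)
    expected_hit: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(f"unknown compound class: {self.compound_class}")


def _class_spec(cid: str, cls: str, variant: str = "") -> CompoundSpec:
    """Parameterise one compound; expected filter outcomes follow the class."""
    none_stage = {"A": None, "B": None}
    no_hit = {"A": False, "B": False}
    if cls == "inactive":
        return CompoundSpec(cid, cls, expected_stage=none_stage, expected_hit=no_hit)
    if cls == "true_inhibitor_A":
        return CompoundSpec(
            cid, cls, ki={"A": 15e-6},
            expected_stage=none_stage, expected_hit={"A": True, "B": False},
        )
    if cls == "true_inhibitor_B":
        return CompoundSpec(
            cid, cls, ki={"B": 40e-6},
            expected_stage=none_stage, expected_hit={"A": False, "B": True},
        )
    fluor_stage = {"A": "fluorescence", "B": "fluorescence"}
    if cls == "blue_fluor":
        f = 150000.0 if variant == "strong" else 42000.0
        return CompoundSpec(
            cid, cls, variant=variant,
            fluorescence={(410, 477): f, (430, 477): f},
            expected_stage=fluor_stage, expected_hit=no_hit,
        )
    if cls == "green_fluor":
        f = 150000.0 if variant == "strong" else 30000.0
        return CompoundSpec(
            cid, cls, variant=variant,
            fluorescence={(410, 527): f, (430, 527): f},
            expected_stage=fluor_stage, expected_hit=no_hit,
        )
    if cls == "excitation_shifted_fluor":
        return CompoundSpec(
            cid, cls,
            fluorescence={(410, 477): 9000.0, (430, 477): 30000.0},
            expected_stage={"A": "dual_excitation", "B": "dual_excitation"},
            expected_hit=no_hit,
        )
    if cls == "dual_quencher":
        if variant == "gray":
            # ratio-preserving: rFRET untouched, caught by the +/-30% rule
            return CompoundSpec(
                cid, cls, variant=variant, quench={477: 0.5, 527: 0.5},
                expected_stage=fluor_stage, expected_hit=no_hit,
            )
        # chromatic: 527 nm quenched more than 477 nm, both within 30%, so it
        # mimics inhibition in both assays -> pan-assay exclusion
        return CompoundSpec(
            cid, cls, variant="chromatic", quench={477: 1.0, 527: 0.78},
            expected_stage={"A": "pan_assay", "B": "pan_assay"}, expected_hit=no_hit,
        )
    raise ValidationError(f"unknown compound class: {cls}")


#: default validatory-library composition (1,120 compounds)
DEFAULT_LIBRARY_COMPOSITION = (
    ("inactive", "", 1072),
    ("true_inhibitor_A", "", 10),
    ("true_inhibitor_B", "", 8),
    ("blue_fluor", "strong", 4),
    ("blue_fluor", "moderate", 4),
    ("green_fluor", "strong", 3),
    ("green_fluor", "moderate", 3),
    ("excitation_shifted_fluor", "", 6),
    ("dual_quencher", "gray", 5),
    ("dual_quencher", "chromatic", 5),
)


def make_library(
    composition=DEFAULT_LIBRARY_COMPOSITION, seed: int = 0, library_size: Optional[int] = None
) -> list[CompoundSpec]:
    """Seeded compound library; compound ids are assigned after shuffling."""
    total = sum(n for _, _, n in composition)
    if library_size is not None and total != library_size:
        raise ConfigurationError(
            f"library composition sums to {total}, expected {library_size}"
        )
    entries = [
        (cls, variant) for cls, variant, n in composition for _ in range(n)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return [
        _class_spec(f"C{i + 1:04d}", *entries[j]) for i, j in enumerate(order)
    ]


def _complex_concentration(
    config: SimConfig, compound: Optional[CompoundSpec], compound_conc: float
) -> float:
    """Equilibrium DA (molar); competitive displacement when applicable."""
    ki = compound.ki.get(config.assay_key) if compound else None
    if ki is not None and compound_conc > 0:
        system = CompetitionSystem(
            config.donor_total, config.acceptor_total, config.kd_pair, ki
        )
        return competition_equilibrium(system, compound_conc).complex_da
    return bound_complex(config.donor_total, config.acceptor_total, config.kd_pair)


def noiseless_intensity(
    config: SimConfig,
    channel: Channel,
    compound: Optional[CompoundSpec] = None,
    compound_conc: float = 0.0,
    binding_enabled: bool = True,
    donor_total: Optional[float] = None,
    acceptor_total: Optional[float] = None,
) -> float:
    """Expected intensity of one well in one channel (no noise)."""
    d = config.donor_total if donor_total is None else donor_total
    a = config.acceptor_total if acceptor_total is None else acceptor_total
    cfg = replace(config, donor_total=d, acceptor_total=a)
    lx = int(channel.excitation_nm)
    lm = int(channel.emission_nm)
    e = config.transfer_efficiency

    if binding_enabled and d > 0 and a > 0:
        da = _complex_concentration(cfg, compound, compound_conc)
    else:
        da = 0.0

    d_nm, a_nm, da_nm = d * 1e9, a * 1e9, da * 1e9
    donor, acceptor = config.donor, config.acceptor
    protein = (
        (d_nm - e * da_nm) * donor.ex(lx) * donor.em(lm) * donor.brightness
        + a_nm * acceptor.ex(lx) * acceptor.em(lm) * acceptor.brightness
        + e * da_nm * donor.ex(lx) * acceptor.em(lm) * acceptor.brightness
    )

    quench = 1.0
    fluor = 0.0
    if compound is not None and compound_conc > 0:
        scale = compound_conc / compound.reference_conc
        q_ref = compound.quench.get(lm, 1.0)
        quench = 1.0 - (1.0 - q_ref) * scale
        fluor = compound.fluorescence.get((lx, lm), 0.0) * scale

    return config.blank_rfu + quench * protein + fluor


def _noisy_reads(
    rng: np.random.Generator, config: SimConfig, true_values: dict[Channel, float]
) -> dict[Channel, float]:
    """Apply the noise model to one well's channel reads.

    The per-well dispensing factor is shared by all channels and scales only
    the signal above the plate background; the per-read detection factor and
    the additive floor are independent per channel.  Channels are processed
    in a fixed (excitation, emission) order so output is byte-identical for
    identical seeds.
    """
    well_factor = 1.0 + rng.normal(0.0, config.noise_cv) if config.noise_cv else 1.0
    additive = config.additive_sd
    out = {}
    for ch in sorted(true_values, key=lambda c: (c.excitation_nm, c.emission_nm)):
        signal = true_values[ch] - config.blank_rfu
        v = config.blank_rfu + signal * well_factor
        if config.read_noise_cv:
            v *= 1.0 + rng.normal(0.0, config.read_noise_cv)
        if additive:
            v += rng.normal(0.0, additive)
        out[ch] = v
    return out


def simulate_well(
    config: SimConfig,
    channel: Channel,
    compound: Optional[CompoundSpec] = None,
    compound_conc: float = 0.0,
    binding_enabled: bool = True,
    seed: Optional[int] = None,
) -> float:
    """One noisy intensity (seed defaults to ``config.seed``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    true = noiseless_intensity(
        config, channel, compound, compound_conc, binding_enabled
    )
    return _noisy_reads(rng, config, {channel: true})[channel]


def _well_iter(plate_format: int):
    nrow, ncol = PLATE_DIMS[plate_format]
    for col in range(ncol):
        for row in range(nrow):
            yield f"{row_label(row)}{col + 1}"


def _add_well(
    plate: Plate,
    rng: np.random.Generator,
    config: SimConfig,
    well_id: str,
    role: str,
    channels: Sequence[Channel],
    compound: Optional[CompoundSpec] = None,
    compound_conc: float = 0.0,
    binding_enabled: bool = True,
    donor_total: Optional[float] = None,
    acceptor_total: Optional[float] = None,
) -> None:
    d = config.donor_total if donor_total is None else donor_total
    a = config.acceptor_total if acceptor_total is None else acceptor_total
    if role == "blank":
        d = a = 0.0
    true = {
        ch: noiseless_intensity(
            config, ch, compound, compound_conc, binding_enabled,
            donor_total=d, acceptor_total=a,
        )
        for ch in channels
    }
    well = WellRecord(
        well_id=well_id,
        role=role,
        compound_id=compound.compound_id if compound else None,
        compound_conc=compound_conc if compound else None,
        donor_conc=d,
        acceptor_conc=a,
        reads=_noisy_reads(rng, config, true),
    )
    plate.add_well(well)


# ---------------------------------------------------------------------------
# QC / control plates
# ---------------------------------------------------------------------------

def simulate_qc_plate(
    config: SimConfig,
    n_neg: int = 680,
    n_pos: int = 680,
    n_blanks: int = 16,
    plate_id: str = "qc",
    seed: Optional[int] = None,
) -> Plate:
    """Control-only plate: intact FRET pair (negative) vs GdnHCl-disrupted
    (positive) wells plus buffer blanks, read at 410 nm."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nrow, ncol = PLATE_DIMS[config.plate_format]
    if n_neg + n_pos + n_blanks > nrow * ncol:
        raise ConfigurationError("controls do not fit on the plate")
    plate = Plate(plate_id=plate_id, format=config.plate_format, assay_label=config.assay_label)
    wells = _well_iter(config.plate_format)
    for _ in range(n_blanks):
        _add_well(plate, rng, config, next(wells), "blank", RFRET_CHANNELS)
    for _ in range(n_neg):
        _add_well(plate, rng, config, next(wells), "negative_control", RFRET_CHANNELS)
    for _ in range(n_pos):
        _add_well(
            plate, rng, config, next(wells), "positive_control", RFRET_CHANNELS,
            binding_enabled=False,
        )
    return plate


# ---------------------------------------------------------------------------
# Kd titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationSim:
    plate: Plate
    series: TitrationSeries
    truth: dict


def simulate_titration(
    config: SimConfig,
    acceptor_ladder: Optional[Sequence[float]] = None,
    replicates: int = 1,
    n_calibration: int = 8,
    n_blanks: int = 4,
    seed: Optional[int] = None,
) -> TitrationSim:
    """Acceptor-ladder titration plate with calibration wells and truth record.

    Emits the three EmFRET channels per titration point plus donor-only and
    acceptor-only calibration wells; the truth record carries the configured
    Kd and the implied EmFRET plateau.  Acceptor-only wells are placed at the
    top of the ladder: the direct-excitation ratio scales the correction
    linearly in acceptor concentration, so it must be measured where its
    relative error is smallest.
    """
    ladder = DEFAULT_ACCEPTOR_LADDER_M if acceptor_ladder is None else tuple(acceptor_ladder)
    if len(ladder) < 2:
        raise ConfigurationError("acceptor ladder needs >= 2 concentrations")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fmt = 384 if len(ladder) * replicates + 2 * n_calibration + n_blanks <= 384 else 1536
    plate = Plate(plate_id="titration", format=fmt, assay_label=config.assay_label)
    wells = _well_iter(fmt)

    for _ in range(n_blanks):
        _add_well(plate, rng, config, next(wells), "blank", EMFRET_CHANNELS)
    for _ in range(n_calibration):  # donor-only calibration
        _add_well(
            plate, rng, config, next(wells), "sample", EMFRET_CHANNELS,
            acceptor_total=0.0,
        )
    for _ in range(n_calibration):  # acceptor-only calibration, ladder top
        _add_well(
            plate, rng, config, next(wells), "sample", EMFRET_CHANNELS,
            donor_total=0.0, acceptor_total=max(ladder),
        )
    marker = CompoundSpec("titration_point", "inactive")
    for a_conc in ladder:
        for _ in range(replicates):
            _add_well(
                plate, rng, config, next(wells), "sample", EMFRET_CHANNELS,
                compound=marker, compound_conc=0.0, acceptor_total=a_conc,
            )

    from .fret_model import series_from_plate  # deferred: plate -> series glue
    from .plate_io import subtract_blanks

    series = series_from_plate(subtract_blanks(plate), donor_total=config.donor_total)
    emfret_max = (
        config.transfer_efficiency * config.donor_total * 1e9
        * config.donor.ex(430) * config.acceptor.em(527) * config.acceptor.brightness
    )
    truth = {
        "kd": config.kd_pair,
        "emfret_max": emfret_max,
        "donor_total": config.donor_total,
    }
    return TitrationSim(plate=plate, series=series, truth=truth)


def simulate_titration_series(
    config: SimConfig,
    acceptor_ladder: Optional[Sequence[float]] = None,
    replicates: int = 4,
    seed: Optional[int] = None,
) -> tuple[TitrationSeries, dict]:
    """EmFRET-level titration series: model values with per-point noise.

    Unlike :func:`simulate_titration` (which builds a full plate and runs the
    blank-subtraction/calibration path), this generator perturbs the EmFRET
    values directly — multiplicative CV per point plus an additive floor of
    0.5% of the plateau.  It is the right input for Monte-Carlo studies of
    the fit and its confidence interval, where per-plate calibration
    systematics would confound the per-point error model.
    """
    ladder = np.asarray(
        DEFAULT_ACCEPTOR_LADDER_M if acceptor_ladder is None else acceptor_ladder,
        dtype=float,
    )
    if ladder.size < 2:
        raise ConfigurationError("acceptor ladder needs >= 2 concentrations")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d = config.donor_total
    emfret_max = (
        config.transfer_efficiency * d * 1e9
        * config.donor.ex(430) * config.acceptor.em(527) * config.acceptor.brightness
    )
    acceptors = np.repeat(ladder, replicates)
    y = emfret_max * bound_complex(d, acceptors, config.kd_pair) / d
    if config.noise_cv:
        y = y * (1.0 + rng.normal(0.0, config.noise_cv, size=y.size))
    floor = 0.005 * emfret_max
    if config.noise_cv and floor:
        y = y + rng.normal(0.0, floor, size=y.size)
    series = TitrationSeries(donor_total=d, acceptor_totals=acceptors, emfret=y)
    truth = {"kd": config.kd_pair, "emfret_max": emfret_max, "donor_total": d}
    return series, truth


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenSim:
    """Plates for both assays plus the per-compound truth table."""

    pre_a: Plate
    assay_a: Plate
    pre_b: Plate
    assay_b: Plate
    truth: "pd.DataFrame"  # type: ignore[name-defined]  # noqa: F821
    library: list[CompoundSpec]


SCREEN_CHANNELS = RFRET_CHANNELS + RFRET_CHANNELS_430
PREREAD_CHANNELS = RFRET_CHANNELS


def _screen_plates(
    config: SimConfig,
    library: Sequence[CompoundSpec],
    screen_conc: float,
    rng: np.random.Generator,
    n_controls: int = 32,
    n_blanks: int = 16,
) -> tuple[Plate, Plate]:
    nrow, ncol = PLATE_DIMS[config.plate_format]
    if len(library) + 2 * n_controls + n_blanks > nrow * ncol:
        raise ConfigurationError("library does not fit on one plate")

    pre = Plate(
        plate_id=f"pre_{config.assay_key}", format=config.plate_format,
        assay_label=config.assay_label,
    )
    assay = Plate(
        plate_id=f"assay_{config.assay_key}", format=config.plate_format,
        assay_label=config.assay_label,
    )

    wells = list(_well_iter(config.plate_format))
    blank_wells = wells[:n_blanks]
    neg_wells = wells[n_blanks : n_blanks + n_controls]
    pos_wells = wells[n_blanks + n_controls : n_blanks + 2 * n_controls]
    compound_wells = wells[n_blanks + 2 * n_controls :]

    # compound-only pre-read plate (no protein), excitation 410 nm
    for w in blank_wells:
        _add_well(pre, rng, config, w, "blank", PREREAD_CHANNELS)
    for w, spec in zip(compound_wells, library):
        _add_well(
            pre, rng, config, w, "sample", PREREAD_CHANNELS,
            compound=spec, compound_conc=screen_conc,
            donor_total=0.0, acceptor_total=0.0,
        )

    # assay plate with the FRET pair, read at 410 and 430 nm
    for w in blank_wells:
        _add_well(assay, rng, config, w, "blank", SCREEN_CHANNELS)
    for w in neg_wells:
        _add_well(assay, rng, config, w, "negative_control", SCREEN_CHANNELS)
    for w in pos_wells:
        _add_well(
            assay, rng, config, w, "positive_control", SCREEN_CHANNELS,
            binding_enabled=False,
        )
    for w, spec in zip(compound_wells, library):
        _add_well(
            assay, rng, config, w, "sample", SCREEN_CHANNELS,
            compound=spec, compound_conc=screen_conc,
        )
    return pre, assay


def simulate_screen(
    config_a: SimConfig = ASSAY_A_CONFIG,
    config_b: SimConfig = ASSAY_B_CONFIG,
    library: Optional[Sequence[CompoundSpec]] = None,
    screen_conc: float = 100e-6,
    seed: int = 0,
) -> ScreenSim:
    """Two parallel assay screens of the same library, with truth table."""
    import pandas as pd

    if library is None:
        library = make_library(seed=seed)
    library = list(library)
    if not library:
        raise ConfigurationError("empty compound library")

    rng = np.random.default_rng(seed)
    pre_a, assay_a = _screen_plates(config_a, library, screen_conc, rng)
    pre_b, assay_b = _screen_plates(config_b, library, screen_conc, rng)

    truth = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in library],
            "compound_class": [c.compound_class for c in library],
            "variant": [c.variant for c in library],
            "expected_stage_A": [c.expected_stage.get("A") for c in library],
            "expected_stage_B": [c.expected_stage.get("B") for c in library],
            "expected_hit_A": [c.expected_hit.get("A", False) for c in library],
            "expected_hit_B": [c.expected_hit.get("B", False) for c in library],
        }
    )
    return ScreenSim(
        pre_a=pre_a, assay_a=assay_a, pre_b=pre_b, assay_b=assay_b,
        truth=truth, library=library,
    )


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

#: IC50-assay probe conditions: 50 nM donor, 100 nM acceptor, Kd 35 nM
IC50_ASSAY_CONFIG = SimConfig(
    kd_pair=35e-9, donor_total=50e-9, acceptor_total=100e-9,
    assay_key="A", assay_label="ARC4-TBM IC50",
)

#: dilution-series design: points per ladder and half-span (decades) around
#: the expected potency, as an IC50 assay brackets its transition
DOSE_LADDER_POINTS = 17
DOSE_LADDER_HALF_SPAN_DECADES = 2.0


@dataclass
class DoseResponseSim:
    series: "object"  # DoseResponseSeries
    truth: dict


def true_ic50(config: SimConfig, ki: float) -> float:
    """Inhibitor total at which the complex is halved (exact equilibrium)."""
    from scipy.optimize import brentq

    system = CompetitionSystem(config.donor_total, config.acceptor_total, config.kd_pair, ki)
    da0 = bound_complex(config.donor_total, config.acceptor_total, config.kd_pair)

    def g(log_i: float) -> float:
        return competition_equilibrium(system, 10.0**log_i).complex_da - 0.5 * da0

    return float(10.0 ** brentq(g, -12.0, 1.0, xtol=1e-12))


def simulate_dose_response(
    ki: float,
    config: SimConfig = IC50_ASSAY_CONFIG,
    concentrations: Optional[Sequence[float]] = None,
    replicates: int = 4,
    seed: Optional[int] = None,
    compound_id: str = "compound",
):
    """Percent-inhibition dose-response series from the ternary equilibrium.

    The readout emulated here is the sensitized acceptor emission (linear in
    complex concentration); per-point signals carry multiplicative CV noise
    plus a small additive floor, and are normalised to percent inhibition
    against no-compound (0%) and GdnHCl (100%) controls.  Anchor controls sit
    two log-units beyond the tested range, as in the assay layout.  The
    default dilution series brackets the compound's expected potency by two
    decades on either side, the way an IC50 experiment is ranged in practice.
    """
    from .dose_response import DoseResponseSeries

    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if concentrations is None:
        center = true_ic50(config, ki)
        half = 10.0**DOSE_LADDER_HALF_SPAN_DECADES
        concentrations = np.geomspace(center / half, center * half, DOSE_LADDER_POINTS)
    concs = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    system = CompetitionSystem(config.donor_total, config.acceptor_total, config.kd_pair, ki)
    sens = (
        config.transfer_efficiency * 1e9 * config.donor.ex(410)
        * config.acceptor.em(527) * config.acceptor.brightness
    )  # RFU per molar of complex
    da0 = bound_complex(config.donor_total, config.acceptor_total, config.kd_pair)
    signal0 = sens * da0
    additive = 0.0025 * signal0 if config.noise_cv else 0.0

    def measure(da: float, n: int) -> np.ndarray:
        s = sens * da
        vals = s * (1.0 + rng.normal(0.0, config.noise_cv, size=n))
        if additive:
            vals = vals + rng.normal(0.0, additive, size=n)
        return vals

    neg_ref = float(np.mean(measure(da0, replicates)))  # no compound: 0%
    pos_ref = float(np.mean(measure(0.0, replicates)))  # GdnHCl: 100%

    def to_inhibition(values: np.ndarray) -> np.ndarray:
        return 100.0 * (neg_ref - values) / (neg_ref - pos_ref)

    xs, ys = [], []
    for c in concs:
        da = competition_equilibrium(system, float(c)).complex_da
        inh = to_inhibition(measure(da, replicates))
        xs.extend([float(c)] * replicates)
        ys.extend(inh.tolist())

    anchor_low = float(np.mean(to_inhibition(measure(da0, replicates))))
    anchor_high = float(np.mean(to_inhibition(measure(0.0, replicates))))

    series = DoseResponseSeries(
        compound_id=compound_id,
        concentrations=np.array(xs),
        responses=np.array(ys),
        anchor_low_response=anchor_low,
        anchor_high_response=anchor_high,
    )
    truth = {"ki": ki, "ic50": true_ic50(config, ki), "kd_probe": config.kd_pair}
    return DoseResponseSim(series=series, truth=truth)


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------

@dataclass
class MeltSim:
    sample: list[MeltCurve]
    control: list[MeltCurve]
    truth: dict


def simulate_melt_curves(
    tm: float,
    delta_tm: float = 0.0,
    replicates: int = 4,
    noise_cv: float = 0.01,
    seed: int = 0,
    temp_min: float = 20.0,
    temp_max: float = 95.0,
    condition: str = "compound",
) -> MeltSim:
    """SYPRO-orange-type melt curves: Boltzmann rise, post-peak linear decline.

    Control replicates melt at ``tm``; sample replicates at ``tm + delta_tm``.
    Curves are sampled at 1 degree C steps and carry multiplicative noise.
    """
    if not temp_min < tm < temp_max:
        raise ConfigurationError(f"tm={tm} outside ({temp_min}, {temp_max})")
    if not temp_min < tm + delta_tm < temp_max:
        raise ConfigurationError("shifted tm outside the temperature range")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")

    rng = np.random.default_rng(seed)
    temps = np.arange(temp_min, temp_max + 0.5, 1.0)
    b_low, b_high, slope = 1000.0, 11000.0, 2.0
    peak_offset = 12.0  # degrees past Tm where aggregation takes over
    decline = 0.02 * (b_high - b_low)  # RFU per degree after the peak

    def curve(true_tm: float, sample_id: str, cond: str) -> MeltCurve:
        boltz = b_low + (b_high - b_low) / (1.0 + np.exp((true_tm - temps) / slope))
        t_peak = true_tm + peak_offset
        f = np.where(
            temps <= t_peak,
            boltz,
            (b_low + (b_high - b_low) / (1.0 + np.exp(-peak_offset / slope)))
            - decline * (temps - t_peak),
        )
        if noise_cv:
            f = f * (1.0 + rng.normal(0.0, noise_cv, size=f.size))
        return MeltCurve(
            temperatures=temps.copy(), fluorescence=f, sample_id=sample_id, condition=cond
        )

    control = [curve(tm, f"control_{i + 1}", "control") for i in range(replicates)]
    sample = [curve(tm + delta_tm, f"{condition}_{i + 1}", condition) for i in range(replicates)]
    truth = {"tm_control": tm, "tm_sample": tm + delta_tm, "delta_tm": delta_tm}
    return MeltSim(sample=sample, control=control, truth=truth)
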