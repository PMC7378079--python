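"""Validatory-screen analysis: interference filtering and hit calling.

Two assays (an ARC-TBM-type and a SAM-dimer-type FRET pair) are screened in
parallel against the same library.  Per compound and assay the pipeline
computes percent inhibition at both excitation wavelengths (410 nm primary,
430 nm secondary) and applies a three-stage exclusion cascade:

1. fluorescence interference: a compound-only pre-read more than 5x above the
   plate background in either emission channel, or assay-well fluorescence
   deviating more than 30% from the FRET-pair controls in either channel;
2. dual-excitation discrepancy: more than 10 percentage points difference in
   apparent inhibition between the 410 and 430 nm readouts;
3. pan-assay interference: apparent signal reduction in both assays
   simultaneously (evaluated on survivors of stages 1-2 within each assay).

Each excluded compound is attributed to the first triggering stage, so the
stage counts partition the exclusions.  Survivors with >= 20% inhibition at
410 nm are hits.  Stage thresholds follow the strict "more than" reading;
the hit threshold is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import assay_qc, fret_model, plate_io
from .errors import ConfigurationError, QCError, ReconciliationError, ValidationError

FLAG_AUTOFLUOR = "strong_autofluorescence"
FLAG_DEVIATION = "fret_fluor_deviation"
FLAG_DUAL = "dual_excitation_discrepancy"
FLAG_PAN = "pan_assay"

STAGE_FLUOR = "fluorescence"
STAGE_DUAL = "dual_excitation"
STAGE_PAN = "pan_assay"


@dataclass(frozen=True)
class CompoundPreRead:
    """Compound-only fluorescence measured before protein transfer (ex 410)."""

    compound_id: str
    fluor_477: float
    fluor_527: float
    background_477: float
    background_527: float

    def __post_init__(self) -> None:
        if min(self.fluor_477, self.fluor_527) < 0:
            raise ValidationError("pre-read intensities must be >= 0")


@dataclass
class ScreenResult:
    compound_id: str
    inhibition_410: float
    inhibition_430: float
    flags: set[str] = field(default_factory=set)
    excluded_by: Optional[str] = None
    is_hit: bool = False
    pan_not_evaluable: bool = False


@dataclass(frozen=True)
class ScreenSummary:
    n_screened: int
    n_excluded_fluor: int
    n_excluded_dual: int
    n_excluded_pan: int
    n_excluded_total: int
    n_hits: int
    pct_excluded_fluor: str
    pct_excluded_dual: str
    pct_excluded_pan: str
    pct_excluded_total: str
    pct_hits: str

    @classmethod
    def from_counts(
        cls,
        n_screened: int,
        n_excluded_fluor: int,
        n_excluded_dual: int,
        n_excluded_pan: int,
        n_hits: int,
    ) -> "ScreenSummary":
        if n_screened <= 0:
            raise ValidationError("n_screened must be positive")
        total = n_excluded_fluor + n_excluded_dual + n_excluded_pan
        if n_hits > n_screened - total:
            raise ValidationError("more hits than surviving compounds")
        fp = plate_io.format_percent
        return cls(
            n_screened=n_screened,
            n_excluded_fluor=n_excluded_fluor,
            n_excluded_dual=n_excluded_dual,
            n_excluded_pan=n_excluded_pan,
            n_excluded_total=total,
            n_hits=n_hits,
            pct_excluded_fluor=fp(n_excluded_fluor, n_screened, 1),
            pct_excluded_dual=fp(n_excluded_dual, n_screened, 1),
            pct_excluded_pan=fp(n_excluded_pan, n_screened, 1),
            pct_excluded_total=fp(total, n_screened, 1),
            pct_hits=fp(n_hits, n_screened, 2),
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ScreenConfig:
    autofluorescence_fold: float = 5.0
    deviation_fraction: float = 0.30
    dual_excitation_diff: float = 10.0  # percentage points
    pan_reduction: float = 20.0  # percent inhibition
    hit_threshold: float = 20.0  # percent inhibition, inclusive


def filter_autofluorescence(pre: CompoundPreRead, fold_threshold: float = 5.0) -> bool:
    """True (exclude) iff either pre-read channel is strictly above
    ``fold_threshold`` times the plate background."""
    if pre.background_477 <= 0 or pre.background_527 <= 0:
        raise ConfigurationError("pre-read background must be > 0")
    return (
        pre.fluor_477 > fold_threshold * pre.background_477
        or pre.fluor_527 > fold_threshold * pre.background_527
    )


def filter_fret_deviation(
    sample_477: float,
    sample_527: float,
    control_477: float,
    control_527: float,
    rel_threshold: float = 0.30,
) -> bool:
    """True iff the FRET-pair well intensity deviates strictly more than
    ``rel_threshold`` (relative) from the control mean in either channel."""
    if control_477 <= 0 or control_527 <= 0:
        raise ConfigurationError("control intensities must be > 0")
    return (
        abs(sample_477 - control_477) / control_477 > rel_threshold
        or abs(sample_527 - control_527) / control_527 > rel_threshold
    )


def filter_dual_excitation(
    inhibition_410: float, inhibition_430: float, diff_threshold: float = 10.0
) -> bool:
    """True iff apparent inhibition differs strictly more than
    ``diff_threshold`` percentage points between the two excitations."""
    return abs(inhibition_410 - inhibition_430) > diff_threshold


def filter_pan_assay(
    inhibition_this: float,
    inhibition_other: Optional[float],
    reduction_threshold: float = 20.0,
) -> tuple[bool, bool]:
    """(flag, evaluable): flagged iff inhibition reaches the reduction
    threshold in this assay *and* in the parallel assay.  A compound missing
    from the other assay is not evaluable and never excluded by this filter."""
    if inhibition_other is None:
        return False, False
    return (
        inhibition_this >= reduction_threshold
        and inhibition_other >= reduction_threshold,
        True,
    )


def call_hits(results, hit_threshold: float = 20.0):
    """Mark survivors with inhibition (410 nm) at or above the threshold."""
    for r in results:
        r.is_hit = r.excluded_by is None and r.inhibition_410 >= hit_threshold
    return results


def summarize_screen(results) -> ScreenSummary:
    results = list(results)
    counts = {STAGE_FLUOR: 0, STAGE_DUAL: 0, STAGE_PAN: 0}
    hits = 0
    for r in results:
        if r.excluded_by is not None:
            counts[r.excluded_by] += 1
        elif r.is_hit:
            hits += 1
    return ScreenSummary.from_counts(
        n_screened=len(results),
        n_excluded_fluor=counts[STAGE_FLUOR],
        n_excluded_dual=counts[STAGE_DUAL],
        n_excluded_pan=counts[STAGE_PAN],
        n_hits=hits,
    )


@dataclass
class AssayData:
    """One assay's screening plates: compound pre-read + FRET assay plate."""

    pre_plate: plate_io.Plate
    assay_plate: plate_io.Plate
    label: str = ""


def _control_channel_means(plate: plate_io.Plate) -> tuple[float, float]:
    """Mean blank-subtracted control intensities at (410,477) and (410,527)."""
    negs = plate.wells_by_role("negative_control")
    if not negs:
        raise QCError("assay plate has no negative controls")
    c477 = float(np.mean([w.intensity(410, 477) for w in negs]))
    c527 = float(np.mean([w.intensity(410, 527) for w in negs]))
    return c477, c527


def _prereads(pre_plate: plate_io.Plate) -> dict[str, CompoundPreRead]:
    blanks = pre_plate.wells_by_role("blank")
    if not blanks:
        raise QCError("pre-read plate has no blank wells for the background")
    bg477 = float(np.mean([w.intensity(410, 477) for w in blanks]))
    bg527 = float(np.mean([w.intensity(410, 527) for w in blanks]))
    out = {}
    for w in pre_plate.wells_by_role("sample"):
        if w.compound_id is None:
            continue
        out[w.compound_id] = CompoundPreRead(
            compound_id=w.compound_id,
            fluor_477=max(w.intensity(410, 477), 0.0),
            fluor_527=max(w.intensity(410, 527), 0.0),
            background_477=bg477,
            background_527=bg527,
        )
    return out


def _screen_single_assay(assay: AssayData, config: ScreenConfig) -> dict[str, ScreenResult]:
    """Stages 1-2 for one assay; the pan-assay stage needs both assays."""
    pre = _prereads(assay.pre_plate)
    plate = plate_io.subtract_blanks(assay.assay_plate)

    controls_410 = assay_qc.control_stats_from_plate(plate, 410, subtract=False)
    controls_430 = assay_qc.control_stats_from_plate(plate, 430, subtract=False)
    control_477, control_527 = _control_channel_means(plate)

    results: dict[str, ScreenResult] = {}
    for well in plate.wells_by_role("sample"):
        cid = well.compound_id
        if cid is None:
            continue
        inh410 = assay_qc.percent_inhibition(
            fret_model.compute_rfret(well, 410).rfret, controls_410
        )
        inh430 = assay_qc.percent_inhibition(
            fret_model.compute_rfret(well, 430).rfret, controls_430
        )
        r = ScreenResult(compound_id=cid, inhibition_410=inh410, inhibition_430=inh430)

        if cid in pre and filter_autofluorescence(pre[cid], config.autofluorescence_fold):
            r.flags.add(FLAG_AUTOFLUOR)
        if filter_fret_deviation(
            well.intensity(410, 477),
            well.intensity(410, 527),
            control_477,
            control_527,
            config.deviation_fraction,
        ):
            r.flags.add(FLAG_DEVIATION)
        if r.flags:
            r.excluded_by = STAGE_FLUOR
        elif filter_dual_excitation(inh410, inh430, config.dual_excitation_diff):
            r.flags.add(FLAG_DUAL)
            r.excluded_by = STAGE_DUAL
        results[cid] = r
    return results


def run_screen(
    assay_a: AssayData,
    assay_b: AssayData,
    config: Optional[ScreenConfig] = None,
) -> tuple[ScreenSummary, ScreenSummary, dict[str, dict[str, ScreenResult]]]:
    """Full two-assay cascade: stages 1-2 per assay, pan-assay stage across
    assays on stage-1/2 survivors, then hit calling and exclusion accounting.
    """
    config = config or ScreenConfig()
    results_a = _screen_single_assay(assay_a, config)
    results_b = _screen_single_assay(assay_b, config)

    if not results_a or not results_b:
        raise ValidationError("empty compound library")
    ids_a, ids_b = set(results_a), set(results_b)
    if ids_a != ids_b:
        raise ReconciliationError(
            "assays screened different libraries; "
            f"A-only={sorted(ids_a - ids_b)[:10]}, B-only={sorted(ids_b - ids_a)[:10]}"
        )

    for this, other in ((results_a, results_b), (results_b, results_a)):
        for cid, r in this.items():
            if r.excluded_by is not None:
                continue
            o = other.get(cid)
            other_inh = o.inhibition_410 if o is not None else None
            flagged, evaluable = filter_pan_assay(
                r.inhibition_410, other_inh, config.pan_reduction
            )
            r.pan_not_evaluable = not evaluable
            if flagged:
                r.flags.add(FLAG_PAN)
                r.excluded_by = STAGE_PAN

    call_hits(results_a.values(), config.hit_threshold)
    call_hits(results_b.values(), config.hit_threshold)
    summary_a = summarize_screen(results_a.values())
    summary_b = summarize_screen(results_b.values())
    return summary_a, summary_b, {"A": results_a, "B": results_b}
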