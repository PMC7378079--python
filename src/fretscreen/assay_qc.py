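"""Control-based assay quality statistics.

The Z'-factor, 1 - 3*(sd_pos + sd_neg)/|mean_neg - mean_pos|, summarises how
well the negative controls (intact FRET pair, 0% inhibition) separate from
the positive controls (chaotrope-disrupted pair, 100% inhibition).  Values
above 0.5 denote an excellent screening window.  All statistics are computed
on the ratiometric FRET signal, and sample standard deviations (n-1
denominator) are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import fret_model, plate_io
from .errors import QCError, ValidationError


@dataclass(frozen=True)
class ControlStats:
    """Per-plate summary of negative and positive control rFRET signals."""

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise QCError("need at least 2 wells per control condition")
        if self.sd_neg < 0 or self.sd_pos < 0:
            raise ValidationError("standard deviations must be >= 0")

    @classmethod
    def from_values(cls, neg: Sequence[float], pos: Sequence[float]) -> "ControlStats":
        neg = np.asarray(neg, dtype=float)
        pos = np.asarray(pos, dtype=float)
        if neg.size < 2 or pos.size < 2:
            raise QCError("need at least 2 wells per control condition")
        return cls(
            mean_neg=float(neg.mean()),
            sd_neg=float(neg.std(ddof=1)),
            mean_pos=float(pos.mean()),
            sd_pos=float(pos.std(ddof=1)),
            n_neg=int(neg.size),
            n_pos=int(pos.size),
        )


@dataclass(frozen=True)
class QCReport:
    zprime: float
    controls: ControlStats
    threshold: float
    passed: bool


def zprime(controls: ControlStats) -> float:
    """Z'-factor of a control pair; undefined when the control means agree."""
    window = abs(controls.mean_neg - controls.mean_pos)
    if window == 0:
        raise QCError("control means are equal; Z' undefined")
    return 1.0 - 3.0 * (controls.sd_pos + controls.sd_neg) / window


def percent_inhibition(rfret_sample, controls: ControlStats):
    """Map an rFRET signal onto the 0% (negative) / 100% (positive) scale.

    Affine and monotone decreasing in the sample signal; values outside
    [0, 100] are reported as-is.  Accepts scalars or arrays.
    """
    window = controls.mean_neg - controls.mean_pos
    if window == 0:
        raise QCError("control means are equal; percent inhibition undefined")
    sample = np.asarray(rfret_sample, dtype=float)
    out = 100.0 * (controls.mean_neg - sample) / window
    if out.ndim == 0:
        return float(out)
    return out


def control_stats_from_plate(
    plate: plate_io.Plate,
    excitation_nm: float = fret_model.RFRET_EXCITATION_NM,
    subtract: bool = True,
) -> ControlStats:
    """Aggregate control rFRET values of a plate (blanks subtracted first)."""
    work = plate_io.subtract_blanks(plate) if subtract else plate
    neg = [
        fret_model.compute_rfret(w, excitation_nm).rfret
        for w in work.wells_by_role("negative_control")
    ]
    pos = [
        fret_model.compute_rfret(w, excitation_nm).rfret
        for w in work.wells_by_role("positive_control")
    ]
    return ControlStats.from_values(neg, pos)


def qc_plate(
    plate: plate_io.Plate,
    threshold: float = 0.5,
    excitation_nm: float = fret_model.RFRET_EXCITATION_NM,
    subtract: bool = True,
) -> QCReport:
    """Compute the plate's Z'-factor and compare against the pass threshold."""
    controls = control_stats_from_plate(plate, excitation_nm, subtract=subtract)
    z = zprime(controls)
    return QCReport(zprime=z, controls=controls, threshold=threshold, passed=z >= threshold)
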