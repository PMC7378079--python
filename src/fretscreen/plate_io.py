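"""Plate-level data model and tabular I/O.

The canonical measurement file is long format with columns
``well, excitation_nm, emission_nm, intensity`` — channel-explicit storage
avoids any ambiguity between the three excitation wavelengths used by the
assay (410, 430 and 477 nm).  The plate map carries one row per well:
``well, role, compound_id, compound_conc_m, donor_conc_m, acceptor_conc_m``.
Concentrations are molar, intensities are relative fluorescence units (RFU).

Well coordinates are row letter(s) + 1-based column ("A1"); 1536-well plates
extend the row alphabet beyond ``Z`` with ``AA``–``AF``, matching plate-reader
export conventions.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import (
    DuplicateReadError,
    FormatError,
    MissingBlankError,
    MissingChannelError,
    ValidationError,
)

ROLES = ("sample", "negative_control", "positive_control", "blank")

#: plate format -> (rows, columns)
PLATE_DIMS = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

_WELL_RE = re.compile(r"^([A-Z]{1,2})(\d{1,2})$")

MEASUREMENT_COLUMNS = ("well", "excitation_nm", "emission_nm", "intensity")
MAP_COLUMNS = (
    "well",
    "role",
    "compound_id",
    "compound_conc_m",
    "donor_conc_m",
    "acceptor_conc_m",
)


def row_label(index: int) -> str:
    """0-based row index -> row letters (A..Z, AA..AF)."""
    if index < 26:
        return chr(ord("A") + index)
    return "A" + chr(ord("A") + index - 26)


def parse_well(well_id: str) -> tuple[int, int]:
    """Well id -> 0-based (row, column) indices."""
    m = _WELL_RE.match(str(well_id).strip().upper())
    if not m:
        raise ValidationError(f"unparseable well coordinate: {well_id!r}")
    letters, digits = m.groups()
    if len(letters) == 1:
        row = ord(letters) - ord("A")
    else:
        if letters[0] != "A":
            raise ValidationError(f"row label out of range: {well_id!r}")
        row = 26 + ord(letters[1]) - ord("A")
    col = int(digits) - 1
    if col < 0:
        raise ValidationError(f"column must be >= 1: {well_id!r}")
    return row, col


def validate_well(well_id: str, plate_format: int) -> None:
    if plate_format not in PLATE_DIMS:
        raise ValidationError(f"unknown plate format: {plate_format}")
    nrow, ncol = PLATE_DIMS[plate_format]
    row, col = parse_well(well_id)
    if row >= nrow or col >= ncol:
        raise ValidationError(
            f"well {well_id!r} outside {plate_format}-well plate ({nrow}x{ncol})"
        )


@dataclass(frozen=True)
class Channel:
    """One (excitation, emission) wavelength pair.

    The free-text label ("donor", "fret", ...) is metadata and does not take
    part in channel identity.
    """

    excitation_nm: float
    emission_nm: float
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.excitation_nm <= 0 or self.emission_nm <= 0:
            raise ValidationError("wavelengths must be positive")
        if self.excitation_nm >= self.emission_nm:
            raise ValidationError(
                "FRET channels require excitation below emission "
                f"({self.excitation_nm} >= {self.emission_nm})"
            )


@dataclass
class WellRecord:
    """A well's role, contents and all of its channel reads."""

    well_id: str
    role: str
    compound_id: Optional[str] = None
    compound_conc: Optional[float] = None  # molar
    donor_conc: float = 0.0  # molar
    acceptor_conc: float = 0.0  # molar
    reads: dict[Channel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role: {self.role!r}")
        if self.donor_conc < 0 or self.acceptor_conc < 0:
            raise ValidationError("protein concentrations must be >= 0")
        if self.role == "blank" and (self.donor_conc > 0 or self.acceptor_conc > 0):
            raise ValidationError(
                f"blank well {self.well_id} must not carry protein"
            )

    def intensity(self, excitation_nm: float, emission_nm: float) -> float:
        ch = Channel(excitation_nm, emission_nm)
        try:
            return self.reads[ch]
        except KeyError:
            raise MissingChannelError(
                f"well {self.well_id} has no read at "
                f"(ex {excitation_nm} nm, em {emission_nm} nm)"
            ) from None

    def has_channel(self, excitation_nm: float, emission_nm: float) -> bool:
        return Channel(excitation_nm, emission_nm) in self.reads


@dataclass
class Plate:
    """A microplate: format, assay label and all well records."""

    plate_id: str
    format: int
    wells: dict[str, WellRecord] = field(default_factory=dict)
    assay_label: str = ""

    def __post_init__(self) -> None:
        if self.format not in PLATE_DIMS:
            raise ValidationError(f"unknown plate format: {self.format}")
        for well_id in self.wells:
            validate_well(well_id, self.format)

    def add_well(self, well: WellRecord) -> None:
        validate_well(well.well_id, self.format)
        if well.well_id in self.wells:
            raise DuplicateReadError(f"well {well.well_id} defined twice")
        self.wells[well.well_id] = well

    def wells_by_role(self, role: str) -> list[WellRecord]:
        if role not in ROLES:
            raise ValidationError(f"unknown well role: {role!r}")
        return [w for w in self.wells.values() if w.role == role]

    def channels(self) -> set[Channel]:
        out: set[Channel] = set()
        for w in self.wells.values():
            out.update(w.reads)
        return out


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing columns: {missing}")


def infer_format(well_ids: Iterable[str]) -> int:
    """Smallest standard plate format containing every coordinate."""
    coords = [parse_well(w) for w in well_ids]
    for fmt in sorted(PLATE_DIMS):
        nrow, ncol = PLATE_DIMS[fmt]
        if all(r < nrow and c < ncol for r, c in coords):
            return fmt
    raise ValidationError("well coordinates exceed the largest supported format")


def read_plate(
    measurement_table,
    plate_map,
    plate_id: str = "plate",
    plate_format: Optional[int] = None,
    assay_label: str = "",
) -> Plate:
    """Read and cross-validate a long-format measurement table and a plate map.

    Wells present in only one of the two files are an error; duplicate
    (well, channel) rows and unknown roles are errors.  Requires at least one
    blank well so downstream blank subtraction is possible.
    """
    meas = _read_table(measurement_table)
    pmap = _read_table(plate_map)
    _require_columns(meas, MEASUREMENT_COLUMNS, "measurement table")
    _require_columns(pmap, ("well", "role"), "plate map")

    meas = meas.copy()
    pmap = pmap.copy()
    meas["well"] = meas["well"].astype(str).str.strip().str.upper()
    pmap["well"] = pmap["well"].astype(str).str.strip().str.upper()

    if pmap["well"].duplicated().any():
        dups = sorted(pmap.loc[pmap["well"].duplicated(), "well"].unique())
        raise DuplicateReadError(f"plate map lists wells twice: {dups}")

    dup_mask = meas.duplicated(subset=["well", "excitation_nm", "emission_nm"])
    if dup_mask.any():
        dups = meas.loc[dup_mask, ["well", "excitation_nm", "emission_nm"]]
        raise DuplicateReadError(
            "duplicate (well, channel) measurements: "
            + ", ".join(
                f"{r.well}({r.excitation_nm:g},{r.emission_nm:g})"
                for r in dups.itertuples()
            )
        )

    meas_wells = set(meas["well"])
    map_wells = set(pmap["well"])
    if meas_wells != map_wells:
        only_meas = sorted(meas_wells - map_wells)
        only_map = sorted(map_wells - meas_wells)
        raise ValidationError(
            "measurement table and plate map disagree on wells; "
            f"measurements-only={only_meas[:10]}, map-only={only_map[:10]}"
        )

    if plate_format is None:
        plate_format = infer_format(map_wells)

    plate = Plate(plate_id=plate_id, format=plate_format, assay_label=assay_label)
    grouped = {w: g for w, g in meas.groupby("well")}
    for rec in pmap.itertuples():
        role = str(rec.role)
        cid = getattr(rec, "compound_id", None)
        if cid is not None and (pd.isna(cid) or str(cid) == ""):
            cid = None
        cc = getattr(rec, "compound_conc_m", None)
        cc = None if cc is None or pd.isna(cc) else float(cc)
        dc = getattr(rec, "donor_conc_m", 0.0)
        ac = getattr(rec, "acceptor_conc_m", 0.0)
        well = WellRecord(
            well_id=rec.well,
            role=role,
            compound_id=None if cid is None else str(cid),
            compound_conc=cc,
            donor_conc=0.0 if pd.isna(dc) else float(dc),
            acceptor_conc=0.0 if pd.isna(ac) else float(ac),
        )
        for m in grouped[rec.well].itertuples():
            well.reads[Channel(float(m.excitation_nm), float(m.emission_nm))] = float(
                m.intensity
            )
        plate.add_well(well)

    if not plate.wells_by_role("blank"):
        raise ValidationError(
            f"plate {plate_id!r} has no blank wells; blank subtraction impossible"
        )
    return plate


def plate_to_tables(plate: Plate) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`read_plate`: long measurement table + plate map."""
    meas_rows = []
    map_rows = []
    for well in plate.wells.values():
        map_rows.append(
            {
                "well": well.well_id,
                "role": well.role,
                "compound_id": well.compound_id,
                "compound_conc_m": well.compound_conc,
                "donor_conc_m": well.donor_conc,
                "acceptor_conc_m": well.acceptor_conc,
            }
        )
        for ch, intensity in sorted(
            well.reads.items(), key=lambda kv: (kv[0].excitation_nm, kv[0].emission_nm)
        ):
            meas_rows.append(
                {
                    "well": well.well_id,
                    "excitation_nm": ch.excitation_nm,
                    "emission_nm": ch.emission_nm,
                    "intensity": intensity,
                }
            )
    return pd.DataFrame(meas_rows), pd.DataFrame(map_rows)


def write_plate(plate: Plate, measurement_path, map_path) -> None:
    meas, pmap = plate_to_tables(plate)
    meas.to_csv(measurement_path, index=False)
    pmap.to_csv(map_path, index=False)


def subtract_blanks(plate: Plate, floor: Optional[float] = None) -> Plate:
    """Subtract per-channel mean blank intensity from every non-blank well.

    The mean over all blank wells is used (robust for more than one blank).
    Negative corrected intensities are kept and a warning is emitted under the
    default policy; pass ``floor`` to clamp them instead.  A channel present
    in non-blank wells but absent from the blanks is an error.
    """
    blanks = plate.wells_by_role("blank")
    if not blanks:
        raise MissingBlankError(f"plate {plate.plate_id!r} has no blank wells")

    blank_means: dict[Channel, float] = {}
    for ch in plate.channels():
        vals = [b.reads[ch] for b in blanks if ch in b.reads]
        if vals:
            blank_means[ch] = sum(vals) / len(vals)

    new_wells: dict[str, WellRecord] = {}
    n_negative = 0
    for well_id, well in plate.wells.items():
        if well.role == "blank":
            new_wells[well_id] = replace(well, reads=dict(well.reads))
            continue
        reads: dict[Channel, float] = {}
        for ch, intensity in well.reads.items():
            if ch not in blank_means:
                raise MissingBlankError(
                    f"channel (ex {ch.excitation_nm:g}, em {ch.emission_nm:g}) has "
                    "no blank reads"
                )
            corrected = intensity - blank_means[ch]
            if corrected < 0:
                if floor is not None:
                    corrected = floor
                else:
                    n_negative += 1
            reads[ch] = corrected
        new_wells[well_id] = replace(well, reads=reads)

    if n_negative:
        warnings.warn(
            f"{n_negative} blank-subtracted intensities are negative on plate "
            f"{plate.plate_id!r} (kept as-is)",
            stacklevel=2,
        )
    return Plate(
        plate_id=plate.plate_id,
        format=plate.format,
        wells=new_wells,
        assay_label=plate.assay_label,
    )


def format_percent(count: float, total: float, decimals: int) -> str:
    """``round(100*count/total, decimals)`` as a fixed-point percent string.

    Uses Python's round-half-even; exclusion percentages are printed to one
    decimal and hit rates to two.
    """
    if total <= 0:
        raise ValidationError("total must be positive for percentage formatting")
    value = round(100.0 * count / total, decimals)
    return f"{value:.{decimals}f}%"


def write_screen_report(results, path, summaries: Optional[Mapping] = None) -> None:
    """Write the per-compound screen report (CSV) plus a JSON summary block.

    ``results`` is a collection of ScreenResult-like objects (see
    :mod:`fretscreen.screen_pipeline`).  The JSON summary lands next to the
    CSV with suffix ``.summary.json`` and contains per-filter exclusion counts
    (integer), exclusion percentages to one decimal and hit rates to two.
    """
    results = list(results)
    if not results:
        raise ValidationError("cannot write a report for an empty result set")

    rows = []
    for r in results:
        rows.append(
            {
                "compound_id": r.compound_id,
                "inhibition_410_pct": r.inhibition_410,
                "inhibition_430_pct": r.inhibition_430,
                "flag_strong_autofluorescence": "strong_autofluorescence" in r.flags,
                "flag_fret_fluor_deviation": "fret_fluor_deviation" in r.flags,
                "flag_dual_excitation_discrepancy": "dual_excitation_discrepancy"
                in r.flags,
                "flag_pan_assay": "pan_assay" in r.flags,
                "excluded_by": r.excluded_by or "",
                "is_hit": r.is_hit,
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)

    if summaries is None:
        from .screen_pipeline import summarize_screen  # local: avoids cycle

        summaries = {"summary": summarize_screen(results)}
    payload = {
        name: (summ.to_dict() if hasattr(summ, "to_dict") else summ)
        for name, summ in summaries.items()
    }
    summary_path = path.with_suffix(".summary.json")
    summary_path.write_text(json.dumps(payload, indent=2))
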