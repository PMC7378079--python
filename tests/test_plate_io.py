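"""Plate I/O: parsing, validation, blank subtraction and report formatting."""

import numpy as np
import pandas as pd
import pytest

from fretscreen import plate_io
from fretscreen.errors import (
    DuplicateReadError,
    FormatError,
    MissingBlankError,
    ValidationError,
)
from fretscreen.plate_io import Channel, Plate, WellRecord


class TestWellCoordinates:
    @pytest.mark.parametrize(
        "well,expected",
        [("A1", (0, 0)), ("H12", (7, 11)), ("P24", (15, 23)), ("AA1", (26, 0)), ("AF48", (31, 47))],
    )
    def test_parse(self, well, expected):
        assert plate_io.parse_well(well) == expected

    @pytest.mark.parametrize("well", ["1A", "A0", "ZZ99", "", "A485"])
    def test_unparseable_or_out_of_range(self, well):
        with pytest.raises(ValidationError):
            plate_io.parse_well(well)

    def test_validate_against_format(self):
        plate_io.validate_well("AF48", 1536)
        with pytest.raises(ValidationError):
            plate_io.validate_well("AA1", 384)  # row 27 beyond 16-row plate
        with pytest.raises(ValidationError):
            plate_io.validate_well("I13", 96)

    def test_row_labels_extend_past_z(self):
        assert plate_io.row_label(0) == "A"
        assert plate_io.row_label(25) == "Z"
        assert plate_io.row_label(26) == "AA"
        assert plate_io.row_label(31) == "AF"


class TestDataModel:
    def test_channel_identity_ignores_label(self):
        assert Channel(410, 477, "donor") == Channel(410, 477, "")

    def test_channel_requires_stokes_shift(self):
        with pytest.raises(ValidationError):
            Channel(527, 477)
        with pytest.raises(ValidationError):
            Channel(-410, 477)

    def test_blank_cannot_carry_protein(self):
        with pytest.raises(ValidationError):
            WellRecord("A1", "blank", donor_conc=1e-7)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValidationError):
            WellRecord("A1", "standard")


class TestReadWriteRoundTrip:
    def test_round_trip_losslessly(self, toy_plate, tmp_path):
        mpath, ppath = tmp_path / "meas.csv", tmp_path / "map.csv"
        plate_io.write_plate(toy_plate, mpath, ppath)
        back = plate_io.read_plate(mpath, ppath, plate_id="toy")
        assert set(back.wells) == set(toy_plate.wells)
        assert back.format == 96
        for wid, well in toy_plate.wells.items():
            other = back.wells[wid]
            assert other.role == well.role
            assert other.compound_id == well.compound_id
            assert other.donor_conc == pytest.approx(well.donor_conc)
            assert other.reads == well.reads

    def test_duplicate_channel_row_rejected(self, toy_plate, tmp_path):
        mpath, ppath = tmp_path / "meas.csv", tmp_path / "map.csv"
        plate_io.write_plate(toy_plate, mpath, ppath)
        meas = pd.read_csv(mpath)
        pd.concat([meas, meas.iloc[[0]]]).to_csv(mpath, index=False)
        with pytest.raises(DuplicateReadError):
            plate_io.read_plate(mpath, ppath)

    def test_missing_column_is_format_error(self, toy_plate, tmp_path):
        mpath, ppath = tmp_path / "meas.csv", tmp_path / "map.csv"
        plate_io.write_plate(toy_plate, mpath, ppath)
        pd.read_csv(mpath).drop(columns=["intensity"]).to_csv(mpath, index=False)
        with pytest.raises(FormatError):
            plate_io.read_plate(mpath, ppath)

    def test_unmatched_wells_rejected(self, toy_plate, tmp_path):
        mpath, ppath = tmp_path / "meas.csv", tmp_path / "map.csv"
        plate_io.write_plate(toy_plate, mpath, ppath)
        pmap = pd.read_csv(ppath)
        pmap.loc[len(pmap)] = ["B1", "sample", "CMPX", 1e-6, 1e-7, 2e-7]
        pmap.to_csv(ppath, index=False)
        with pytest.raises(ValidationError, match="disagree"):
            plate_io.read_plate(mpath, ppath)

    def test_out_of_format_coordinate_rejected(self, toy_plate, tmp_path):
        mpath, ppath = tmp_path / "meas.csv", tmp_path / "map.csv"
        plate_io.write_plate(toy_plate, mpath, ppath)
        with pytest.raises(ValidationError):
            # force a 96-well interpretation onto wells that fit, then break it
            meas = pd.read_csv(mpath)
            meas["well"] = meas["well"].str.replace("A", "AA")
            pmap = pd.read_csv(ppath)
            pmap["well"] = pmap["well"].str.replace("A", "AA")
            meas.to_csv(mpath, index=False)
            pmap.to_csv(ppath, index=False)
            plate_io.read_plate(mpath, ppath, plate_format=96)


class TestSubtractBlanks:
    def _plate(self, blanks, sample):
        plate = Plate(plate_id="p", format=96)
        ch = Channel(410, 477)
        for i, b in enumerate(blanks):
            plate.add_well(WellRecord(f"A{i + 1}", "blank", reads={ch: b}))
        plate.add_well(
            WellRecord("B1", "sample", donor_conc=1e-7, reads={ch: sample})
        )
        return plate, ch

    def test_mean_of_blanks_subtracted(self):
        plate, ch = self._plate([8.0, 12.0], 100.0)
        out = plate_io.subtract_blanks(plate)
        assert out.wells["B1"].reads[ch] == pytest.approx(90.0)

    def test_negative_result_kept_with_warning(self):
        plate, ch = self._plate([10.0], 5.0)
        with pytest.warns(UserWarning, match="negative"):
            out = plate_io.subtract_blanks(plate)
        assert out.wells["B1"].reads[ch] == pytest.approx(-5.0)

    def test_floor_clamps_negative(self):
        plate, ch = self._plate([10.0], 5.0)
        out = plate_io.subtract_blanks(plate, floor=0.0)
        assert out.wells["B1"].reads[ch] == 0.0

    def test_not_idempotent_unless_blanks_zero(self):
        plate, ch = self._plate([10.0], 100.0)
        once = plate_io.subtract_blanks(plate)
        twice = plate_io.subtract_blanks(once)
        # blanks keep their raw values, so a second pass subtracts again
        assert twice.wells["B1"].reads[ch] == pytest.approx(80.0)

    def test_zero_blanks_make_it_idempotent(self):
        plate, ch = self._plate([0.0, 0.0], 100.0)
        once = plate_io.subtract_blanks(plate)
        twice = plate_io.subtract_blanks(once)
        assert twice.wells["B1"].reads[ch] == once.wells["B1"].reads[ch]

    def test_channel_missing_from_blanks(self):
        plate, ch = self._plate([10.0], 100.0)
        plate.wells["B1"].reads[Channel(410, 527)] = 50.0
        with pytest.raises(MissingBlankError):
            plate_io.subtract_blanks(plate)


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "count,total,decimals,expected",
        [
            (130, 1120, 1, "11.6%"),
            (153, 1120, 1, "13.7%"),
            (89, 1120, 1, "7.9%"),
            (121, 1120, 1, "10.8%"),
            (29, 1120, 1, "2.6%"),
            (6, 1120, 2, "0.54%"),
            (5, 1120, 2, "0.45%"),  # round-half-even on 0.446...
        ],
    )
    def test_matches_printed_precision(self, count, total, decimals, expected):
        assert plate_io.format_percent(count, total, decimals) == expected

    def test_always_equals_rounded_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = int(rng.integers(0, 2000))
            t = int(rng.integers(1, 2000))
            for d in (1, 2):
                s = plate_io.format_percent(c, t, d)
                assert float(s.rstrip("%")) == round(100.0 * c / t, d)


class TestScreenReport:
    def _results(self):
        from fretscreen.screen_pipeline import ScreenResult

        return [
            ScreenResult("C1", 25.0, 24.0, is_hit=True),
            ScreenResult("C2", 80.0, 10.0, flags={"strong_autofluorescence"},
                         excluded_by="fluorescence"),
            ScreenResult("C3", 5.0, 6.0),
        ]

    def test_report_counts_and_rows(self, tmp_path):
        path = tmp_path / "screen.csv"
        plate_io.write_screen_report(self._results(), path)
        df = pd.read_csv(path)
        assert len(df) == 3
        assert df.is_hit.sum() == 1
        assert (df.excluded_by.fillna("") != "").sum() == 1
        import json

        summary = json.loads(path.with_suffix(".summary.json").read_text())["summary"]
        assert summary["n_excluded_total"] == 1
        assert summary["n_hits"] == 1

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            plate_io.write_screen_report([], tmp_path / "screen.csv")
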