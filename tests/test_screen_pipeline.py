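"""Interference-filter cascade, hit calling and exclusion accounting."""

import pytest

from fretscreen import screen_pipeline as sp
from fretscreen import synthetic_data as sd
from fretscreen.errors import ConfigurationError, ReconciliationError, ValidationError


def preread(f477, f527, bg=100.0):
    return sp.CompoundPreRead("C", fluor_477=f477, fluor_527=f527,
                              background_477=bg, background_527=bg)


class TestAutofluorescenceFilter:
    def test_above_fold_threshold_excluded(self):
        assert sp.filter_autofluorescence(preread(600.0, 0.0))

    def test_exactly_fivefold_is_kept(self):
        # "more than 5 times" is a strict inequality
        assert not sp.filter_autofluorescence(preread(500.0, 500.0))

    def test_dark_compound_kept(self):
        assert not sp.filter_autofluorescence(preread(0.0, 0.0))

    def test_zero_background_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            sp.filter_autofluorescence(preread(10.0, 10.0, bg=0.0))

    def test_monotone_in_threshold(self):
        p = preread(450.0, 0.0)
        assert sp.filter_autofluorescence(p, fold_threshold=4)
        assert not sp.filter_autofluorescence(p, fold_threshold=5)


class TestFretDeviationFilter:
    @pytest.mark.parametrize(
        "s477,s527,excluded",
        [
            (140.0, 100.0, True),   # +40% at 477
            (110.0, 95.0, False),   # within +/-10%
            (100.0, 60.0, True),    # -40% at 527
            (130.0, 130.0, False),  # exactly 30% is kept (strict >)
        ],
    )
    def test_band(self, s477, s527, excluded):
        assert sp.filter_fret_deviation(s477, s527, 100.0, 100.0) is excluded

    def test_zero_control_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            sp.filter_fret_deviation(1.0, 1.0, 0.0, 100.0)


class TestDualExcitationFilter:
    @pytest.mark.parametrize(
        "i410,i430,excluded",
        [(35.0, 12.0, True), (25.0, 25.0, False), (25.0, 15.000001, False),
         (25.0, 14.999, True), (-5.0, 8.0, True)],
    )
    def test_difference_threshold(self, i410, i430, excluded):
        assert sp.filter_dual_excitation(i410, i430) is excluded


class TestPanAssayFilter:
    def test_reduction_in_both_assays(self):
        assert sp.filter_pan_assay(40.0, 45.0) == (True, True)

    def test_one_sided_reduction_kept(self):
        assert sp.filter_pan_assay(40.0, 5.0) == (False, True)

    def test_missing_other_assay_not_evaluable(self):
        assert sp.filter_pan_assay(40.0, None) == (False, False)


class TestHitCalling:
    def test_threshold_is_inclusive(self):
        r = [sp.ScreenResult("C1", 20.0, 20.0), sp.ScreenResult("C2", 19.9, 19.9)]
        sp.call_hits(r)
        assert r[0].is_hit and not r[1].is_hit

    def test_excluded_compounds_cannot_be_hits(self):
        r = [sp.ScreenResult("C1", 80.0, 20.0, flags={sp.FLAG_DUAL},
                             excluded_by=sp.STAGE_DUAL)]
        sp.call_hits(r)
        assert not r[0].is_hit


class TestSummaryAccounting:
    def test_counts_partition_and_formatting(self):
        s = sp.ScreenSummary.from_counts(1120, 89, 12, 29, 6)
        assert s.n_excluded_total == 130
        assert s.pct_excluded_total == "11.6%"
        assert s.pct_hits == "0.54%"

    def test_more_hits_than_survivors_rejected(self):
        with pytest.raises(ValidationError):
            sp.ScreenSummary.from_counts(10, 4, 3, 3, 1)


SMALL_COMPOSITION = (
    ("inactive", "", 60),
    ("true_inhibitor_A", "", 4),
    ("true_inhibitor_B", "", 3),
    ("blue_fluor", "strong", 2),
    ("blue_fluor", "moderate", 2),
    ("green_fluor", "strong", 2),
    ("green_fluor", "moderate", 2),
    ("excitation_shifted_fluor", "", 3),
    ("dual_quencher", "gray", 2),
    ("dual_quencher", "chromatic", 2),
)


@pytest.fixture(scope="module")
def small_screen():
    lib = sd.make_library(SMALL_COMPOSITION, seed=5)
    sim = sd.simulate_screen(
        sd.ASSAY_A_CONFIG.without_noise(), sd.ASSAY_B_CONFIG.without_noise(),
        library=lib, seed=5,
    )
    return sim


class TestRunScreen:
    def test_zero_noise_matches_truth_table(self, small_screen):
        sim = small_screen
        sa, sb, res = sp.run_screen(
            sp.AssayData(sim.pre_a, sim.assay_a), sp.AssayData(sim.pre_b, sim.assay_b)
        )
        for key in ("A", "B"):
            r = res[key]
            for row in sim.truth.itertuples():
                obs = r[row.compound_id]
                assert obs.excluded_by == getattr(row, f"expected_stage_{key}"), (
                    row.compound_id, row.compound_class, row.variant)
                assert obs.is_hit == getattr(row, f"expected_hit_{key}")

    def test_exclusions_partition_and_disjoint_from_hits(self, small_screen):
        sim = small_screen
        sa, sb, res = sp.run_screen(
            sp.AssayData(sim.pre_a, sim.assay_a), sp.AssayData(sim.pre_b, sim.assay_b)
        )
        for summary, r in ((sa, res["A"]), (sb, res["B"])):
            n_stage = sum(1 for x in r.values() if x.excluded_by is not None)
            assert summary.n_excluded_total == n_stage
            assert (summary.n_excluded_fluor + summary.n_excluded_dual
                    + summary.n_excluded_pan) == summary.n_excluded_total
            assert not any(x.is_hit and x.excluded_by for x in r.values())

    def test_raising_thresholds_weakly_decreases_exclusions(self, small_screen):
        sim = small_screen
        data = (sp.AssayData(sim.pre_a, sim.assay_a), sp.AssayData(sim.pre_b, sim.assay_b))
        base = sp.run_screen(*data, config=sp.ScreenConfig())[0]
        looser = sp.run_screen(
            *data,
            config=sp.ScreenConfig(autofluorescence_fold=50.0,
                                   deviation_fraction=3.0,
                                   dual_excitation_diff=1000.0),
        )[0]
        assert looser.n_excluded_fluor <= base.n_excluded_fluor
        assert looser.n_excluded_dual <= base.n_excluded_dual
        assert looser.n_excluded_fluor == 0 and looser.n_excluded_dual == 0

    def test_library_mismatch_detected(self, small_screen):
        sim = small_screen
        other = sd.simulate_screen(
            sd.ASSAY_B_CONFIG.without_noise(), sd.ASSAY_B_CONFIG.without_noise(),
            library=sd.make_library(SMALL_COMPOSITION[:1], seed=5), seed=5,
        )
        with pytest.raises(ReconciliationError):
            sp.run_screen(
                sp.AssayData(sim.pre_a, sim.assay_a),
                sp.AssayData(other.pre_b, other.assay_b),
            )

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.simulate_screen(library=[], seed=1)
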