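"""FRET mathematics: rFRET, EmFRET unmixing, binding isotherm and Kd fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import brute_force_bound
from fretscreen import fret_model as fm
from fretscreen import synthetic_data as sd
from fretscreen.errors import (
    CalibrationError,
    FitError,
    UndefinedRatioError,
    ValidationError,
)
from fretscreen.plate_io import Channel, WellRecord


def _well(reads):
    return WellRecord("A1", "sample", donor_conc=1e-7, acceptor_conc=2e-7,
                      reads={Channel(*k): v for k, v in reads.items()})


class TestRatiometricFRET:
    def test_ratio(self):
        w = _well({(410, 477): 1.0, (410, 527): 2.0})
        assert fm.compute_rfret(w).rfret == pytest.approx(2.0)

    def test_zero_donor_is_undefined(self):
        w = _well({(410, 477): 0.0, (410, 527): 1.0})
        with pytest.raises(UndefinedRatioError):
            fm.compute_rfret(w)

    def test_alternative_excitation(self):
        w = _well({(430, 477): 4.0, (430, 527): 2.0})
        assert fm.compute_rfret(w, excitation_nm=430).rfret == pytest.approx(0.5)

    def test_bound_pair_exceeds_unbound_control(self):
        # forward simulation: interacting pair vs donor + free acceptor
        cfg = sd.ASSAY_A_CONFIG.without_noise()
        bound = {
            ch: sd.noiseless_intensity(cfg, ch) for ch in sd.RFRET_CHANNELS
        }
        unbound = {
            ch: sd.noiseless_intensity(cfg, ch, binding_enabled=False)
            for ch in sd.RFRET_CHANNELS
        }
        r_bound = bound[Channel(410, 527)] / bound[Channel(410, 477)]
        r_unbound = unbound[Channel(410, 527)] / unbound[Channel(410, 477)]
        assert r_bound > r_unbound


class TestBleedthrough:
    def test_alpha_beta_from_calibration_wells(self):
        donor_only = [_well({(430, 477): 100.0, (430, 527): 10.0})]
        acceptor_only = [_well({(477, 527): 50.0, (430, 527): 5.0})]
        c = fm.calibrate_bleedthrough(donor_only, acceptor_only)
        assert c.alpha == pytest.approx(0.10)
        assert c.beta == pytest.approx(0.10)

    def test_zero_denominator_is_calibration_error(self):
        donor_only = [_well({(430, 477): 0.0, (430, 527): 10.0})]
        acceptor_only = [_well({(477, 527): 50.0, (430, 527): 5.0})]
        with pytest.raises(CalibrationError):
            fm.calibrate_bleedthrough(donor_only, acceptor_only)

    def test_emfret_arithmetic(self):
        w = _well({(430, 527): 100.0, (430, 477): 200.0, (477, 527): 300.0})
        c = fm.BleedthroughCoefficients(alpha=0.1, beta=0.1)
        assert fm.compute_emfret(w, c) == pytest.approx(50.0)

    def test_single_fluorophore_wells_correct_to_zero(self):
        # a donor-only well corrected with its own calibration has EmFRET 0
        donor_only = [_well({(430, 477): 80.0, (430, 527): 20.0, (477, 527): 0.0})]
        acceptor_only = [_well({(477, 527): 400.0, (430, 527): 32.0, (430, 477): 0.0})]
        c = fm.calibrate_bleedthrough(donor_only, acceptor_only)
        assert fm.compute_emfret(donor_only[0], c) == pytest.approx(0.0, abs=1e-9)
        assert fm.compute_emfret(acceptor_only[0], c) == pytest.approx(0.0, abs=1e-9)


class TestBoundComplex:
    def test_zero_kd_limit(self):
        assert fm.bound_complex(100e-9, 100e-9, 0.0) == pytest.approx(100e-9)

    def test_no_acceptor(self):
        assert fm.bound_complex(100e-9, 0.0, 1e-7) == 0.0

    def test_worked_example_by_back_substitution(self):
        da = fm.bound_complex(100e-9, 200e-9, 100e-9)
        assert da == pytest.approx(58.5786e-9, rel=1e-4)
        kd_back = (100e-9 - da) * (200e-9 - da) / da
        assert kd_back == pytest.approx(100e-9, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fm.bound_complex(-1e-9, 1e-9, 1e-9)

    @given(
        st.floats(1e-12, 1e-4), st.floats(1e-12, 1e-4), st.floats(1e-12, 1e-2)
    )
    def test_agrees_with_brute_force(self, d, a, kd):
        da = fm.bound_complex(d, a, kd)
        ref = brute_force_bound(d, a, kd)
        assert da == pytest.approx(ref, rel=1e-10, abs=1e-30)

    def test_brute_force_agreement_on_random_grid(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            d, a = 10.0 ** rng.uniform(-12, -4, size=2)
            kd = 10.0 ** rng.uniform(-12, -2)
            assert fm.bound_complex(d, a, kd) == pytest.approx(
                brute_force_bound(d, a, kd), rel=1e-10
            )

    def test_monotonicity_and_limits(self):
        a = np.geomspace(1e-10, 1e-4, 50)
        da = fm.bound_complex(1e-7, a, 1e-7)
        assert np.all(np.diff(da) > 0)  # increasing in acceptor
        assert da[-1] == pytest.approx(1e-7, rel=1e-3)  # saturation at donor
        kd = np.geomspace(1e-10, 1e-4, 50)
        da_k = fm.bound_complex(1e-7, 2e-7, kd)
        assert np.all(np.diff(da_k) < 0)  # decreasing in Kd

    def test_dilute_limit(self):
        d, a, kd = 1e-12, 1e-12, 1e-6  # D*A << Kd^2
        da = fm.bound_complex(d, a, kd)
        assert da == pytest.approx(d * a / kd, rel=1e-2)


def _clean_series(kd, donor=100e-9, replicates=1):
    cfg = sd.SimConfig(kd_pair=kd, donor_total=donor, acceptor_total=2 * donor,
                       transfer_efficiency=0.35).without_noise()
    series, truth = sd.simulate_titration_series(cfg, replicates=replicates, seed=1)
    return series, truth


class TestFitKd:
    @pytest.mark.parametrize("kd", [1e-9, 8.2e-9, 35e-9, 230e-9, 970e-9, 2.6e-6, 1e-5])
    def test_noise_free_exact_recovery(self, kd):
        series, truth = _clean_series(kd)
        fit = fm.fit_kd(series)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.emfret_max == pytest.approx(truth["emfret_max"], rel=1e-6)

    def test_noise_free_ci_collapses_to_point(self):
        series, _ = _clean_series(35e-9)
        fit = fm.fit_kd(series)
        lo, hi = fit.kd_ci_95
        assert lo <= fit.kd <= hi
        assert hi / lo - 1 < 1e-2

    def test_all_zero_emfret_is_fit_error(self):
        series, _ = _clean_series(35e-9)
        series.emfret = np.zeros_like(series.emfret)
        with pytest.raises(FitError):
            fm.fit_kd(series)

    def test_decreasing_emfret_flagged_unreliable(self):
        series, _ = _clean_series(35e-9)
        series.emfret = series.emfret[::-1].copy()
        with pytest.warns(UserWarning, match="decreases"):
            fit = fm.fit_kd(series)
        assert fit.ci_unreliable

    def test_too_few_concentrations_rejected(self):
        cfg = sd.SimConfig(kd_pair=35e-9).without_noise()
        series, _ = sd.simulate_titration_series(
            cfg, acceptor_ladder=[0, 1e-7, 2e-7, 3e-7, 4e-7], replicates=1, seed=0
        )
        with pytest.raises(ValidationError):
            fm.fit_kd(series)

    def test_noisy_recovery_within_20pct_most_of_the_time(self):
        # 2% multiplicative noise, 4 replicates, Kd = 230 nM
        cfg = sd.SimConfig(kd_pair=230e-9, donor_total=150e-9, acceptor_total=300e-9,
                           transfer_efficiency=0.45)
        hits = 0
        n = 200
        for i in range(n):
            series, _ = sd.simulate_titration_series(cfg, replicates=4, seed=3000 + i)
            fit = fm.fit_kd(series)
            hits += abs(fit.kd - 230e-9) / 230e-9 <= 0.20
        assert hits / n >= 0.95

    def test_weak_binder_has_open_or_wide_upper_bound(self):
        # Kd far beyond the acceptor ladder: the curve never saturates
        cfg = sd.SimConfig(kd_pair=5e-5, donor_total=100e-9, acceptor_total=200e-9)
        series, _ = sd.simulate_titration_series(cfg, replicates=4, seed=11)
        fit = fm.fit_kd(series)
        assert fit.ci_upper_open or fit.kd_ci_95[1] / fit.kd > 10


class TestProfileLikelihood:
    def test_level_validated(self):
        series, _ = _clean_series(35e-9)
        fit = fm.fit_kd(series)
        with pytest.raises(ValidationError):
            fm.profile_likelihood_ci(series, fit, level=1.5)

    def test_interval_widens_with_level(self):
        cfg = sd.SimConfig(kd_pair=300e-9, donor_total=250e-9, acceptor_total=500e-9)
        series, _ = sd.simulate_titration_series(cfg, replicates=4, seed=5)
        fit = fm.fit_kd(series)
        ci90 = fm.profile_likelihood_ci(series, fit, level=0.90)
        ci99 = fm.profile_likelihood_ci(series, fit, level=0.99)
        assert ci99.lower <= ci90.lower
        assert ci99.upper >= ci90.upper
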