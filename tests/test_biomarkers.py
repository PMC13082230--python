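"""Band fitting, shift quantification, labeling-fraction estimators, and
the sorting criterion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sipraman as sr
from sipraman.simulate import _cell_rng, pseudo_voigt

from conftest import make_spectrum

FULL_LABEL_DELTAS = {  # c12 − c13 from the reference positions
    "pyrrole_breathing": 22.0,
    "nu_CN": 10.0,
    "delta_CH": 12.0,
    "nu_CC": 48.0,
    "phe_ring": 37.0,
}


def lorentzian(x, center, fwhm, amp=1.0):
    return amp / (1.0 + ((x - center) / (fwhm / 2)) ** 2)


class TestFitBand:
    def test_noiseless_lorentzian_recovered(self, reference_table):
        band = reference_table["pyrrole_breathing"]
        x = np.arange(700.0, 800.0)
        fit = sr.fit_band(make_spectrum(x, lorentzian(x, 747.0, 12.0)), band)
        assert fit.success
        assert fit.center == pytest.approx(747.0, abs=0.5)
        assert fit.fwhm > 0

    def test_flat_zero_signal_fails(self, reference_table):
        band = reference_table["pyrrole_breathing"]
        x = np.arange(700.0, 800.0)
        fit = sr.fit_band(make_spectrum(x, np.zeros_like(x)), band)
        assert not fit.success

    def test_two_population_window_flags_bimodal(self, reference_table):
        """Two equal Lorentzians at 1002 and 965 cm⁻¹: flagged bimodal,
        center at a smoothed apex — cross-checked against brute-force local
        maxima of the summed profile on a 0.1 cm⁻¹ grid."""
        band = reference_table["phe_ring"]
        x = np.arange(930.0, 1030.0)
        y = lorentzian(x, 1002.0, 12.0) + lorentzian(x, 965.0, 12.0)
        fit = sr.fit_band(make_spectrum(x, y), band)
        assert fit.success
        assert fit.bimodal_flag
        # independent oracle: fine-grid local maxima of the generative model
        xf = np.arange(930.0, 1030.0, 0.1)
        yf = lorentzian(xf, 1002.0, 12.0) + lorentzian(xf, 965.0, 12.0)
        interior = (np.diff(np.sign(np.diff(yf))) < 0).nonzero()[0] + 1
        apexes = xf[interior]
        assert np.min(np.abs(apexes - fit.center)) < 0.5

    def test_window_outside_axis_is_range_error(self, reference_table):
        band = reference_table["nu_CC"]  # window around 1526-1594
        x = np.arange(700.0, 800.0)
        with pytest.raises(sr.RangeError):
            sr.fit_band(make_spectrum(x, np.ones_like(x)), band)

    def test_noise_only_window_fails(self, reference_table, rng):
        band = reference_table["pyrrole_breathing"]
        x = np.arange(700.0, 800.0)
        fit = sr.fit_band(make_spectrum(x, rng.normal(0, 1.0, len(x))), band)
        assert not fit.success


class TestPositionFraction:
    def _fit(self, center):
        return sr.BandFit(band_name="phe_ring", center=center, success=True)

    def test_endpoints(self, reference_table):
        phe = reference_table["phe_ring"]
        assert sr.estimate_label_fraction_position(self._fit(1002.0), phe) == 0.0
        assert sr.estimate_label_fraction_position(self._fit(965.0), phe) == 1.0

    def test_tx1_partial_fraction(self):
        # observed TX1 phenylalanine position 985 cm⁻¹ read against the true
        # endmembers (1003, 965): f = (1003−985)/(1003−965) = 0.474
        phe = sr.BandDefinition(name="phe_ring", mode_label="ring breathing",
                                c12=1003.0, c13=965.0, role="phenylalanine")
        f = sr.estimate_label_fraction_position(self._fit(985.0), phe)
        assert f == pytest.approx(0.474, abs=0.001)

    def test_failed_fit_is_undefined(self, reference_table):
        with pytest.raises(sr.UndefinedInputError):
            sr.estimate_label_fraction_position(
                sr.BandFit(band_name="phe_ring", success=False),
                reference_table["phe_ring"],
            )

    @given(center=st.floats(900.0, 1100.0))
    def test_monotone_and_clamped(self, center):
        phe = sr.load_band_table("reference_strains")["phe_ring"]
        f = sr.estimate_label_fraction_position(self._fit(center), phe)
        assert 0.0 <= f <= 1.0
        f_right = sr.estimate_label_fraction_position(self._fit(center + 1.0), phe)
        assert f_right <= f  # f is non-increasing in the fitted center


@pytest.fixture(scope="module")
def setup(reference_table, noiseless_config):
    e12 = sr.endmember_spectrum(reference_table, "12C", noiseless_config)
    e13 = sr.endmember_spectrum(reference_table, "13C", noiseless_config)
    return reference_table, e12, e13


@pytest.fixture(scope="module")
def labeled_profile(reference_table, noiseless_config):
    sset, _ = sr.simulate_cohort(
        sr.SimConfig(**{**noiseless_config.__dict__, "n_cells": 1,
                        "label_fraction": 1.0})
    )
    prepped = sr.preprocess_spectrum(sset.spectra[0])
    return sr.compute_shift_profile(prepped, reference_table)


class TestDecompositionFraction:
    @pytest.mark.parametrize("w13,expect,tol", [(0.0, 0.0, 0.01), (1.0, 1.0, 0.01),
                                                (0.3, 0.3, 0.02)])
    def test_recovers_mixture_weight(self, setup, w13, expect, tol):
        table, e12, e13 = setup
        mix = e12.with_intensities((1 - w13) * e12.intensities + w13 * e13.intensities)
        fd = sr.estimate_label_fraction_decomposition(mix, table, (e12, e13))
        for band in table:
            assert fd[band.name] == pytest.approx(expect, abs=tol)

    def test_axis_mismatch_rejected(self, setup):
        table, e12, e13 = setup
        shifted = make_spectrum(e12.axis + 0.5, e12.intensities)
        with pytest.raises(sr.AxisError):
            sr.estimate_label_fraction_decomposition(shifted, table, (e12, e13))

    def test_empty_window_flagged_nan(self, setup, reference_table):
        table, e12, e13 = setup
        flat = e12.with_intensities(np.zeros_like(e12.intensities))
        fd = sr.estimate_label_fraction_decomposition(flat, table, (e12, e13))
        assert all(np.isnan(v) for v in fd.values())


class TestShiftProfile:
    def test_fully_labeled_deltas(self, labeled_profile):
        for name, expect in FULL_LABEL_DELTAS.items():
            assert labeled_profile.delta[name] == pytest.approx(expect, abs=1.0)

    def test_unlabeled_deltas_near_zero(self, reference_table, noiseless_config):
        sset, _ = sr.simulate_cohort(
            sr.SimConfig(**{**noiseless_config.__dict__, "n_cells": 1,
                            "label_fraction": 0.0, "active_fraction": 0.0})
        )
        profile = sr.compute_shift_profile(
            sr.preprocess_spectrum(sset.spectra[0]), reference_table
        )
        assert all(abs(d) < 1.0 for d in profile.delta.values())

    def test_missing_phe_window_recorded_not_dropped(self, reference_table, noiseless_config):
        sset, _ = sr.simulate_cohort(
            sr.SimConfig(**{**noiseless_config.__dict__, "n_cells": 1})
        )
        prepped = sr.preprocess_spectrum(sset.spectra[0])
        cropped = sr.crop_fingerprint(prepped, 1050.0, 1800.0)  # excludes phe window
        profile = sr.compute_shift_profile(cropped, reference_table)
        assert not profile.fits["phe_ring"].success
        for name in ("nu_CN", "delta_CH", "nu_CC"):
            assert name in profile.delta

    def test_noiseless_fraction_recovery_per_band(self, reference_table, noiseless_config):
        """f̂_position matches the generative f within ±0.02 on every band."""
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            spectrum, _ = sr.simulate_spectrum(noiseless_config, f, _cell_rng(0, 0))
            profile = sr.compute_shift_profile(
                sr.preprocess_spectrum(spectrum), reference_table
            )
            for band in reference_table:
                assert profile.f_position[band.name] == pytest.approx(f, abs=0.02)


class TestClassification:
    def _profile(self, reference_table, deltas):
        profile = sr.CellShiftProfile(cell_id="c", table=reference_table)
        for band in reference_table:
            d = deltas.get(band.name)
            success = d is not None
            profile.fits[band.name] = sr.BandFit(
                band_name=band.name,
                center=band.c12 - d if success else np.nan,
                success=success,
            )
            if success:
                profile.delta[band.name] = d
        return profile

    def test_fully_labeled_cell_is_active(self, reference_table):
        cls = sr.classify_cell(self._profile(reference_table, FULL_LABEL_DELTAS))
        assert cls.is_active
        assert cls.n_cytc_shifted == 4 and cls.phe_shifted

    def test_unshifted_cell_is_inactive(self, reference_table):
        deltas = {k: 0.0 for k in FULL_LABEL_DELTAS}
        cls = sr.classify_cell(self._profile(reference_table, deltas))
        assert not cls.is_active
        assert cls.n_cytc_shifted == 0

    def test_three_of_four_cytc_is_inactive(self, reference_table):
        deltas = dict(FULL_LABEL_DELTAS, nu_CN=0.0)
        cls = sr.classify_cell(self._profile(reference_table, deltas))
        assert not cls.is_active
        assert cls.n_cytc_shifted == 3 and cls.phe_shifted

    def test_failed_fit_counts_as_not_shifted(self, reference_table):
        deltas = dict(FULL_LABEL_DELTAS)
        deltas["phe_ring"] = None  # fit failure
        cls = sr.classify_cell(self._profile(reference_table, deltas))
        assert not cls.is_active
        assert cls.n_cytc_shifted == 4 and not cls.phe_shifted

    def test_quartet_only_rule(self, reference_table):
        deltas = dict(FULL_LABEL_DELTAS)
        deltas["phe_ring"] = None
        cls = sr.classify_cell(self._profile(reference_table, deltas), require_phe=False)
        assert cls.is_active
        assert cls.rule == "cytc4"

    def test_incomplete_table_is_configuration_error(self, reference_table):
        table = sr.BandTable(
            table_id="partial",
            bands=[b for b in reference_table if b.name != "nu_CC"],
        )
        profile = sr.CellShiftProfile(cell_id="c", table=table)
        with pytest.raises(sr.ConfigurationError):
            sr.classify_cell(profile)

    def test_delta_min_bounds_printed_shifts(self, reference_table):
        # every reported biomarker shift exceeds the default threshold;
        # sub-resolution jitter (< 3 cm-1) never counts as shifted
        for table_id in ("reference_strains", "sediment_enrichment", "strain_TX1"):
            for band in sr.load_band_table(table_id):
                assert band.span >= 5.0
        deltas = {k: 2.9 for k in FULL_LABEL_DELTAS}
        assert not sr.classify_cell(self._profile(reference_table, deltas)).is_active

    def test_invariant_to_global_intensity_scaling(self, reference_table):
        cfg = sr.SimConfig(band_table=reference_table, n_cells=1, snr=30.0, seed=5)
        sset, _ = sr.simulate_cohort(cfg)
        s = sset.spectra[0]
        scaled = s.with_intensities(s.intensities * 10.0)
        cls1 = sr.classify_cell(
            sr.compute_shift_profile(sr.preprocess_spectrum(s), reference_table)
        )
        cls2 = sr.classify_cell(
            sr.compute_shift_profile(sr.preprocess_spectrum(scaled), reference_table)
        )
        assert cls1 == cls2


class TestCohortSummary:
    def _run(self, cfg, table):
        sset, truth = sr.simulate_cohort(cfg)
        profiles, classifications = [], []
        for s in sset:
            profile = sr.compute_shift_profile(sr.preprocess_spectrum(s), table)
            profiles.append(profile)
            classifications.append(sr.classify_cell(profile))
        return classifications, profiles, truth

    def test_all_active_cohort(self, reference_table):
        cfg = sr.SimConfig(band_table=reference_table, n_cells=10, snr=30.0,
                           label_fraction=1.0, active_fraction=1.0, seed=8)
        classifications, profiles, _ = self._run(cfg, reference_table)
        report = sr.summarize_cohort(classifications, profiles, set_id="all_active")
        assert report.n_active == 10
        assert len(report.sort_candidates) == 10

    def test_all_inactive_cohort_has_empty_sort_list(self, reference_table):
        cfg = sr.SimConfig(band_table=reference_table, n_cells=5, snr=30.0,
                           active_fraction=0.0, seed=9)
        classifications, profiles, _ = self._run(cfg, reference_table)
        report = sr.summarize_cohort(classifications, profiles)
        assert report.n_active == 0
        assert report.sort_candidates == []

    def test_empty_input_rejected(self):
        with pytest.raises(sr.ParameterError):
            sr.summarize_cohort([], [])

    def test_sort_candidates_ranked_by_mean_cytc_delta(self, reference_table):
        cfg = sr.SimConfig(band_table=reference_table, n_cells=6, snr=30.0,
                           label_fraction=1.0, active_fraction=1.0, seed=10)
        classifications, profiles, _ = self._run(cfg, reference_table)
        report = sr.summarize_cohort(classifications, profiles)
        by_id = {p.cell_id: p.mean_cytc_delta() for p in profiles}
        ranked = [by_id[c] for c in report.sort_candidates]
        assert ranked == sorted(ranked, reverse=True)
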