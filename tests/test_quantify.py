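"""EIC extraction/integration, recovery, CV, and summaries."""

import numpy as np
import pytest

from arpmap.chemdb import mz_from_mass
from arpmap.quantify import (
    ChromatographicFeature,
    RecoveryRecord,
    averagine_envelope,
    cv,
    enrichment_summary,
    extract_eic,
    integrate,
    ion_mobility_filter,
    recovery_percent,
    upscale_compare,
)
from arpmap.spectra_io import Spectrum

# the study loads: 11 µg enriched-fraction equivalent vs 70 ng control
LOAD_ENR, LOAD_NON = 11.0, 0.07


def _ms1_run(neutral_mass=1258.616, charge=2, height=1000.0, apex=5.0, sigma=0.1,
             baseline=0.0, rt_max=10.0, dt=0.05):
    """Synthetic MS1 run with one Gaussian elution peak (3 isotopes)."""
    env = averagine_envelope(neutral_mass)
    spectra = []
    for i, rt in enumerate(np.arange(0, rt_max, dt)):
        h = height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
        mzs, ints = [], []
        for k, w in enumerate(env):
            mzs.append(mz_from_mass(neutral_mass + k * 1.00335483, charge))
            ints.append(h * w + baseline)
        spectra.append(
            Spectrum(run_id="r", scan_id=f"{i}", ms_level=1, retention_time=float(rt),
                     mz=np.array(mzs), intensity=np.array(ints))
        )
    return spectra


class TestExtractEic:
    def test_apex_recovered(self):
        run = _ms1_run(apex=5.0)
        rts, trace = extract_eic(run, 1258.616, 2)
        assert rts[np.argmax(trace)] == pytest.approx(5.0, abs=0.05)

    def test_linearity(self):
        run = _ms1_run(height=1000.0)
        run2 = [
            Spectrum(run_id="r", scan_id=s.scan_id, ms_level=1,
                     retention_time=s.retention_time, mz=s.mz, intensity=2 * s.intensity)
            for s in run
        ]
        _, t1 = extract_eic(run, 1258.616, 2)
        _, t2 = extract_eic(run2, 1258.616, 2)
        np.testing.assert_allclose(t2, 2 * t1)

    def test_infinite_resolving_power_empties_off_grid_trace(self):
        run = _ms1_run()
        _, trace = extract_eic(run, 1258.616 + 0.05, 2, resolving_power=1e12)
        assert trace.sum() == 0.0


class TestRobustEic:
    def test_interfered_isotopes_dropped(self):
        """A coeluting species that contaminates the 2nd/3rd isotope windows
        must not inflate the integrated area."""
        from arpmap.quantify import extract_eic_robust

        mass, charge, height, sigma = 1530.6885, 2, 1000.0, 0.1
        run = _ms1_run(neutral_mass=mass, charge=charge, height=height, sigma=sigma)
        # add an interferer 0.02 m/z above isotopes 1 and 2, eluting nearby
        interferer_mass = mass + 2 * 1.00335483 * 0.0 + 0.04 * charge  # +0.04 m/z
        for s in run:
            h = 5000.0 * np.exp(-0.5 * ((s.retention_time - 5.3) / sigma) ** 2)
            if h < 1e-3:
                continue
            extra_mz = np.array([
                (mass + k * 1.00335483) / charge + 1.00727646677 + 0.02
                for k in (1, 2)
            ])
            s.mz = np.concatenate([s.mz, extra_mz])
            s.intensity = np.concatenate([s.intensity, [h, h / 2]])
            s.__post_init__()
        truth = height * sigma * np.sqrt(2 * np.pi)
        rts, plain = extract_eic(run, mass, charge)
        plain_area, _, _ = integrate(rts, plain, (4.5, 5.5))
        rts, robust = extract_eic_robust(run, mass, charge)
        robust_area, _, _ = integrate(rts, robust, (4.5, 5.5))
        assert plain_area > 1.5 * truth  # contaminated
        assert robust_area == pytest.approx(truth, rel=0.10)

    def test_matches_plain_extraction_when_clean(self):
        from arpmap.quantify import extract_eic_robust

        run = _ms1_run()
        rts, plain = extract_eic(run, 1258.616, 2)
        _, robust = extract_eic_robust(run, 1258.616, 2)
        np.testing.assert_allclose(robust, plain, rtol=1e-9)


class TestRefineWindow:
    @staticmethod
    def _two_peaks(apex_a=5.0, apex_b=5.5, h_a=1000.0, h_b=5000.0, sigma=0.1):
        rts = np.arange(4.0, 7.0, 0.05)
        y = h_a * np.exp(-0.5 * ((rts - apex_a) / sigma) ** 2)
        y += h_b * np.exp(-0.5 * ((rts - apex_b) / sigma) ** 2)
        return rts, y

    def test_isolated_peak_keeps_full_window(self):
        from arpmap.quantify import refine_rt_window

        rts, y = self._two_peaks(h_b=0.0)
        lo, hi = refine_rt_window(rts, y, (4.7, 5.3), apex_hint=5.0)
        assert lo == pytest.approx(4.7, abs=0.06)
        assert hi == pytest.approx(5.3, abs=0.06)

    def test_coeluting_peak_clipped_at_valley(self):
        from arpmap.quantify import refine_rt_window

        rts, y = self._two_peaks()
        lo, hi = refine_rt_window(rts, y, (4.7, 5.3), apex_hint=5.0)
        assert lo == pytest.approx(4.7, abs=0.06)
        assert 5.1 <= hi < 5.3  # clipped before the neighbouring peak

    def test_apex_hint_resists_stronger_neighbour(self):
        from arpmap.quantify import refine_rt_window, integrate

        rts, y = self._two_peaks(apex_b=5.6)
        window = refine_rt_window(rts, y, (4.7, 5.3), apex_hint=5.0)
        area, _, _ = integrate(rts, y, window)
        truth = 1000.0 * 0.1 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(truth, rel=0.15)


class TestIntegrate:
    def test_rectangular_peak_closed_form(self):
        rts = np.arange(0.0, 10.0, 0.05)
        y = np.where((rts >= 4.0) & (rts <= 6.0), 100.0, 0.0)
        area, background, ratio = integrate(rts, y, (3.0, 7.0))
        assert area == pytest.approx(200.0, rel=0.05)  # h*w = 100*2
        assert background == pytest.approx(0.0, abs=1e-9)
        assert ratio == float("inf")

    def test_flat_baseline_gives_zero_area(self):
        rts = np.arange(0.0, 10.0, 0.05)
        y = np.full_like(rts, 40.0)
        area, background, ratio = integrate(rts, y, (3.0, 7.0))
        assert area == pytest.approx(0.0, abs=1e-9)
        assert background == pytest.approx(160.0, rel=0.01)
        assert ratio == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_peak_area_matches_truth(self):
        height, sigma = 1000.0, 0.1
        run = _ms1_run(height=height, sigma=sigma)
        rts, trace = extract_eic(run, 1258.616, 2)
        area, _, _ = integrate(rts, trace, (4.5, 5.5))
        assert area == pytest.approx(height * sigma * np.sqrt(2 * np.pi), rel=0.05)

    def test_empty_window(self):
        rts = np.arange(0.0, 1.0, 0.1)
        assert integrate(rts, rts * 0, (5.0, 6.0)) == (0.0, 0.0, 0.0)


class TestRecovery:
    def test_equal_areas_equal_loads(self):
        assert recovery_percent(10.0, 10.0, 1.0, 1.0) == pytest.approx(100.0)

    def test_lossless_enrichment_identity_under_study_loads(self):
        # lossless: area ratio equals the load ratio 11 µg / 70 ng = 157.14
        assert recovery_percent(157.14, 1.0, LOAD_ENR, LOAD_NON) == pytest.approx(
            100.0, abs=0.1
        )

    def test_partial_recovery(self):
        assert recovery_percent(9.43, 1.0, LOAD_ENR, LOAD_NON) == pytest.approx(
            6.0, abs=0.01
        )

    def test_zero_non_enriched_area_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent(1.0, 0.0, LOAD_ENR, LOAD_NON)


class TestCv:
    def test_identical_replicates(self):
        assert cv([1.0, 1.0, 1.0]) == 0.0

    def test_closed_form(self):
        assert cv([8.0, 10.0, 12.0]) == pytest.approx(20.0, abs=1e-9)

    def test_scale_invariance(self):
        base = [8.0, 10.0, 12.0]
        assert cv([7.0 * x for x in base]) == pytest.approx(cv(base), abs=1e-9)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            cv([5.0])


def _record(pid, recovery, is_arp):
    return RecoveryRecord(
        peptidoform_id=pid, area_enriched=1.0, area_non_enriched=1.0,
        load_enriched=LOAD_ENR, load_non_enriched=LOAD_NON,
        recovery_percent=recovery, quantifiable_pre_enrichment=True, is_arp=is_arp,
    )


class TestEnrichmentSummary:
    def test_median_ratio(self):
        records = [_record(f"a{i}", 100.0, True) for i in range(3)] + [
            _record(f"b{i}", 1.0, False) for i in range(3)
        ]
        summary = enrichment_summary(records)
        assert summary.median_ratio == pytest.approx(100.0)

    def test_single_peptide_groups(self):
        summary = enrichment_summary([_record("a", 42.0, True), _record("b", 7.0, False)])
        assert summary.median_recovery_arp == 42.0
        assert summary.median_recovery_background == 7.0

    def test_cv_pass_fractions(self):
        records = [_record("a", 100.0, True), _record("b", 1.0, False)]
        areas = {"a": [8.0, 10.0, 12.0], "b": [1.0, 3.0, 9.0]}
        summary = enrichment_summary(records, replicate_areas=areas, cv_threshold=20.0)
        assert summary.cv_pass_fraction_arp == 0.0  # CV exactly 20 is not below
        assert summary.cv_pass_fraction_background == 0.0
        summary2 = enrichment_summary(records, replicate_areas=areas, cv_threshold=25.0)
        assert summary2.cv_pass_fraction_arp == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_summary([_record("a", 100.0, True)])


class TestUpscale:
    def test_identical_conditions_give_unit_ratios(self):
        areas = {f"p{i}": [float(i + 1)] for i in range(5)}
        summary = upscale_compare(areas, areas)
        assert summary.median_ratio == 1.0 and summary.mean_ratio == 1.0

    def test_unpaired_peptides_excluded_and_counted(self):
        low = {"a": [1.0], "b": [2.0]}
        high = {"a": [7.0], "c": [1.0]}
        summary = upscale_compare(low, high)
        assert list(summary.ratios) == ["a"]
        assert summary.n_excluded == 2

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            upscale_compare({"a": [1.0]}, {"b": [1.0]})


class TestIonMobility:
    @staticmethod
    def _feature(drift):
        return ChromatographicFeature(
            run_id="r", peptidoform_id="p", charge=2, isotopes_used=3,
            rt_apex=5.0, rt_window=(4.5, 5.5), area=10.0, background_area=0.0,
            ab_ratio=float("inf"), drift_time=drift,
        )

    def test_exact_match_kept(self):
        kept = ion_mobility_filter([self._feature(5.0)], {"p": 5.0})
        assert len(kept) == 1

    def test_outside_window_removed(self):
        # half-window = 5.0 / (2*15) = 0.167 ms; 0.2 ms away is out
        kept = ion_mobility_filter([self._feature(5.2)], {"p": 5.0}, resolving_power=15)
        assert kept == []

    def test_infinite_resolving_power_keeps_only_exact(self):
        inside = self._feature(5.0)
        off = self._feature(5.0000001)
        kept = ion_mobility_filter([inside, off], {"p": 5.0}, resolving_power=1e12)
        assert kept == [inside]

    def test_missing_drift_passes_through(self):
        f = self._feature(None)
        assert ion_mobility_filter([f], {"p": 5.0}) == [f]
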