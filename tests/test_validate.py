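"""Error model, six-criterion classification, and ambiguity resolution."""

import numpy as np
import pytest

from arpmap.psm import PSM, match_spectrum
from arpmap.quantify import ChromatographicFeature
from arpmap.triage import ReporterEvidence, ReporterHit
from arpmap.validate import (
    AmbiguityDecision,
    ErrorModel,
    apply_criteria,
    classify,
    fit_error_model,
    resolve_modification_ambiguity,
)
from test_psm import make_form, render


def _psm(error_ppm=0.0, coverage=1.0, site=True):
    from arpmap.insilico import Peptidoform

    form = Peptidoform(
        sequence="PEPTIDEK", protein_accession="P", start=1, end=8,
        missed_cleavages=0, neutral_mass=900.0,
        variable_mods=((2, "glu_asp_isoimide"),),
    )
    return PSM(
        scan_id="s", peptidoform=form, precursor_error_ppm=error_ppm,
        matched_fragments=[], n_theoretical=14, sequence_coverage=coverage,
        score=50.0, site_confirmed=site, is_decoy=False,
    )


def _feature(area, background=0.0, run="enr_r1"):
    ratio = area / background if background > 0 else (float("inf") if area > 0 else 0.0)
    return ChromatographicFeature(
        run_id=run, peptidoform_id="x", charge=2, isotopes_used=3,
        rt_apex=5.0, rt_window=(4.7, 5.3), area=area,
        background_area=background, ab_ratio=ratio,
    )


def _reporter(candidate=True):
    return ReporterEvidence(
        scan_id="s",
        found={"biotin_227": ReporterHit(227.085, 100.0, 0.1)} if candidate else {},
        relative_intensity={"biotin_227": 0.5} if candidate else {},
        is_candidate=candidate,
    )


class TestErrorModel:
    def test_all_zero_errors_floor_sd(self):
        model = fit_error_model([_psm(0.0) for _ in range(20)])
        assert model.mean_ppm == 0.0
        assert model.sd_ppm == 0.5  # documented degeneracy floor

    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(3)
        psms = [_psm(e) for e in rng.normal(2.0, 5.0, size=1000)]
        model = fit_error_model(psms)
        assert model.mean_ppm == pytest.approx(2.0, abs=0.5)
        assert model.sd_ppm == pytest.approx(5.0, abs=0.7)

    def test_robust_to_single_outlier(self):
        psms = [_psm(0.0) for _ in range(99)] + [_psm(100.0)]
        model = fit_error_model(psms)
        assert abs(model.mean_ppm) < 0.01

    def test_too_few_psms(self):
        with pytest.raises(ValueError):
            fit_error_model([_psm()] * 5)


class TestApplyCriteria:
    MODEL = ErrorModel(mean_ppm=0.0, sd_ppm=5.0, n=100)

    def test_all_pass_is_confident(self):
        v = apply_criteria(
            _psm(), self.MODEL, reporter=_reporter(),
            feature_enriched=_feature(1000.0),
            feature_non_enriched=_feature(10.0, run="non_r1"),
        )
        assert v.verdict == "confident"
        assert all(s == "pass" for s in v.criteria.values())

    def test_site_failure_only_is_ambiguous(self):
        v = apply_criteria(
            _psm(site=False), self.MODEL, reporter=_reporter(),
            feature_enriched=_feature(1000.0),
            feature_non_enriched=_feature(10.0, run="non_r1"),
        )
        assert v.criteria[5] == "fail" and v.verdict == "ambiguous"

    def test_large_precursor_error_is_ambiguous(self):
        v = apply_criteria(
            _psm(error_ppm=25.0), self.MODEL, reporter=_reporter(),
            feature_enriched=_feature(1000.0),
            feature_non_enriched=_feature(10.0, run="non_r1"),
        )
        assert v.criteria[6] == "fail" and v.verdict == "ambiguous"

    def test_low_coverage_is_rejected(self):
        v = apply_criteria(
            _psm(coverage=0.4), self.MODEL, reporter=_reporter(),
            feature_enriched=_feature(1000.0),
            feature_non_enriched=_feature(10.0, run="non_r1"),
        )
        assert v.criteria[4] == "fail" and v.verdict == "rejected"

    def test_missing_quantitation_is_not_evaluable(self):
        v = apply_criteria(_psm(), self.MODEL, reporter=_reporter())
        assert v.criteria[1] == "not_evaluable" and v.criteria[2] == "not_evaluable"
        assert v.verdict == "confident"  # remaining criteria all pass

    def test_unresolved_peak_fails_criterion_one(self):
        v = apply_criteria(
            _psm(), self.MODEL, reporter=_reporter(),
            feature_enriched=_feature(10.0, background=9.0),
            feature_non_enriched=_feature(1.0, run="non_r1"),
        )
        assert v.criteria[1] == "fail" and v.verdict == "rejected"

    def test_chimera_notes(self):
        v = apply_criteria(
            _psm(), self.MODEL, reporter=_reporter(),
            coeluting_precursors=[631.1],
        )
        assert any("chimeric" in note for note in v.notes)

    def test_classification_is_total(self):
        for c5 in ("pass", "fail"):
            for c4 in ("pass", "fail"):
                verdict = classify({4: c4, 5: c5, 6: "pass"})
                assert verdict in ("confident", "ambiguous", "rejected")


class TestResolveAmbiguity:
    def test_multi_ptm_correction(self, registry_by_id):
        """A three-modification assignment (oxidized Lys + two CAM-Cys) must
        beat the isobaric-by-precursor two-modification proposal (acrolein-Cys
        + one CAM) when the discriminating b/y ions are present."""
        truth = make_form(
            "LKECCEKPLLEK",
            [(2, "lys_semialdehyde"), (4, "carbamidomethyl"), (5, "carbamidomethyl")],
            registry_by_id,
        )
        wrong = make_form(
            "LKECCEKPLLEK",
            [(4, "cys_acrolein"), (5, "carbamidomethyl")],
            registry_by_id,
        )
        spectrum = render(truth, registry_by_id, charge=2)
        decision = resolve_modification_ambiguity(
            spectrum, [truth, wrong], registry_by_id
        )
        assert not decision.all_ambiguous
        assert decision.chosen.peptidoform.mods == truth.mods

    def test_glyoxal_vs_cam_plus_imide(self, registry_by_id):
        """Exactly isobaric alternatives resolved by the ions between the
        candidate Cys and Gln sites."""
        truth = make_form(
            "ALCGQNLK",
            [(3, "carbamidomethyl"), (5, "gln_asn_imide")],
            registry_by_id,
        )
        wrong = make_form("ALCGQNLK", [(3, "cys_glyoxal")], registry_by_id)
        assert wrong.neutral_mass == pytest.approx(truth.neutral_mass, abs=1e-5)
        spectrum = render(truth, registry_by_id, charge=2)
        decision = resolve_modification_ambiguity(
            spectrum, [truth, wrong], registry_by_id
        )
        assert decision.chosen.peptidoform.mods == truth.mods

    def test_single_alternative_returned_unchanged(self, registry_by_id):
        form = make_form("ELVISLIVESK", (), registry_by_id)
        spectrum = render(form, registry_by_id)
        decision = resolve_modification_ambiguity(spectrum, [form], registry_by_id)
        assert decision.chosen.peptidoform is form and decision.alternatives == []

    def test_no_discriminating_ions_all_ambiguous(self, registry_by_id):
        truth = make_form(
            "ALCGQNLK", [(3, "carbamidomethyl"), (5, "gln_asn_imide")], registry_by_id
        )
        wrong = make_form("ALCGQNLK", [(3, "cys_glyoxal")], registry_by_id)
        import numpy as np
        from arpmap.spectra_io import Spectrum

        empty_ish = Spectrum(
            run_id="r", scan_id="s", ms_level=2, retention_time=1.0,
            mz=np.array([150.0]), intensity=np.array([1.0]),
            precursor_mz=truth.neutral_mass / 2, precursor_charge=2,
        )
        decision = resolve_modification_ambiguity(
            empty_ish, [truth, wrong], registry_by_id
        )
        assert decision.all_ambiguous and decision.chosen is None
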