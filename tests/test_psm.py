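"""Fragmentation rules, spectrum matching, scoring, and FDR filtering."""

import numpy as np
import pytest

from arpmap.chemdb import PROTON_MASS, mz_from_mass
from arpmap.insilico import Peptidoform, with_mass
from arpmap.psm import (
    PSM,
    fdr_filter,
    match_spectrum,
    score_psm,
    theoretical_fragments,
)
from arpmap.spectra_io import Spectrum


def make_form(sequence, mods=(), registry_by_id=None, is_decoy=False):
    p = Peptidoform(
        sequence=sequence, protein_accession="P", start=1, end=len(sequence),
        missed_cleavages=0, variable_mods=tuple(mods), is_decoy=is_decoy,
    )
    return with_mass(p, registry_by_id)


def render(form, registry_by_id, charge=2, extra=(), intensity=100.0):
    """Noiseless peak list of all theoretical fragments plus extras."""
    frags = theoretical_fragments(form, registry_by_id, precursor_charge=charge)
    mzs = [f.mz for f in frags] + [mz for mz, _ in extra]
    ints = [intensity] * len(frags) + [i for _, i in extra]
    return Spectrum(
        run_id="r", scan_id="s", ms_level=2, retention_time=5.0,
        mz=np.array(mzs), intensity=np.array(ints),
        precursor_mz=mz_from_mass(form.neutral_mass, charge),
        precursor_charge=charge,
    )


class TestTheoreticalFragments:
    def test_by_complementarity(self, registry_by_id):
        form = make_form(
            "LKCASLQK",
            [(2, "lys_semialdehyde"), (3, "carbamidomethyl")],
            registry_by_id,
        )
        frags = {
            (f.series, f.index): f.mz
            for f in theoretical_fragments(form, registry_by_id)
            if f.charge == 1 and f.loss is None
        }
        n = len(form.sequence)
        for i in range(1, n):
            b = frags[("b", i)] - PROTON_MASS
            y = frags[("y", n - i)] - PROTON_MASS
            assert b + y == pytest.approx(form.neutral_mass, abs=1e-3)

    def test_full_tag_losses_on_modified_ions_only(self, registry_by_id):
        form = make_form(
            "LKCASLQK",
            [(2, "lys_semialdehyde"), (3, "carbamidomethyl")],
            registry_by_id,
        )
        frags = theoretical_fragments(form, registry_by_id)
        y7_losses = {f.loss for f in frags if f.series == "y" and f.index == 7}
        y5_losses = {f.loss for f in frags if f.series == "y" and f.index == 5}
        assert {"tag_partial", "tag_full"} <= y7_losses  # contains the mod
        assert y5_losses == {None}  # C-terminal of the mod, unmodified
        assert any(f.series == "precursor" for f in frags)

    def test_keto_loss_for_thr_type_adduct(self, registry_by_id):
        form = make_form(
            "LCTVATLR", [(2, "carbamidomethyl"), (3, "thr_keto")], registry_by_id
        )
        losses = {f.loss for f in theoretical_fragments(form, registry_by_id)}
        assert "keto" in losses
        assert "tag_partial" not in losses and "tag_full" not in losses

    def test_unmodified_peptide_has_no_losses(self, registry_by_id):
        form = make_form("ELVISLIVES", (), registry_by_id)
        assert all(
            f.loss is None for f in theoretical_fragments(form, registry_by_id)
        )


class TestMatchSpectrum:
    def test_self_match_is_complete(self, registry_by_id):
        form = make_form(
            "LKCASLQK",
            [(2, "lys_semialdehyde"), (3, "carbamidomethyl")],
            registry_by_id,
        )
        s = render(form, registry_by_id)
        psm = match_spectrum(s, form, registry_by_id)
        assert psm.sequence_coverage == 1.0
        assert psm.site_confirmed
        assert abs(psm.precursor_error_ppm) < 0.1
        assert len(psm.matched_fragments) == psm.n_theoretical

    def test_wrong_site_isomer_scores_lower(self, registry_by_id):
        truth = make_form(
            "LKCASLQK",
            [(2, "lys_semialdehyde"), (3, "carbamidomethyl")],
            registry_by_id,
        )
        # same mass, adduct placed on the C-terminal-region Leu instead
        wrong = make_form(
            "LKCASLQK",
            [(3, "carbamidomethyl"), (6, "backbone_cleavage_semialdehyde")],
            registry_by_id,
        )
        assert wrong.neutral_mass == pytest.approx(truth.neutral_mass, abs=1e-6)
        s = render(truth, registry_by_id)
        psm_truth = match_spectrum(s, truth, registry_by_id)
        psm_wrong = match_spectrum(s, wrong, registry_by_id)
        assert psm_truth.score > psm_wrong.score
        assert psm_truth.site_confirmed

    def test_unknown_charge_rejected(self, registry_by_id):
        form = make_form("ELVISLIVESK", (), registry_by_id)
        s = render(form, registry_by_id)
        s.precursor_charge = None
        with pytest.raises(ValueError):
            match_spectrum(s, form, registry_by_id)

    def test_precursor_error_below_one_ppm_for_printed_value(self, registry_by_id):
        form = make_form(
            "LKCASLQK",
            [(2, "lys_semialdehyde"), (3, "carbamidomethyl")],
            registry_by_id,
        )
        s = render(form, registry_by_id)
        s.precursor_mz = 630.315  # three-decimal printed value
        psm = match_spectrum(s, form, registry_by_id)
        assert abs(psm.precursor_error_ppm) < 1.0


class TestScore:
    def test_zero_matches_scores_zero(self):
        assert score_psm(0, 20, 100, 1000.0, 20.0, 500.0, 0.0) == 0.0

    def test_monotone_in_matches(self):
        scores = [
            score_psm(k, 20, 40, 1000.0, 20.0, 500.0, k / 20)
            for k in range(0, 21, 5)
        ]
        assert scores == sorted(scores)
        assert scores[-1] > scores[2]

    def test_deterministic(self):
        a = score_psm(10, 20, 40, 1000.0, 20.0, 500.0, 0.5)
        b = score_psm(10, 20, 40, 1000.0, 20.0, 500.0, 0.5)
        assert a == b


class TestFdrFilter:
    @staticmethod
    def _psm(seq, score, is_decoy=False):
        form = Peptidoform(
            sequence=seq, protein_accession="P", start=1, end=len(seq),
            missed_cleavages=0, neutral_mass=1000.0, is_decoy=is_decoy,
        )
        return PSM(
            scan_id=f"{seq}:{score}", peptidoform=form, precursor_error_ppm=0.0,
            matched_fragments=[], n_theoretical=10, sequence_coverage=1.0,
            score=score, site_confirmed=True, is_decoy=is_decoy,
        )

    def test_hand_computed_q_sequence(self):
        psms = [
            self._psm("AAAAK", 10.0),
            self._psm("CCCCK", 9.0),
            self._psm("DDDDK", 8.0),
            self._psm("EEEEK", 7.0),
            self._psm("FFFFK", 7.5, is_decoy=True),
        ]
        kept = fdr_filter(psms, q_threshold=0.05)
        assert {m.peptidoform.sequence for m in kept} == {"AAAAK", "CCCCK", "DDDDK"}
        all_q = {m.peptidoform.sequence: m.q_value for m in psms}
        assert all_q["EEEEK"] == pytest.approx(0.25)

    def test_all_decoys_on_top_empties_result(self):
        psms = [
            self._psm("AAAAK", 1.0),
            self._psm("CCCCK", 9.0, is_decoy=True),
            self._psm("DDDDK", 8.0, is_decoy=True),
        ]
        assert fdr_filter(psms, q_threshold=0.05) == []

    def test_threshold_one_keeps_all_targets(self):
        psms = [
            self._psm("AAAAK", 1.0),
            self._psm("CCCCK", 0.5),
            self._psm("DDDDK", 8.0, is_decoy=True),
        ]
        kept = fdr_filter(psms, q_threshold=1.0)
        assert {m.peptidoform.sequence for m in kept} == {"AAAAK", "CCCCK"}

    def test_no_decoys_is_hard_error(self):
        with pytest.raises(ValueError, match="decoy"):
            fdr_filter([self._psm("AAAAK", 1.0)], 0.05)

    def test_best_psm_per_peptide(self):
        psms = [
            self._psm("AAAAK", 5.0),
            self._psm("AAAAK", 9.0),
            self._psm("DDDDK", 1.0, is_decoy=True),
        ]
        kept = fdr_filter(psms, 0.05)
        assert len(kept) == 1 and kept[0].score == 9.0
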