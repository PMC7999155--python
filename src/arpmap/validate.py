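"""Six-criterion confidence classification and ambiguity resolution.

A proposed ARP peptide is *confident* when it satisfies every evaluable
criterion: (1) a resolved chromatographic peak in the enriched fraction,
(2) higher relative intensity in the enriched than the non-enriched fraction,
(3) ARP reporter ions present in the tandem mass spectrum, (4) sequence
coverage above 50%, (5) fragment ions confirming the modification site, and
(6) a precursor error within +/-2 standard deviations of the dataset error
mean.  Failures confined to criteria 5/6 (weak site evidence or a larger
precursor error) downgrade the peptide to *ambiguous*; any other failure
rejects it.  Criteria 1-2 are not evaluable without paired enriched /
non-enriched quantitation and are then excluded from the all-pass rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemdb import ModificationSpec
from .insilico import Peptidoform
from .psm import PSM, match_spectrum
from .quantify import ChromatographicFeature
from .spectra_io import Spectrum
from .triage import ReporterEvidence

AMBIGUOUS_CRITERIA = frozenset({5, 6})

#: minimum area/background for a "resolved" chromatographic peak
RESOLVED_PEAK_AB_RATIO = 3.0
#: floor on the error-model SD to avoid degeneracy on noiseless data (ppm)
SD_FLOOR_PPM = 0.5
#: chimeric coelution annotation window (m/z units)
CHIMERA_WINDOW_MZ = 2.0


@dataclass(frozen=True)
class ErrorModel:
    """Robust precursor mass-error model (ppm) of a PSM population."""

    mean_ppm: float
    sd_ppm: float
    n: int

    def within(self, error_ppm: float, n_sd: float = 2.0) -> bool:
        return abs(error_ppm - self.mean_ppm) <= n_sd * self.sd_ppm


def fit_error_model(psms: Sequence[PSM], min_psms: int = 10) -> ErrorModel:
    """Median / scaled-MAD estimate of the precursor error distribution.

    MAD * 1.4826 estimates the SD of a normal population while ignoring
    outliers; the SD is floored at 0.5 ppm so a noiseless dataset does not
    collapse the acceptance window to zero.
    """
    errors = np.array([m.precursor_error_ppm for m in psms if not m.is_decoy])
    if errors.size < min_psms:
        raise ValueError(f"need at least {min_psms} PSMs to fit the error model")
    mean = float(np.median(errors))
    sd = float(1.4826 * np.median(np.abs(errors - mean)))
    return ErrorModel(mean_ppm=mean, sd_ppm=max(sd, SD_FLOOR_PPM), n=errors.size)


@dataclass
class ConfidenceVerdict:
    peptidoform_id: str
    criteria: dict[int, str]  # 1..6 -> "pass" | "fail" | "not_evaluable"
    verdict: str  # "confident" | "ambiguous" | "rejected"
    notes: list[str] = field(default_factory=list)


def classify(criteria: dict[int, str]) -> str:
    failed = {k for k, v in criteria.items() if v == "fail"}
    if not failed:
        return "confident"
    if failed <= AMBIGUOUS_CRITERIA:
        return "ambiguous"
    return "rejected"


def apply_criteria(
    psm: PSM,
    error_model: ErrorModel,
    reporter: ReporterEvidence | None = None,
    feature_enriched: ChromatographicFeature | None = None,
    feature_non_enriched: ChromatographicFeature | None = None,
    coeluting_precursors: Sequence[float] = (),
    coverage_threshold: float = 0.5,
) -> ConfidenceVerdict:
    """Evaluate the six confidence criteria for one PSM."""
    criteria: dict[int, str] = {}
    notes: list[str] = []

    if feature_enriched is None:
        criteria[1] = "not_evaluable"
    else:
        resolved = (
            feature_enriched.area > 0
            and feature_enriched.ab_ratio >= RESOLVED_PEAK_AB_RATIO
        )
        criteria[1] = "pass" if resolved else "fail"

    if feature_enriched is None or feature_non_enriched is None:
        criteria[2] = "not_evaluable"
    else:
        criteria[2] = (
            "pass" if feature_enriched.area > feature_non_enriched.area else "fail"
        )

    if reporter is None:
        criteria[3] = "not_evaluable"
    else:
        criteria[3] = "pass" if reporter.is_candidate else "fail"

    criteria[4] = "pass" if psm.sequence_coverage > coverage_threshold else "fail"
    criteria[5] = "pass" if psm.site_confirmed else "fail"
    criteria[6] = "pass" if error_model.within(psm.precursor_error_ppm) else "fail"

    # chimeric coelution: another candidate precursor within 2 m/z units
    for other in coeluting_precursors:
        notes.append(f"chimeric coelution candidate at m/z {other:.3f}")

    registry_free_id = psm.peptidoform.sequence + "/" + ",".join(
        f"{pos}:{mid}" for pos, mid in psm.peptidoform.mods
    )
    return ConfidenceVerdict(
        peptidoform_id=registry_free_id,
        criteria=criteria,
        verdict=classify(criteria),
        notes=notes,
    )


def find_coeluting_precursors(
    psm_precursor_mz: float,
    other_precursor_mzs: Sequence[float],
    window: float = CHIMERA_WINDOW_MZ,
) -> list[float]:
    """Precursors of other candidates within the chimera annotation window."""
    return [
        mz
        for mz in other_precursor_mzs
        if mz != psm_precursor_mz and abs(mz - psm_precursor_mz) < window
    ]


@dataclass
class AmbiguityDecision:
    chosen: PSM | None
    alternatives: list[PSM]
    all_ambiguous: bool
    rationale: str


def resolve_modification_ambiguity(
    spectrum: Spectrum,
    alternatives: Sequence[Peptidoform],
    registry_by_id: dict[str, ModificationSpec],
    frag_tol_ppm: float = 20.0,
) -> AmbiguityDecision:
    """Choose among isobaric modification assignments of one spectrum.

    Each alternative is rescored against the spectrum; the assignment whose
    site-discriminating ions are matched (site verdict true) and whose score
    is highest wins.  If no alternative has its sites confirmed, all are
    marked ambiguous.  A single alternative is returned unchanged.
    """
    psms = [
        match_spectrum(spectrum, p, registry_by_id, frag_tol_ppm=frag_tol_ppm)
        for p in alternatives
    ]
    if len(psms) == 1:
        return AmbiguityDecision(
            chosen=psms[0], alternatives=[], all_ambiguous=False,
            rationale="single assignment",
        )
    confirmed = [m for m in psms if m.site_confirmed]
    if not confirmed:
        return AmbiguityDecision(
            chosen=None, alternatives=psms, all_ambiguous=True,
            rationale="no site-discriminating ions matched for any alternative",
        )
    confirmed.sort(key=lambda m: -m.score)
    winner = confirmed[0]
    losers = [m for m in psms if m is not winner]
    return AmbiguityDecision(
        chosen=winner, alternatives=losers, all_ambiguous=False,
        rationale=(
            f"site-discriminating ions matched for "
            f"{winner.peptidoform.mod_string(registry_by_id)} "
            f"(score {winner.score:.2f} vs "
            f"{', '.join(f'{m.score:.2f}' for m in losers)})"
        ),
    )
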