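"""Theoretical fragmentation with ARP-specific losses, spectrum matching,
scoring, site localization, and target-decoy FDR.

Fragmentation emits b/y series at charges 1..2 (CID, trap region).  Fragments
containing an ARP-modified residue additionally carry neutral-loss variants
according to the modification's reporter profile: semialdehyde-type oximes
lose part (227.085 Da) or all (331.139 Da) of the tag from precursor, b and y
ions; keto-type oximes lose 288.126 Da from modified y ions.

The score is a transparent tail probability: -log10 of the binomial
probability of matching at least the observed number of fragments by chance
given the spectrum's peak density, plus the matched-intensity fraction.  It
replaces the proprietary scoring of commercial search engines and is
deterministic given its inputs.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .chemdb import (
    ARP,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    ModificationSpec,
    ReporterProfile,
    mass_from_mz,
    mz_from_mass,
)
from .insilico import Peptidoform
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

LOSS_MASSES = {
    "tag_partial": ARP.tag_loss_partial,
    "tag_full": ARP.tag_loss_full,
    "keto": ARP.keto_loss,
}


@dataclass(frozen=True, slots=True)
class TheoreticalFragment:
    series: str  # "b" | "y" | "precursor"
    index: int  # fragment length (0 for precursor)
    charge: int
    loss: str | None  # None | "tag_partial" | "tag_full" | "keto"
    mz: float
    carries_mod: bool

    def label(self) -> str:
        loss = f"-{LOSS_MASSES[self.loss]:.3f}" if self.loss else ""
        if self.series == "precursor":
            return f"[M+{self.charge}H]{loss}"
        return f"{self.series}{self.index}{loss}^{self.charge}"


def theoretical_fragments(
    p: Peptidoform,
    registry_by_id: dict[str, ModificationSpec],
    max_fragment_charge: int = 2,
    include_precursor: bool = True,
    precursor_charge: int | None = None,
) -> list[TheoreticalFragment]:
    """All b/y fragments (and precursor loss variants) of one peptidoform."""
    seq = p.sequence
    n = len(seq)
    mod_delta = np.zeros(n + 1)
    arp_profile_at: dict[int, ReporterProfile] = {}
    for pos, mid in p.mods:
        spec = registry_by_id[mid]
        mod_delta[pos] += spec.delta_mass
        if spec.is_arp:
            arp_profile_at[pos] = spec.reporter_profile

    residue = np.array([RESIDUE_MASSES[r] for r in seq])
    prefix = np.concatenate([[0.0], np.cumsum(residue + mod_delta[1:])])

    def losses_for(positions: Iterable[int], series: str) -> list[str]:
        out: list[str] = []
        for pos in positions:
            profile = arp_profile_at.get(pos)
            if profile is ReporterProfile.FULL_TAG:
                out += ["tag_partial", "tag_full"]
            elif profile is ReporterProfile.BIOTIN_ONLY and series in ("y", "precursor"):
                out.append("keto")
        return out

    frags: list[TheoreticalFragment] = []
    for i in range(1, n):
        b_neutral = prefix[i]
        y_neutral = prefix[n] - prefix[i] + WATER_MASS
        b_positions = [pos for pos in arp_profile_at if pos <= i]
        y_positions = [pos for pos in arp_profile_at if pos > i]
        for z in range(1, max_fragment_charge + 1):
            for series, neutral, positions in (
                ("b", b_neutral, b_positions),
                ("y", y_neutral, y_positions),
            ):
                idx = i if series == "b" else n - i
                carries = bool(positions)
                frags.append(
                    TheoreticalFragment(series, idx, z, None, mz_from_mass(neutral, z), carries)
                )
                for loss in losses_for(positions, series):
                    frags.append(
                        TheoreticalFragment(
                            series, idx, z, loss,
                            mz_from_mass(neutral - LOSS_MASSES[loss], z), carries,
                        )
                    )
    if include_precursor and arp_profile_at:
        neutral = prefix[n] + WATER_MASS
        zs = [precursor_charge] if precursor_charge else range(1, max_fragment_charge + 1)
        for z in zs:
            for loss in set(losses_for(arp_profile_at, "precursor")):
                frags.append(
                    TheoreticalFragment(
                        "precursor", 0, z, loss,
                        mz_from_mass(neutral - LOSS_MASSES[loss], z), True,
                    )
                )
    return frags


@dataclass
class PSM:
    scan_id: str
    peptidoform: Peptidoform
    precursor_error_ppm: float
    matched_fragments: list[tuple[TheoreticalFragment, float, float]]
    n_theoretical: int
    sequence_coverage: float
    score: float
    site_confirmed: bool
    is_decoy: bool
    q_value: float = float("nan")
    runner_up: "PSM | None" = None

    @property
    def peptide_key(self) -> tuple:
        return self.peptidoform.key()


def _match_peaks(
    spectrum: Spectrum, frags: Sequence[TheoreticalFragment], tol_ppm: float
) -> list[tuple[TheoreticalFragment, float, float]]:
    """Greedy nearest-ppm assignment; each peak satisfies at most one fragment."""
    candidates: list[tuple[float, int, int]] = []  # (|ppm|, frag idx, peak idx)
    mz = spectrum.mz
    for fi, frag in enumerate(frags):
        tol = frag.mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(mz, frag.mz - tol)
        hi = bisect.bisect_right(mz, frag.mz + tol)
        for pi in range(lo, hi):
            ppm = abs(mz[pi] - frag.mz) / frag.mz * 1e6
            candidates.append((ppm, fi, pi))
    candidates.sort()
    used_frags: set[int] = set()
    used_peaks: set[int] = set()
    matches = []
    for ppm, fi, pi in candidates:
        if fi in used_frags or pi in used_peaks:
            continue
        used_frags.add(fi)
        used_peaks.add(pi)
        matches.append((frags[fi], float(mz[pi]), float(spectrum.intensity[pi])))
    return matches


def _coverage_and_sites(
    p: Peptidoform,
    registry_by_id: dict[str, ModificationSpec],
    matched: Sequence[tuple[TheoreticalFragment, float, float]],
) -> tuple[float, bool]:
    """Sequence coverage and site localization from matched backbone ions.

    Backbone cleavage k (between residues k and k+1) counts as observed when
    any b_k or y_(n-k) variant is matched.  Coverage is the fraction of the
    n-1 cleavages observed.  A modified residue j is localized when the
    cleavages on both of its sides are observed (peptide termini count);
    the site verdict requires every ARP-modified residue to be localized.
    """
    n = len(p.sequence)
    observed = set()
    for frag, _, _ in matched:
        if frag.series == "b":
            observed.add(frag.index)
        elif frag.series == "y":
            observed.add(n - frag.index)
    observed.discard(0)
    observed.discard(n)
    coverage = len(observed) / (n - 1) if n > 1 else 0.0

    arp_positions = [
        pos for pos, mid in p.mods if registry_by_id[mid].is_arp
    ]
    if arp_positions:
        confirmed = all(
            (pos == 1 or (pos - 1) in observed) and (pos == n or pos in observed)
            for pos in arp_positions
        )
    else:
        confirmed = True
    return coverage, confirmed


def score_psm(
    n_matched: int,
    n_theoretical: int,
    n_peaks: int,
    mz_range: float,
    tol_ppm: float,
    mean_frag_mz: float,
    matched_intensity_fraction: float,
) -> float:
    """-log10 binomial tail probability of >= n_matched chance matches,
    plus the matched-intensity fraction as a bonus term."""
    if n_matched == 0 or n_theoretical == 0:
        return 0.0
    window = 2.0 * tol_ppm * 1e-6 * mean_frag_mz
    p_chance = min(0.5, n_peaks * window / max(mz_range, 1.0))
    tail = stats.binom.sf(n_matched - 1, n_theoretical, p_chance)
    tail = max(tail, 1e-300)
    return float(-np.log10(tail) + matched_intensity_fraction)


def match_spectrum(
    spectrum: Spectrum,
    p: Peptidoform,
    registry_by_id: dict[str, ModificationSpec],
    frag_tol_ppm: float = 20.0,
    prec_tol_ppm: float = 15.0,
    max_fragment_charge: int = 2,
) -> PSM:
    """Match one peptidoform against one MS2 spectrum."""
    if spectrum.ms_level != 2:
        raise ValueError("match_spectrum requires an MS2 spectrum")
    charge = spectrum.precursor_charge
    if not charge:
        raise ValueError(f"{spectrum.scan_id}: unknown precursor charge")
    observed_mass = mass_from_mz(spectrum.precursor_mz, charge)
    error_ppm = (observed_mass - p.neutral_mass) / p.neutral_mass * 1e6

    frags = theoretical_fragments(
        p, registry_by_id, max_fragment_charge, precursor_charge=charge
    )
    matched = _match_peaks(spectrum, frags, frag_tol_ppm)
    coverage, site_ok = _coverage_and_sites(p, registry_by_id, matched)

    total_intensity = float(spectrum.intensity.sum()) or 1.0
    matched_intensity = sum(inten for _, _, inten in matched)
    mz_range = float(spectrum.mz[-1] - spectrum.mz[0]) if spectrum.mz.size > 1 else 1.0
    mean_mz = float(np.mean([f.mz for f in frags])) if frags else 0.0
    score = score_psm(
        len(matched), len(frags), spectrum.mz.size, mz_range,
        frag_tol_ppm, mean_mz, matched_intensity / total_intensity,
    )
    return PSM(
        scan_id=spectrum.scan_id,
        peptidoform=p,
        precursor_error_ppm=float(error_ppm),
        matched_fragments=matched,
        n_theoretical=len(frags),
        sequence_coverage=coverage,
        score=score,
        site_confirmed=site_ok,
        is_decoy=p.is_decoy,
    )


class PeptidoformIndex:
    """Peptidoforms indexed by neutral mass for precursor-window lookup."""

    def __init__(self, forms: Sequence[Peptidoform]):
        self.forms = sorted(forms, key=lambda f: f.neutral_mass)
        self.masses = np.array([f.neutral_mass for f in self.forms])

    def __len__(self) -> int:
        return len(self.forms)

    def candidates(self, neutral_mass: float, tol_ppm: float) -> list[Peptidoform]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self.masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + tol, side="right"))
        return self.forms[lo:hi]


def _best_psm_for_scan(
    spectrum: Spectrum,
    index: PeptidoformIndex,
    registry_by_id: dict[str, ModificationSpec],
    frag_tol_ppm: float,
    prec_tol_ppm: float,
) -> PSM | None:
    charge = spectrum.precursor_charge
    if not charge:
        logger.info("scan %s: unknown charge, skipped", spectrum.scan_id)
        return None
    observed_mass = mass_from_mz(spectrum.precursor_mz, charge)
    # generous candidate gate; the strict ±2 SD rule is applied downstream
    cands = index.candidates(observed_mass, 3.0 * prec_tol_ppm)
    if not cands:
        return None
    psms = [
        match_spectrum(spectrum, p, registry_by_id, frag_tol_ppm, prec_tol_ppm)
        for p in cands
    ]
    # rank by score; at exactly equal score, target beats decoy
    psms.sort(key=lambda m: (-m.score, m.is_decoy))
    best = psms[0]
    if len(psms) > 1 and psms[1].score == best.score and not psms[1].is_decoy == best.is_decoy:
        logger.info("scan %s: target/decoy score tie, target kept", spectrum.scan_id)
    if len(psms) > 1:
        best.runner_up = psms[1]
    return best


def search(
    spectra: Iterable[Spectrum],
    pass1_index: PeptidoformIndex,
    pass2_index: PeptidoformIndex,
    registry_by_id: dict[str, ModificationSpec],
    frag_tol_ppm: float = 20.0,
    prec_tol_ppm: float = 15.0,
    pass1_min_score: float = 3.0,
    pass1_min_coverage: float = 0.5,
    min_matched_fragments: int = 3,
) -> list[PSM]:
    """Two-pass database search.

    Pass 1 searches every MS2 scan against peptidoforms with standard
    modifications only (carbamidomethyl / Met oxidation).  A scan counts as
    assigned only when its best pass-1 match reaches ``pass1_min_score`` and
    ``pass1_min_coverage`` (a chance isobaric hit rarely covers half the
    backbone); all other scans are re-searched in pass 2 against the full
    ARP registry.  Decoys are searched identically.
    """
    if not len(pass1_index) and not len(pass2_index):
        raise ValueError("empty peptidoform database")
    results: list[PSM] = []
    for spectrum in spectra:
        if spectrum.ms_level != 2:
            continue
        best = _best_psm_for_scan(
            spectrum, pass1_index, registry_by_id, frag_tol_ppm, prec_tol_ppm
        )
        if (
            best is None
            or best.score < pass1_min_score
            or best.sequence_coverage < pass1_min_coverage
        ):
            second = _best_psm_for_scan(
                spectrum, pass2_index, registry_by_id, frag_tol_ppm, prec_tol_ppm
            )
            if second is not None and (best is None or second.score > best.score):
                best = second
        if best is not None and len(best.matched_fragments) >= min_matched_fragments:
            results.append(best)
    return results


def fdr_filter(psms: Sequence[PSM], q_threshold: float = 0.05) -> list[PSM]:
    """Peptide-level target-decoy FDR.

    Keeps the best PSM per peptide (sequence + localized mods), computes
    q = (#decoys at or above score) / (#targets at or above score), monotonized
    from the bottom of the score ranking, and retains target peptides with
    q <= threshold.  Requires at least one decoy PSM in the input.
    """
    if not any(m.is_decoy for m in psms):
        raise ValueError("FDR undefined: no decoy PSMs in input")
    best: dict[tuple, PSM] = {}
    for m in psms:
        key = (m.is_decoy, *m.peptide_key)
        if key not in best or m.score > best[key].score:
            best[key] = m
    ranked = sorted(best.values(), key=lambda m: (-m.score, m.is_decoy))
    decoys = 0
    targets = 0
    raw_q: list[float] = []
    for m in ranked:
        if m.is_decoy:
            decoys += 1
        else:
            targets += 1
        raw_q.append(decoys / max(targets, 1))
    # monotonize: q at a cut is the minimum FDR achievable at or below it
    running = float("inf")
    qvals = [0.0] * len(ranked)
    for i in range(len(ranked) - 1, -1, -1):
        running = min(running, raw_q[i])
        qvals[i] = running
    kept = []
    for m, q in zip(ranked, qvals):
        m.q_value = q
        if not m.is_decoy and q <= q_threshold:
            kept.append(m)
    return kept
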