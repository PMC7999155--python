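"""End-to-end orchestration: digest, search, FDR, validation, quantitation.

This module wires the stage modules together for the common case of a run
set with enriched and non-enriched fractions.  Identification uses the MS2
scans of the enriched fraction(s); quantitation extracts EIC features for
every retained peptidoform in every run.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chemdb
from .chemdb import ModificationSpec
from .insilico import (
    Peptidoform,
    ProteinRecord,
    digest,
    enumerate_peptidoforms,
    flag_shared_decoy_peptides,
    make_decoys,
)
from .psm import PSM, PeptidoformIndex, fdr_filter, search
from .quantify import (
    ChromatographicFeature,
    RecoveryRecord,
    extract_eic_robust,
    feature_from_trace,
    recovery_percent,
    refine_rt_window,
)
from .spectra_io import RunManifest, Spectrum
from .triage import ReporterEvidence, detect_reporters
from .validate import ConfidenceVerdict, ErrorModel, apply_criteria, fit_error_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    frag_tol_ppm: float = 20.0
    prec_tol_ppm: float = 15.0
    reporter_tol_ppm: float = 20.0
    reporter_floor: float = 0.01
    fdr_q: float = 0.05
    cam_mode: str = "fixed"
    max_variable_mods: int = 3
    max_missed: int = 3
    min_length: int = 6
    max_length: int = 45
    semi: bool = False
    pass1_min_score: float = 3.0
    resolving_power: float = 20000.0
    n_isotopes: int = 3
    rt_half_window: float = 0.3  # minutes around the MS2 scan for EIC integration
    combinatorial_cap: int = 10_000


def build_indexes(
    proteins: Sequence[ProteinRecord],
    registry: Sequence[ModificationSpec],
    params: PipelineParams,
) -> tuple[PeptidoformIndex, PeptidoformIndex, dict[str, ModificationSpec]]:
    """Target+decoy peptidoform indexes for the two search passes.

    Pass 1 carries only the standard modifications (fixed/variable
    carbamidomethyl and Met oxidation); pass 2 the full registry.  Decoy
    peptides identical in sequence to any target peptide are excluded from
    the decoy set (they cannot inform the FDR estimate).
    """
    registry_by_id = {m.id: m for m in registry}
    standard = [m for m in registry if m.id in ("carbamidomethyl", "met_oxidation")]

    targets = [p for p in proteins if not p.is_decoy]
    decoys = [p for p in proteins if p.is_decoy] or make_decoys(targets)

    def digest_all(records):
        peptides = []
        for r in records:
            peptides.extend(
                digest(r, params.max_missed, params.min_length, params.max_length, params.semi)
            )
        return peptides

    target_peptides = digest_all(targets)
    decoy_peptides, shared = flag_shared_decoy_peptides(
        target_peptides, digest_all(decoys)
    )
    if shared:
        logger.info("excluded %d decoy peptides shared with targets", len(shared))

    def enumerate_all(peptides, mods, max_var):
        forms = []
        for p in peptides:
            # long peptides with many eligible residues can exceed the
            # per-peptide cap; back off on the variable-mod depth for those
            for depth in range(max_var, -1, -1):
                try:
                    forms.extend(
                        enumerate_peptidoforms(
                            p, mods, depth, params.cam_mode, params.combinatorial_cap
                        )
                    )
                    break
                except ValueError:
                    if depth == 0:
                        raise
                    logger.info(
                        "%s: variable-mod depth reduced to %d (cap)", p.sequence, depth - 1
                    )
        return forms

    pass1 = PeptidoformIndex(
        enumerate_all(target_peptides, standard, 1)
        + enumerate_all(decoy_peptides, standard, 1)
    )
    pass2 = PeptidoformIndex(
        enumerate_all(target_peptides, registry, params.max_variable_mods)
        + enumerate_all(decoy_peptides, registry, params.max_variable_mods)
    )
    return pass1, pass2, registry_by_id


@dataclass
class PipelineResult:
    params: PipelineParams
    psms: list[PSM]  # retained at the FDR threshold
    all_psms: list[PSM]
    error_model: ErrorModel
    reporter_evidence: dict[str, ReporterEvidence]
    verdicts: dict[str, ConfidenceVerdict]  # scan_id -> verdict
    features: dict[tuple[str, str], ChromatographicFeature]  # (run, peptidoform id) -> feature
    recoveries: list[RecoveryRecord]

    def confident_scans(self) -> list[PSM]:
        return [m for m in self.psms if self.verdicts[m.scan_id].verdict == "confident"]


def _pid(p: Peptidoform) -> str:
    return p.sequence + "/" + ",".join(f"{pos}:{mid}" for pos, mid in p.mods)


def run_pipeline(
    spectra_by_run: dict[str, list[Spectrum]],
    runs: RunManifest,
    proteins: Sequence[ProteinRecord],
    registry: Sequence[ModificationSpec] | None = None,
    params: PipelineParams | None = None,
    indexes: tuple | None = None,
) -> PipelineResult:
    """Identify, validate and quantify one run set.

    ``indexes`` may carry a prebuilt (pass1, pass2, registry_by_id) triple
    from :func:`build_indexes` to amortize index construction across runs.
    """
    params = params or PipelineParams()
    registry = registry or chemdb.builtin_registry()
    if indexes is None:
        indexes = build_indexes(proteins, registry, params)
    pass1, pass2, registry_by_id = indexes

    enriched_runs = [rid for rid, info in runs.items() if info.fraction == "enriched"]
    non_enriched_runs = [rid for rid, info in runs.items() if info.fraction == "non_enriched"]

    ms2_scans: list[Spectrum] = []
    scan_by_id: dict[str, Spectrum] = {}
    for rid in enriched_runs:
        for s in spectra_by_run[rid]:
            if s.ms_level == 2:
                ms2_scans.append(s)
                scan_by_id[s.scan_id] = s

    all_psms = search(
        ms2_scans, pass1, pass2, registry_by_id,
        frag_tol_ppm=params.frag_tol_ppm, prec_tol_ppm=params.prec_tol_ppm,
        pass1_min_score=params.pass1_min_score,
    )
    if any(m.is_decoy for m in all_psms):
        kept = fdr_filter(all_psms, params.fdr_q)
    else:
        # decoys were searched but never won a scan; the empirical FDR is
        # then indistinguishable from zero and all best-per-peptide targets
        # are retained with q = 0
        logger.warning("no decoy PSMs; retaining all target peptides at q=0")
        best: dict[tuple, PSM] = {}
        for m in all_psms:
            if m.peptide_key not in best or m.score > best[m.peptide_key].score:
                best[m.peptide_key] = m
        kept = sorted(best.values(), key=lambda m: -m.score)
        for m in kept:
            m.q_value = 0.0
    try:
        error_model = fit_error_model(kept) if len(kept) >= 10 else fit_error_model(
            [m for m in all_psms if not m.is_decoy], min_psms=2
        )
    except ValueError:
        # too few PSMs to estimate the dataset error; fall back to a window
        # matching the instrument-typical +/-15 ppm (2 SD)
        error_model = ErrorModel(mean_ppm=0.0, sd_ppm=params.prec_tol_ppm / 2.0, n=0)

    reporter_evidence = {
        m.scan_id: detect_reporters(
            scan_by_id[m.scan_id], params.reporter_tol_ppm, params.reporter_floor
        )
        for m in kept
    }

    # EIC features per retained peptidoform per run
    ms1_by_run = {
        rid: [s for s in spectra if s.ms_level == 1]
        for rid, spectra in spectra_by_run.items()
    }
    features: dict[tuple[str, str], ChromatographicFeature] = {}
    for m in kept:
        pid = _pid(m.peptidoform)
        scan = scan_by_id[m.scan_id]
        window = (
            scan.retention_time - params.rt_half_window,
            scan.retention_time + params.rt_half_window,
        )
        for rid in spectra_by_run:
            key = (rid, pid)
            if key in features:
                continue
            rts, trace = extract_eic_robust(
                ms1_by_run[rid], m.peptidoform.neutral_mass, scan.precursor_charge,
                params.resolving_power, params.n_isotopes,
            )
            refined = refine_rt_window(
                rts, trace, window, apex_hint=scan.retention_time
            )
            features[key] = feature_from_trace(
                rts, trace, refined, rid, pid, scan.precursor_charge,
                params.n_isotopes, drift_time=scan.drift_time,
            )

    # verdicts (chimera annotation from co-retained precursors)
    precursors = [scan_by_id[m.scan_id].precursor_mz for m in kept]
    verdicts: dict[str, ConfidenceVerdict] = {}
    for m in kept:
        pid = _pid(m.peptidoform)
        feat_enr = _mean_feature(features, enriched_runs, pid)
        feat_non = _mean_feature(features, non_enriched_runs, pid)
        own = scan_by_id[m.scan_id].precursor_mz
        coeluting = [
            mz for mz in precursors if mz != own and abs(mz - own) < 2.0
        ]
        verdicts[m.scan_id] = apply_criteria(
            m, error_model,
            reporter=reporter_evidence.get(m.scan_id),
            feature_enriched=feat_enr,
            feature_non_enriched=feat_non,
            coeluting_precursors=coeluting,
        )

    # recovery records (first replicate of each fraction)
    recoveries: list[RecoveryRecord] = []
    if enriched_runs and non_enriched_runs:
        load_enr = runs[enriched_runs[0]].load
        load_non = runs[non_enriched_runs[0]].load
        for m in kept:
            pid = _pid(m.peptidoform)
            fe = features.get((enriched_runs[0], pid))
            fn = features.get((non_enriched_runs[0], pid))
            if fe is None or fn is None or fn.area <= 0:
                continue
            is_arp = any(registry_by_id[mid].is_arp for _, mid in m.peptidoform.mods)
            recoveries.append(
                RecoveryRecord(
                    peptidoform_id=pid,
                    area_enriched=fe.area,
                    area_non_enriched=fn.area,
                    load_enriched=load_enr,
                    load_non_enriched=load_non,
                    recovery_percent=recovery_percent(fe.area, fn.area, load_enr, load_non),
                    quantifiable_pre_enrichment=fn.ab_ratio > 10,
                    is_arp=is_arp,
                )
            )

    return PipelineResult(
        params=params, psms=kept, all_psms=all_psms, error_model=error_model,
        reporter_evidence=reporter_evidence, verdicts=verdicts,
        features=features, recoveries=recoveries,
    )


def _mean_feature(
    features: dict[tuple[str, str], ChromatographicFeature],
    run_ids: Sequence[str],
    pid: str,
) -> ChromatographicFeature | None:
    """Representative feature across replicate runs (mean area/background)."""
    found = [features[(rid, pid)] for rid in run_ids if (rid, pid) in features]
    if not found:
        return None
    areas = np.array([f.area for f in found])
    bkgs = np.array([f.background_area for f in found])
    mean_bkg = float(bkgs.mean())
    mean_area = float(areas.mean())
    ratio = mean_area / mean_bkg if mean_bkg > 0 else (float("inf") if mean_area > 0 else 0.0)
    rep = found[0]
    return ChromatographicFeature(
        run_id=";".join(f.run_id for f in found),
        peptidoform_id=pid, charge=rep.charge, isotopes_used=rep.isotopes_used,
        rt_apex=rep.rt_apex, rt_window=rep.rt_window,
        area=mean_area, background_area=mean_bkg, ab_ratio=ratio,
        drift_time=rep.drift_time,
    )
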