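"""EIC extraction/integration, recovery estimation, CVs, enrichment and
upscale summaries, and ion-mobility filtering.

Extracted ion chromatograms use the first three isotopes of the precursor
envelope with relative abundances from an averagine approximation, summing
MS1 peaks inside a +/- (m/z / resolving power) window around each isotope.
Peak areas are trapezoidal integrals above a linear baseline interpolated
between the window-edge medians; the background area is the baseline integral
over the same window.  Recovery follows the load-normalized area ratio

    Recovery % = 100 * (A_enriched / A_non_enriched) * (L_non / L_enriched)

so a lossless enrichment scores 100% regardless of the load asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chemdb import mz_from_mass
from .spectra_io import Spectrum

ISOTOPE_SPACING = 1.00335483  # C13 - C12

# averagine residue composition per 111.1254 Da of peptide mass
_AVERAGINE_CARBONS_PER_DA = 4.9384 / 111.1254
_HEAVY_RATE_PER_CARBON = 0.0107  # 13C abundance dominates the envelope


def averagine_envelope(neutral_mass: float, n_isotopes: int = 3) -> np.ndarray:
    """Relative abundances of the first isotopes, Poisson-approximated.

    The number of heavy-isotope substitutions in a peptide of average
    (averagine) composition is approximately Poisson with rate proportional
    to the carbon count; minor contributions of N/H/S are absorbed into the
    effective rate.  Abundances are normalized to sum to one over the first
    ``n_isotopes``.
    """
    lam = neutral_mass * _AVERAGINE_CARBONS_PER_DA * _HEAVY_RATE_PER_CARBON * 1.08
    k = np.arange(n_isotopes)
    log_fact = np.cumsum(np.concatenate([[0.0], np.log(np.arange(1, n_isotopes))])) if n_isotopes > 1 else np.zeros(1)
    weights = np.exp(k * np.log(lam + 1e-300) - lam - log_fact)
    return weights / weights.sum()


@dataclass
class ChromatographicFeature:
    run_id: str
    peptidoform_id: str
    charge: int
    isotopes_used: int
    rt_apex: float
    rt_window: tuple[float, float]
    area: float
    background_area: float
    ab_ratio: float
    drift_time: float | None = None


@dataclass
class RecoveryRecord:
    peptidoform_id: str
    area_enriched: float
    area_non_enriched: float
    load_enriched: float
    load_non_enriched: float
    recovery_percent: float
    quantifiable_pre_enrichment: bool
    is_arp: bool = True


def extract_eic(
    ms1_spectra: Sequence[Spectrum],
    neutral_mass: float,
    charge: int,
    resolving_power: float = 20000.0,
    n_isotopes: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """EIC trace (retention time, summed intensity) for one peptidoform/charge.

    For each MS1 scan, sums the intensity of peaks within
    +/- (m/z / resolving_power) of each of the first ``n_isotopes`` isotope
    m/z values (spacing 1.00335/charge).
    """
    targets = np.array([
        mz_from_mass(neutral_mass + k * ISOTOPE_SPACING, charge)
        for k in range(n_isotopes)
    ])
    half_widths = targets / resolving_power
    rts = np.empty(len(ms1_spectra))
    intensities = np.empty(len(ms1_spectra))
    for i, s in enumerate(ms1_spectra):
        rts[i] = s.retention_time
        total = 0.0
        for target, hw in zip(targets, half_widths):
            lo = np.searchsorted(s.mz, target - hw, side="left")
            hi = np.searchsorted(s.mz, target + hw, side="right")
            if hi > lo:
                total += float(s.intensity[lo:hi].sum())
        intensities[i] = total
    order = np.argsort(rts, kind="stable")
    return rts[order], intensities[order]


def extract_eic_traces(
    ms1_spectra: Sequence[Spectrum],
    neutral_mass: float,
    charge: int,
    resolving_power: float = 20000.0,
    n_isotopes: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-isotope EIC traces: (retention times, array of shape (n_isotopes, n))."""
    targets = np.array([
        mz_from_mass(neutral_mass + k * ISOTOPE_SPACING, charge)
        for k in range(n_isotopes)
    ])
    half_widths = targets / resolving_power
    rts = np.empty(len(ms1_spectra))
    traces = np.zeros((n_isotopes, len(ms1_spectra)))
    for i, s in enumerate(ms1_spectra):
        rts[i] = s.retention_time
        for k, (target, hw) in enumerate(zip(targets, half_widths)):
            lo = np.searchsorted(s.mz, target - hw, side="left")
            hi = np.searchsorted(s.mz, target + hw, side="right")
            if hi > lo:
                traces[k, i] = float(s.intensity[lo:hi].sum())
    order = np.argsort(rts, kind="stable")
    return rts[order], traces[:, order]


def extract_eic_robust(
    ms1_spectra: Sequence[Spectrum],
    neutral_mass: float,
    charge: int,
    resolving_power: float = 20000.0,
    n_isotopes: int = 3,
    interference_factor: float = 1.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Interference-aware EIC: isotopes inconsistent with the envelope are
    dropped before summing, emulating the manual removal of interfered
    isotope traces during integration.

    Each isotope trace is normalized by its expected envelope abundance;
    for an uninterfered peptide the normalized traces coincide, and since
    interference from coeluting species is additive, their elementwise
    minimum is a robust estimate of the true elution profile even when all
    but one isotope is contaminated.  An isotope whose normalized total
    exceeds ``interference_factor`` times the minimum profile's total is
    excluded; the remaining isotopes are summed and rescaled so the returned
    trace estimates the full-envelope intensity.
    """
    rts, traces = extract_eic_traces(
        ms1_spectra, neutral_mass, charge, resolving_power, n_isotopes
    )
    weights = averagine_envelope(neutral_mass, n_isotopes)
    normalized = traces / weights[:, None]
    reference = np.min(normalized, axis=0)
    ref_total = reference.sum()
    if ref_total <= 0:
        return rts, traces.sum(axis=0)
    keep = np.array([
        normalized[k].sum() <= interference_factor * ref_total
        for k in range(n_isotopes)
    ])
    if not keep.any():
        keep[:] = True
    scale = float(weights[keep].sum())
    return rts, traces[keep].sum(axis=0) / scale


def refine_rt_window(
    rts: np.ndarray,
    intensities: np.ndarray,
    window: tuple[float, float],
    apex_floor: float = 0.05,
    apex_hint: float | None = None,
) -> tuple[float, float]:
    """Tighten an RT integration window around the apex it contains.

    ``apex_hint`` (typically the retention time of the triggering MS/MS
    scan) anchors the apex: the nearest local maximum is found by hill
    climbing from the hint, so a stronger coeluting peak elsewhere in the
    window cannot hijack the integration.  Without a hint the most intense
    point is used.  Starting from that apex, each boundary is
    walked outward for as long as the trace keeps descending or sits below
    ``apex_floor`` of the apex intensity; it stops at a genuine valley (the
    trace rising again above the floor, i.e. the flank of a coeluting peak).
    An isolated peak therefore keeps the full window, while a window
    contaminated by a neighbouring peak is clipped at the valley between
    them.  This automates the manual correction of integration windows.
    """
    lo, hi = window
    mask = (rts >= lo) & (rts <= hi)
    if mask.sum() < 3:
        return window
    idx = np.flatnonzero(mask)
    x = rts[idx]
    y = intensities[idx]
    if apex_hint is None:
        apex = int(np.argmax(y))
    else:
        apex = int(np.argmin(np.abs(x - apex_hint)))
        while apex > 0 and y[apex - 1] > y[apex]:
            apex -= 1
        while apex < y.size - 1 and y[apex + 1] > y[apex]:
            apex += 1
    floor = apex_floor * y[apex]
    left = apex
    while left > 0:
        nxt = y[left - 1]
        if nxt > y[left] and nxt > floor:
            break
        left -= 1
    right = apex
    while right < y.size - 1:
        nxt = y[right + 1]
        if nxt > y[right] and nxt > floor:
            break
        right += 1
    if right - left < 2:
        return window
    return float(x[left]), float(x[right])


def integrate(
    rts: np.ndarray,
    intensities: np.ndarray,
    rt_window: tuple[float, float],
    edge_fraction: float = 0.1,
) -> tuple[float, float, float]:
    """Trapezoidal area above a linear edge-median baseline inside a window.

    The baseline is interpolated between the medians of the leading and
    trailing ``edge_fraction`` of points inside the window; the background
    area is the baseline integral over the window.  Returns
    (area, background_area, area/background ratio); the ratio is inf for a
    positive area on zero background and 0 when the window is empty.
    """
    lo, hi = rt_window
    mask = (rts >= lo) & (rts <= hi)
    if mask.sum() < 2:
        return 0.0, 0.0, 0.0
    x = rts[mask]
    y = intensities[mask]
    n_edge = max(1, int(round(edge_fraction * x.size)))
    left = float(np.median(y[:n_edge]))
    right = float(np.median(y[-n_edge:]))
    baseline = np.interp(x, [x[0], x[-1]], [left, right])
    area = float(np.trapezoid(np.clip(y - baseline, 0.0, None), x))
    background = float(np.trapezoid(baseline, x))
    if background > 0:
        ratio = area / background
    else:
        ratio = float("inf") if area > 0 else 0.0
    return area, background, ratio


def feature_from_trace(
    rts: np.ndarray,
    intensities: np.ndarray,
    rt_window: tuple[float, float],
    run_id: str,
    peptidoform_id: str,
    charge: int,
    n_isotopes: int = 3,
    drift_time: float | None = None,
) -> ChromatographicFeature:
    area, background, ratio = integrate(rts, intensities, rt_window)
    lo, hi = rt_window
    mask = (rts >= lo) & (rts <= hi)
    if mask.any():
        apex = float(rts[mask][np.argmax(intensities[mask])])
    else:
        apex = 0.5 * (lo + hi)
    return ChromatographicFeature(
        run_id=run_id, peptidoform_id=peptidoform_id, charge=charge,
        isotopes_used=n_isotopes, rt_apex=apex, rt_window=rt_window,
        area=area, background_area=background, ab_ratio=ratio,
        drift_time=drift_time,
    )


def recovery_percent(
    area_enriched: float,
    area_non_enriched: float,
    load_enriched: float,
    load_non_enriched: float,
) -> float:
    """Load-normalized recovery estimate in percent."""
    if area_non_enriched <= 0:
        raise ValueError("non-enriched area must be positive for recovery")
    if load_enriched <= 0 or load_non_enriched <= 0:
        raise ValueError("loads must be positive")
    return 100.0 * (area_enriched / area_non_enriched) * (load_non_enriched / load_enriched)


def cv(areas: Sequence[float]) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    values = np.asarray(areas, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass
class EnrichmentSummary:
    median_recovery_arp: float
    median_recovery_background: float
    median_ratio: float
    cv_pass_fraction_arp: float | None
    cv_pass_fraction_background: float | None


def enrichment_summary(
    records: Sequence[RecoveryRecord],
    replicate_areas: dict[str, Sequence[float]] | None = None,
    cv_threshold: float = 20.0,
) -> EnrichmentSummary:
    """Group recovery records into ARP vs non-derivatized and summarize.

    ``replicate_areas`` maps peptidoform id -> per-replicate enriched areas,
    used for the fraction of peptides with CV below ``cv_threshold``.
    """
    arp = [r.recovery_percent for r in records if r.is_arp]
    bkg = [r.recovery_percent for r in records if not r.is_arp]
    if not arp or not bkg:
        raise ValueError("both ARP and background groups must be non-empty")
    med_arp = float(np.median(arp))
    med_bkg = float(np.median(bkg))

    def cv_fraction(ids: list[str]) -> float | None:
        if not replicate_areas:
            return None
        cvs = [
            cv(replicate_areas[i])
            for i in ids
            if i in replicate_areas and len(replicate_areas[i]) >= 2
        ]
        if not cvs:
            return None
        return float(np.mean([c < cv_threshold for c in cvs]))

    return EnrichmentSummary(
        median_recovery_arp=med_arp,
        median_recovery_background=med_bkg,
        median_ratio=med_arp / med_bkg if med_bkg > 0 else float("inf"),
        cv_pass_fraction_arp=cv_fraction([r.peptidoform_id for r in records if r.is_arp]),
        cv_pass_fraction_background=cv_fraction(
            [r.peptidoform_id for r in records if not r.is_arp]
        ),
    )


@dataclass
class UpscaleSummary:
    ratios: dict[str, float]
    mean_ratio: float
    median_ratio: float
    fraction_above_one: float
    n_excluded: int


def upscale_compare(
    areas_low: dict[str, Sequence[float]],
    areas_high: dict[str, Sequence[float]],
) -> UpscaleSummary:
    """Per-peptide mean-area ratio (high/low load) and distribution summary.

    Peptides present in only one condition are excluded and counted.
    """
    shared = sorted(set(areas_low) & set(areas_high))
    if not shared:
        raise ValueError("no peptides shared between load conditions")
    ratios = {}
    for pid in shared:
        low = float(np.mean(areas_low[pid]))
        high = float(np.mean(areas_high[pid]))
        if low > 0:
            ratios[pid] = high / low
    values = np.array(list(ratios.values()))
    return UpscaleSummary(
        ratios=ratios,
        mean_ratio=float(values.mean()),
        median_ratio=float(np.median(values)),
        fraction_above_one=float(np.mean(values > 1.0)),
        n_excluded=len(set(areas_low) ^ set(areas_high)),
    )


def ion_mobility_filter(
    features: Sequence[ChromatographicFeature],
    predicted_drift: dict[str, float],
    resolving_power: float = 15.0,
) -> list[ChromatographicFeature]:
    """Keep features whose drift time falls inside the predicted IM window.

    The window is FWHM-style: total width = predicted / resolving_power,
    applied as a half-window of predicted / (2 * resolving_power).  Features
    without drift data pass through unchanged.
    """
    kept = []
    for f in features:
        if f.drift_time is None:
            kept.append(f)
            continue
        predicted = predicted_drift.get(f.peptidoform_id)
        if predicted is None:
            kept.append(f)
            continue
        if abs(f.drift_time - predicted) <= predicted / (2.0 * resolving_power):
            kept.append(f)
    return kept


def predict_drift_time(mz: float, charge: int) -> float:
    """Simple drift-time surrogate (ms), monotone in m/z, used by the
    synthetic generator and the ion-mobility predictor alike."""
    return 0.25 * np.sqrt(mz) / np.sqrt(charge)
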