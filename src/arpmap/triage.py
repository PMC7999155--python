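"""Reporter-ion screening of MS/MS spectra.

ARP-derivatized peptides produce a biotin fragment at m/z 227.085 in every
CID spectrum, and (for semialdehyde-type oximes) ARP fragments at 299.117 and
the protonated probe at 332.139.  Screening for these reporters flags
candidate ARP spectra independently of modification type and site.  The flag
is advisory: it feeds the reporter criterion of the validation stage, it does
not gate the database search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chemdb import ARP
from .spectra_io import Spectrum

REPORTER_MZS: dict[str, float] = {
    "biotin_227": ARP.reporter_biotin_mz,
    "arp_fragment_299": ARP.reporter_arp_fragment_mz,
    "arp_protonated_332": ARP.reporter_arp_protonated_mz,
}


@dataclass(frozen=True)
class ReporterHit:
    observed_mz: float
    intensity: float
    ppm_error: float


@dataclass(frozen=True)
class ReporterEvidence:
    scan_id: str
    found: dict[str, ReporterHit]
    relative_intensity: dict[str, float]
    is_candidate: bool


def detect_reporters(
    spectrum: Spectrum,
    tol_ppm: float = 20.0,
    min_relative_intensity: float = 0.01,
) -> ReporterEvidence:
    """Locate ARP reporter ions in one MS/MS spectrum.

    For each reporter the nearest peak within ``tol_ppm`` is recorded.  The
    spectrum is a candidate ARP spectrum iff the 227.085 biotin reporter is
    found at or above ``min_relative_intensity`` of the base peak (default 1%,
    a free parameter of this implementation).
    """
    if spectrum.ms_level != 2:
        raise ValueError("reporter detection requires an MS2 spectrum")
    found: dict[str, ReporterHit] = {}
    relative: dict[str, float] = {}
    base = spectrum.base_peak_intensity
    for name, target in REPORTER_MZS.items():
        idx = spectrum.nearest_peak(target)
        if idx is None:
            continue
        ppm = (spectrum.mz[idx] - target) / target * 1e6
        if abs(ppm) <= tol_ppm:
            hit = ReporterHit(
                observed_mz=float(spectrum.mz[idx]),
                intensity=float(spectrum.intensity[idx]),
                ppm_error=float(ppm),
            )
            found[name] = hit
            relative[name] = hit.intensity / base if base > 0 else 0.0
    biotin = found.get("biotin_227")
    is_candidate = (
        biotin is not None
        and relative["biotin_227"] >= min_relative_intensity
    )
    return ReporterEvidence(
        scan_id=spectrum.scan_id,
        found=found,
        relative_intensity=relative,
        is_candidate=is_candidate,
    )


def triage_table(evidence: Iterable[ReporterEvidence]) -> "pandas.DataFrame":
    """Tabulate reporter evidence (one row per scan)."""
    import pandas as pd

    rows = []
    for ev in evidence:
        row: dict = {"scan_id": ev.scan_id, "is_candidate": ev.is_candidate}
        for name in REPORTER_MZS:
            hit = ev.found.get(name)
            row[f"{name}_mz"] = hit.observed_mz if hit else None
            row[f"{name}_ppm"] = hit.ppm_error if hit else None
            row[f"{name}_rel_intensity"] = ev.relative_intensity.get(name)
        rows.append(row)
    return pd.DataFrame(rows)
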