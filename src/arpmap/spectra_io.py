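"""Reading/writing centroided MS1 and MS/MS data, and lock-mass recalibration.

mzML and MGF are supported.  MGF (MS2-only) goes through pyteomics.  mzML is
handled by a minimal built-in reader/writer pair: the writer emits plain mzML
with uncompressed 64-bit arrays; the reader resolves cvParams by accession
and accepts plain or indexed documents with 32/64-bit, zlib-compressed or
uncompressed arrays.  Retention times are minutes throughout; drift times
(ms), when present, travel in an MGF ``ION_MOBILITY`` key or the mzML scan
cvParam.
"""

from __future__ import annotations

import base64
import struct
import zlib
import warnings
import xml.sax.saxutils as _sax
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import mgf as _pmgf

from .chemdb import ARP


@dataclass
class Spectrum:
    """One centroided spectrum; peaks sorted ascending in m/z."""

    run_id: str
    scan_id: str
    ms_level: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    drift_time: float | None = None  # ms

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"{self.scan_id}: MS2 spectrum without precursor m/z")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.mz.size and np.any(np.diff(self.mz) == 0):
            # merge duplicate m/z by summing intensities
            uniq, inverse = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, self.intensity)
            self.mz, self.intensity = uniq, summed

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def nearest_peak(self, target_mz: float) -> int | None:
        """Index of the peak nearest to ``target_mz``, or None if empty."""
        if not self.mz.size:
            return None
        i = int(np.searchsorted(self.mz, target_mz))
        candidates = [j for j in (i - 1, i) if 0 <= j < self.mz.size]
        return min(candidates, key=lambda j: abs(self.mz[j] - target_mz))


@dataclass(frozen=True)
class RunInfo:
    run_id: str
    path: str
    fraction: str  # "enriched" | "non_enriched"
    replicate: int
    load: float  # sample amount on column, arbitrary mass units

    def __post_init__(self) -> None:
        if self.fraction not in ("enriched", "non_enriched"):
            raise ValueError(f"unknown fraction label {self.fraction!r}")
        if self.load <= 0:
            raise ValueError("load must be positive")


class RunManifest(dict):
    """run_id -> RunInfo; TSV columns run_id, path, fraction, replicate, load."""

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RunManifest":
        manifest = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                manifest[row["run_id"]] = RunInfo(
                    run_id=row["run_id"], path=row["path"],
                    fraction=row["fraction"], replicate=int(row["replicate"]),
                    load=float(row["load"]),
                )
        return manifest

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("run_id\tpath\tfraction\treplicate\tload\n")
            for info in self.values():
                fh.write(
                    f"{info.run_id}\t{info.path}\t{info.fraction}\t"
                    f"{info.replicate}\t{info.load:g}\n"
                )


# ---------------------------------------------------------------------------
# reading

def _read_mgf(path: str, run_id: str) -> Iterator[Spectrum]:
    with _pmgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            rt = params.get("rtinseconds")
            rt = float(rt) / 60.0 if rt is not None else 0.0
            drift = params.get("ion_mobility") or params.get("drift_time")
            yield Spectrum(
                run_id=run_id,
                scan_id=str(params.get("title", f"index={i}")),
                ms_level=2,
                retention_time=rt,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                precursor_mz=float(pepmass[0]) if pepmass[0] is not None else None,
                precursor_charge=charge,
                drift_time=float(drift) if drift is not None else None,
            )


def _decode_binary(element) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit, no/zlib compression)."""
    accessions = {
        cv.get("accession") for cv in element.iter() if cv.tag.endswith("cvParam")
    }
    binary = None
    for child in element.iter():
        if child.tag.endswith("binary"):
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str, run_id: str) -> Iterator[Spectrum]:
    """Minimal mzML reader (plain or indexed; cvParams matched by accession)."""
    from lxml import etree

    for _, element in etree.iterparse(str(path), tag="{*}spectrum"):
        params: dict[str, str] = {}
        rt = 0.0
        rt_unit = "minute"
        drift = None
        precursor_mz = None
        charge = None
        arrays: dict[str, np.ndarray] = {}
        for cv in element.iterchildren("{*}cvParam"):
            params[cv.get("accession")] = cv.get("value", "")
        for scan_list in element.iterchildren("{*}scanList"):
            for scan in scan_list.iterchildren("{*}scan"):
                for cv in scan.iterchildren("{*}cvParam"):
                    if cv.get("accession") == "MS:1000016":
                        rt = float(cv.get("value"))
                        rt_unit = cv.get("unitName", "minute")
                    elif cv.get("accession") == "MS:1002476":
                        drift = float(cv.get("value"))
        for plist in element.iterchildren("{*}precursorList"):
            for cv in plist.iter("{*}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    precursor_mz = float(cv.get("value"))
                elif cv.get("accession") == "MS:1000041":
                    charge = int(cv.get("value"))
        for alist in element.iterchildren("{*}binaryDataArrayList"):
            for array in alist.iterchildren("{*}binaryDataArray"):
                kinds = {
                    cv.get("accession") for cv in array.iterchildren("{*}cvParam")
                }
                data = _decode_binary(array)
                if "MS:1000514" in kinds:
                    arrays["mz"] = data
                elif "MS:1000515" in kinds:
                    arrays["intensity"] = data
        if "MS:1000128" in params:
            raise ValueError(
                f"{path}: profile-mode spectrum {element.get('id')}; centroided "
                "data required"
            )
        ms_level = int(params.get("MS:1000511", 1))
        if rt_unit == "second":
            rt /= 60.0
        scan_id = element.get("id") or f"index={element.get('index')}"
        element.clear()
        yield Spectrum(
            run_id=run_id,
            scan_id=scan_id,
            ms_level=ms_level,
            retention_time=rt,
            mz=arrays.get("mz", np.empty(0)),
            intensity=arrays.get("intensity", np.empty(0)),
            precursor_mz=precursor_mz,
            precursor_charge=charge,
            drift_time=drift,
        )


def read_spectra(path: str | Path, format: str | None = None, run_id: str | None = None) -> list[Spectrum]:
    """Read all spectra from an mzML or MGF file, in file order."""
    path = Path(path)
    if format is None:
        format = "mgf" if path.suffix.lower() == ".mgf" else "mzml"
    run_id = run_id or path.stem
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty file")
        return []
    if format.lower() == "mgf":
        return list(_read_mgf(str(path), run_id))
    if format.lower() == "mzml":
        return list(_read_mzml(str(path), run_id))
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# writing

def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        if s.ms_level != 2:
            continue
        params = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time * 60.0,
        }
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        if s.drift_time is not None:
            params["ion_mobility"] = s.drift_time
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _pmgf.write(entries, str(path), file_mode="w")


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{array.size}d", *np.asarray(array, dtype=float))
    ).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    value_attr = f' value="{_sax.escape(str(value))}"' if value != "" else ' value=""'
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{_sax.escape(name)}"'
        f"{value_attr}{unit}/>"
    )


_MIN_UNIT = ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
_MS_UNIT = ' unitCvRef="UO" unitAccession="UO:0000028" unitName="millisecond"'


def write_mzml(spectra: Sequence[Spectrum], path: str | Path, run_id: str = "run") -> None:
    """Write a minimal plain mzML file (centroid, uncompressed 64-bit)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UO" URI="http://ontologies.berkeleybop.org/uo.obo"/>'
        "</cvList>",
        f'<run id="{_sax.escape(run_id)}">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for index, s in enumerate(spectra):
        mz64, int64 = _b64(s.mz), _b64(s.intensity)
        lines.append(
            f'<spectrum index="{index}" id="{_sax.escape(s.scan_id)}" '
            f'defaultArrayLength="{s.mz.size}">'
        )
        lines.append(_cv("MS:1000511", "ms level", s.ms_level))
        lines.append(_cv("MS:1000127", "centroid spectrum"))
        lines.append("<scanList count=\"1\"><scan>")
        lines.append(
            _cv("MS:1000016", "scan start time", f"{s.retention_time:.6f}", _MIN_UNIT)
        )
        if s.drift_time is not None:
            lines.append(
                _cv("MS:1002476", "ion mobility drift time", f"{s.drift_time:.6f}", _MS_UNIT)
            )
        lines.append("</scan></scanList>")
        if s.ms_level == 2:
            lines.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
            )
            lines.append(_cv("MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}"))
            if s.precursor_charge:
                lines.append(_cv("MS:1000041", "charge state", s.precursor_charge))
            lines.append("</selectedIon></selectedIonList></precursor></precursorList>")
        lines.append(f'<binaryDataArrayList count="2">')
        for accession, name, data in (
            ("MS:1000514", "m/z array", mz64),
            ("MS:1000515", "intensity array", int64),
        ):
            lines.append(f'<binaryDataArray encodedLength="{len(data)}">')
            lines.append(_cv("MS:1000523", "64-bit float"))
            lines.append(_cv("MS:1000576", "no compression"))
            lines.append(_cv(accession, name))
            lines.append(f"<binary>{data}</binary>")
            lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# lock-mass recalibration

def lockmass_recalibrate(
    spectra: Iterable[Spectrum],
    observed_reference: float,
    reference_mz: float = ARP.lockmass_reference_mz,
    tolerance: float = 0.5,
) -> list[Spectrum]:
    """Multiplicative lock-mass correction of all peak and precursor m/z.

    Every m/z in the block is scaled by ``reference_mz / observed_reference``
    (a ppm-like TOF error model).  If the observed reference deviates from the
    nominal lock mass by more than ``tolerance`` (Da), the block is returned
    uncorrected with a warning.
    """
    spectra = list(spectra)
    if abs(observed_reference - reference_mz) > tolerance:
        warnings.warn(
            f"observed lock mass {observed_reference:.4f} outside ±{tolerance} Da "
            f"of {reference_mz:.4f}; block left uncorrected"
        )
        return spectra
    factor = reference_mz / observed_reference
    out = []
    for s in spectra:
        out.append(
            replace(
                s,
                mz=s.mz * factor,
                intensity=s.intensity.copy(),
                precursor_mz=s.precursor_mz * factor if s.precursor_mz is not None else None,
            )
        )
    return out
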