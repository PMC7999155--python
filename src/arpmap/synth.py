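"""Ground-truth-annotated synthetic LC-MS/MS datasets.

The generator plants ARP-modified and unmodified tryptic peptides from the
bundled protein panel along a shared retention-time axis, then renders

* MS1 spectra: three-isotope envelopes (averagine abundances) under Gaussian
  chromatographic peaks, plus a uniform low-level noise floor;
* MS2 spectra: b/y ladders with the tag-specific neutral losses and reporter
  ions mandated by each modification's profile, plus optional noise peaks
  and pure-noise scans.

Abundance model: each planted peptidoform has a base peak height ``h``; in a
non-enriched fraction the rendered height is ``h * load_non / load_enr`` (the
same material, less of it on column), and in an enriched fraction it is
``h * retention`` where ``retention`` is the fraction of the peptide
surviving affinity enrichment (≈1 for ARP peptides, 1/depletion for
background).  Under the load-normalized recovery formula this makes the
true recovery of a peptide exactly ``100 * retention`` percent.

Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chemdb
from .chemdb import ReporterProfile, mz_from_mass
from .insilico import Peptidoform, ProteinRecord, digest, enumerate_peptidoforms, with_mass, write_fasta
from .panel import protein_panel
from .psm import theoretical_fragments
from .quantify import ISOTOPE_SPACING, averagine_envelope, predict_drift_time
from .spectra_io import RunInfo, RunManifest, Spectrum, write_mgf, write_mzml

# loads mirror the study design: enriched fraction equivalent to 11 µg of
# digest, non-enriched control 70 ng (0.07 µg)
DEFAULT_LOAD_ENRICHED = 11.0
DEFAULT_LOAD_NON_ENRICHED = 0.07


@dataclass
class ScenarioConfig:
    name: str = "baseline"
    n_arp_peptides: int = 50
    n_background_peptides: int = 30
    replicates: int = 1
    load_enriched: float = DEFAULT_LOAD_ENRICHED
    load_non_enriched: float = DEFAULT_LOAD_NON_ENRICHED
    arp_retention: float = 1.0
    background_retention: float = 0.01
    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    baseline_level: float = 0.0  # mean intensity of MS1 noise peaks
    n_noise_scans: int = 0  # pure-noise MS2 scans per run
    rt_max: float = 18.0  # minutes
    ms1_interval: float = 0.05  # minutes between MS1 scans
    rt_sigma: float = 0.08  # chromatographic peak SD, minutes
    base_height: float = 1.0e4
    upscale_load_factor: float | None = None  # second condition, e.g. 10
    upscale_efficiency: float = 0.73
    dilution_ratios: tuple[int, ...] = ()  # e.g. (9, 49, 249)
    chimera_pairs: int = 0
    with_drift_times: bool = True
    max_variable_mods: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        data = json.loads(text)
        if "dilution_ratios" in data:
            data["dilution_ratios"] = tuple(data["dilution_ratios"])
        return cls(**data)


def scenario(name: str, **overrides) -> ScenarioConfig:
    """Named scenario templates."""
    presets: dict[str, dict] = {
        "baseline": {},
        "noisy": {
            "mz_jitter_ppm": 10.0,
            "intensity_cv": 0.2,
            "baseline_level": 2.0,
            "n_noise_scans": 20,
        },
        "noise_only": {
            "n_arp_peptides": 0,
            "n_background_peptides": 0,
            "n_noise_scans": 500,
        },
        "recovery": {"replicates": 3},
        "upscale": {
            "replicates": 3,
            "upscale_load_factor": 10.0,
            "intensity_cv": 0.05,
        },
        "dilution": {"replicates": 3, "dilution_ratios": (9, 49, 249)},
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return ScenarioConfig(name=name, **params)


@dataclass
class PlantedPeptidoform:
    peptidoform: Peptidoform
    charge: int
    rt_apex: float
    base_height: float
    retention: float
    is_arp: bool
    drift_time: float | None = None

    @property
    def pid(self) -> str:
        return self.peptidoform.sequence + "/" + ",".join(
            f"{pos}:{mid}" for pos, mid in self.peptidoform.mods
        )


@dataclass
class GroundTruthManifest:
    seed: int
    config: ScenarioConfig
    proteins: list[ProteinRecord]
    planted: list[PlantedPeptidoform]
    runs: RunManifest

    def truth_recovery_percent(self, planted: PlantedPeptidoform) -> float:
        return 100.0 * planted.retention

    def true_area(self, planted: PlantedPeptidoform, run_id: str) -> float:
        """Noise-free integrated peak area of one planted feature in one run."""
        h = rendered_height(planted, self.runs[run_id], self.config)
        return h * self.config.rt_sigma * np.sqrt(2.0 * np.pi)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "planted": [
                {
                    "sequence": p.peptidoform.sequence,
                    "mods": list(p.peptidoform.mods),
                    "protein": p.peptidoform.protein_accession,
                    "start": p.peptidoform.start,
                    "end": p.peptidoform.end,
                    "charge": p.charge,
                    "rt_apex": p.rt_apex,
                    "base_height": p.base_height,
                    "retention": p.retention,
                    "is_arp": p.is_arp,
                    "drift_time": p.drift_time,
                }
                for p in self.planted
            ],
            "runs": {
                rid: dataclasses.asdict(info) for rid, info in self.runs.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def rendered_height(
    planted: PlantedPeptidoform, run: RunInfo, config: ScenarioConfig
) -> float:
    """Peak height of one planted peptidoform in one run (before noise)."""
    if run.fraction == "enriched":
        h = planted.base_height * planted.retention
    else:
        h = planted.base_height * (config.load_non_enriched / config.load_enriched)
    # upscale / dilution conditions encode their scale factor in the load
    h *= run.load / (
        config.load_enriched if run.fraction == "enriched" else config.load_non_enriched
    )
    return h


def _eligible_arp_sites(
    p: Peptidoform, registry: Sequence[chemdb.ModificationSpec]
) -> list[tuple[int, str]]:
    sites = []
    n = len(p.sequence)
    for i, res in enumerate(p.sequence, start=1):
        # skip C-terminal K/R: modifying the tryptic anchor is chemically
        # possible but would have blocked cleavage; keep planted truth simple
        if i == n and res in "KR":
            continue
        for m in registry:
            if not m.is_arp:
                continue
            if m.applies_to(res, is_n_term=(i == 1), is_c_term=(i == n)):
                sites.append((i, m.id))
    return sites


def generate_truth(config: ScenarioConfig, seed: int) -> GroundTruthManifest:
    """Plant peptidoforms and design runs deterministically from the seed."""
    rng = np.random.default_rng(seed)
    registry = chemdb.builtin_registry()
    registry_by_id = {m.id: m for m in registry}
    proteins = protein_panel()

    peptides = []
    for protein in proteins:
        peptides.extend(digest(protein, max_missed=1, min_length=6, max_length=30))
    # unique sequences, stable order
    seen: set[str] = set()
    unique = []
    for p in peptides:
        if p.sequence not in seen:
            seen.add(p.sequence)
            unique.append(p)

    cam = [m for m in registry if m.id == "carbamidomethyl"]

    def cam_fixed(p: Peptidoform) -> Peptidoform:
        forms = enumerate_peptidoforms(p, cam, max_variable_mods=0, cam_mode="fixed")
        return forms[0]

    arp_capable = [p for p in unique if _eligible_arp_sites(p, registry)]
    rng.shuffle(arp_capable)
    planted: list[PlantedPeptidoform] = []

    used_keys: set[tuple] = set()
    # cycle the capable peptides, planting one new modification form per
    # visit, until the requested count is reached or forms are exhausted
    exhausted: set[str] = set()
    while (
        sum(q.is_arp for q in planted) < config.n_arp_peptides
        and len(exhausted) < len(arp_capable)
    ):
        for p in arp_capable:
            if sum(q.is_arp for q in planted) >= config.n_arp_peptides:
                break
            if p.sequence in exhausted:
                continue
            base = cam_fixed(p)
            sites = _eligible_arp_sites(base, registry)
            order = rng.permutation(len(sites))
            form = None
            for idx in order:
                pos, mid = sites[int(idx)]
                # an ARP adduct on a Cys displaces the fixed carbamidomethyl
                fixed = tuple(f for f in base.fixed_mods if f[0] != pos)
                candidate = with_mass(
                    replace(base, fixed_mods=fixed, variable_mods=((pos, mid),)),
                    registry_by_id,
                )
                if candidate.key() not in used_keys:
                    form = candidate
                    break
            if form is None:
                exhausted.add(p.sequence)
                continue
            used_keys.add(form.key())
            planted.append(
                _plant(form, rng, config, retention=config.arp_retention, is_arp=True)
            )

    background_pool = [p for p in unique if p.sequence not in {q.peptidoform.sequence for q in planted}]
    rng.shuffle(background_pool)
    for p in background_pool[: config.n_background_peptides]:
        form = cam_fixed(p)
        if form.key() in used_keys:
            continue
        used_keys.add(form.key())
        sticky = "HPY" in p.sequence
        retention = 0.5 if sticky else config.background_retention
        planted.append(_plant(form, rng, config, retention=retention, is_arp=False))

    # spread apexes over the gradient deterministically, then jitter slightly
    planted.sort(key=lambda q: q.pid)
    n = len(planted)
    if n:
        span = config.rt_max - 2.0
        apexes = 1.0 + span * (np.arange(n) + 0.5) / n
        apexes = apexes + rng.normal(0.0, 0.02, size=n)
        order = rng.permutation(n)
        for q, rt in zip(planted, apexes[order]):
            q.rt_apex = float(rt)

    runs = RunManifest()
    if config.dilution_ratios:
        for ratio in config.dilution_ratios:
            for rep in range(1, config.replicates + 1):
                rid = f"dil{ratio}_r{rep}"
                runs[rid] = RunInfo(rid, f"{rid}.mzML", "enriched", rep, config.load_enriched)
    elif config.upscale_load_factor:
        for cond, factor in (("low", 1.0), ("high", config.upscale_load_factor)):
            for rep in range(1, config.replicates + 1):
                rid = f"{cond}_r{rep}"
                runs[rid] = RunInfo(
                    rid, f"{rid}.mzML", "enriched", rep, config.load_enriched * factor
                )
    else:
        for rep in range(1, config.replicates + 1):
            rid = f"enr_r{rep}"
            runs[rid] = RunInfo(rid, f"{rid}.mzML", "enriched", rep, config.load_enriched)
            rid = f"non_r{rep}"
            runs[rid] = RunInfo(rid, f"{rid}.mzML", "non_enriched", rep, config.load_non_enriched)
    return GroundTruthManifest(
        seed=seed, config=config, proteins=proteins, planted=planted, runs=runs
    )


def _plant(
    form: Peptidoform, rng: np.random.Generator, config: ScenarioConfig,
    retention: float, is_arp: bool,
) -> PlantedPeptidoform:
    charge = 2 if len(form.sequence) < 13 else 3
    height = config.base_height * float(rng.lognormal(0.0, 0.4))
    mz = mz_from_mass(form.neutral_mass, charge)
    return PlantedPeptidoform(
        peptidoform=form,
        charge=charge,
        rt_apex=0.0,  # assigned after all peptides are planted
        base_height=height,
        retention=retention,
        is_arp=is_arp,
        drift_time=float(predict_drift_time(mz, charge)) if config.with_drift_times else None,
    )


# ---------------------------------------------------------------------------
# rendering


def _upscale_height_factor(run: RunInfo, config: ScenarioConfig) -> float:
    """In the upscale design the tenfold load yields only ~7.3-fold signal
    (recovery efficiency < 1 at higher load)."""
    if config.upscale_load_factor and run.load > config.load_enriched:
        return config.upscale_efficiency
    return 1.0


def render_run(
    manifest: GroundTruthManifest, run_id: str, rng: np.random.Generator
) -> list[Spectrum]:
    """Render all MS1 + MS2 spectra of one run (rt-ordered)."""
    config = manifest.config
    run = manifest.runs[run_id]
    registry_by_id = {m.id: m for m in chemdb.builtin_registry()}
    jitter_sd = config.mz_jitter_ppm * 1e-6

    def jitter(mz: np.ndarray | float):
        if jitter_sd == 0.0:
            return mz
        return mz * (1.0 + rng.normal(0.0, jitter_sd, size=np.shape(mz) or None))

    rt_grid = np.arange(0.0, config.rt_max, config.ms1_interval)
    spectra: list[Spectrum] = []

    # per-run intensity multiplier per peptide (replicate noise)
    heights = {}
    for planted in manifest.planted:
        h = rendered_height(planted, run, config) * _upscale_height_factor(run, config)
        if config.intensity_cv > 0:
            h *= float(rng.lognormal(0.0, config.intensity_cv))
        heights[planted.pid] = h

    for i, rt in enumerate(rt_grid):
        mzs: list[float] = []
        ints: list[float] = []
        for planted in manifest.planted:
            h = heights[planted.pid] * np.exp(
                -0.5 * ((rt - planted.rt_apex) / config.rt_sigma) ** 2
            )
            if h < 1e-3:
                continue
            envelope = averagine_envelope(planted.peptidoform.neutral_mass)
            for k, weight in enumerate(envelope):
                mzs.append(
                    float(jitter(mz_from_mass(
                        planted.peptidoform.neutral_mass + k * ISOTOPE_SPACING,
                        planted.charge,
                    )))
                )
                ints.append(h * float(weight))
        if config.baseline_level > 0:
            n_noise = int(rng.poisson(30))
            mzs.extend(rng.uniform(300.0, 1200.0, size=n_noise).tolist())
            ints.extend(
                rng.exponential(config.baseline_level, size=n_noise).tolist()
            )
        if not mzs:
            mzs, ints = [500.0], [0.0]
        spectra.append(
            Spectrum(
                run_id=run_id, scan_id=f"{run_id}.ms1.{i}", ms_level=1,
                retention_time=float(rt), mz=np.array(mzs), intensity=np.array(ints),
            )
        )

    # MS2: one scan per planted peptidoform near its apex
    for j, planted in enumerate(manifest.planted):
        spectra.append(
            _render_ms2(
                planted, run_id, f"{run_id}.ms2.{j}", registry_by_id, config, rng
            )
        )
    for k in range(config.n_noise_scans):
        n_peaks = 60 + int(rng.integers(0, 40))
        mzs = np.sort(rng.uniform(100.0, 1500.0, size=n_peaks))
        ints = rng.exponential(50.0, size=n_peaks)
        spectra.append(
            Spectrum(
                run_id=run_id, scan_id=f"{run_id}.noise.{k}", ms_level=2,
                retention_time=float(rng.uniform(1.0, config.rt_max - 1.0)),
                mz=mzs, intensity=ints,
                precursor_mz=float(rng.uniform(400.0, 900.0)),
                precursor_charge=2,
            )
        )
    spectra.sort(key=lambda s: (s.retention_time, s.ms_level, s.scan_id))
    return spectra


def _render_ms2(
    planted: PlantedPeptidoform,
    run_id: str,
    scan_id: str,
    registry_by_id: dict,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> Spectrum:
    jitter_sd = config.mz_jitter_ppm * 1e-6
    form = planted.peptidoform
    frags = theoretical_fragments(
        form, registry_by_id, max_fragment_charge=min(2, planted.charge),
        precursor_charge=planted.charge,
    )
    base = 1000.0
    mzs: list[float] = []
    ints: list[float] = []
    for frag in frags:
        intensity = base * float(rng.uniform(0.2, 1.0))
        if config.intensity_cv > 0:
            intensity *= float(rng.lognormal(0.0, config.intensity_cv))
        mzs.append(frag.mz)
        ints.append(intensity)

    profiles = {
        registry_by_id[mid].reporter_profile
        for _, mid in form.mods
        if registry_by_id[mid].is_arp
    }
    if profiles:
        mzs.append(chemdb.ARP.reporter_biotin_mz)
        ints.append(base * 1.5)
        if ReporterProfile.FULL_TAG in profiles:
            mzs.append(chemdb.ARP.reporter_arp_fragment_mz)
            ints.append(base * 1.2)
            mzs.append(chemdb.ARP.reporter_arp_protonated_mz)
            ints.append(base * 1.0)

    if config.baseline_level > 0:
        n_noise = int(rng.poisson(15))
        mzs.extend(rng.uniform(100.0, 1400.0, size=n_noise).tolist())
        ints.extend(rng.exponential(base * 0.02, size=n_noise).tolist())

    mz_arr = np.array(mzs)
    if jitter_sd > 0:
        mz_arr = mz_arr * (1.0 + rng.normal(0.0, jitter_sd, size=mz_arr.size))
    precursor = mz_from_mass(form.neutral_mass, planted.charge)
    if jitter_sd > 0:
        precursor *= 1.0 + float(rng.normal(0.0, jitter_sd))
    return Spectrum(
        run_id=run_id, scan_id=scan_id, ms_level=2,
        retention_time=planted.rt_apex,
        mz=mz_arr, intensity=np.array(ints),
        precursor_mz=float(precursor), precursor_charge=planted.charge,
        drift_time=planted.drift_time,
    )


def render_dataset(
    manifest: GroundTruthManifest, outdir: str | Path, write_mgf_too: bool = True
) -> dict[str, list[Spectrum]]:
    """Render and write every run; returns the in-memory spectra per run.

    Per-run RNG streams are derived from the manifest seed so each run is
    independently reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_run: dict[str, list[Spectrum]] = {}
    for k, run_id in enumerate(manifest.runs):
        rng = np.random.default_rng((manifest.seed, k))
        spectra = render_run(manifest, run_id, rng)
        by_run[run_id] = spectra
        write_mzml(spectra, outdir / f"{run_id}.mzML", run_id=run_id)
        if write_mgf_too:
            write_mgf(spectra, outdir / f"{run_id}.mgf")
    write_fasta(manifest.proteins, outdir / "panel.fasta")
    manifest.runs.write_tsv(outdir / "runs.tsv")
    manifest.to_json(outdir / "truth.json")
    return by_run
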