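"""In-silico tryptic digestion, peptidoform enumeration, and decoy generation.

Digestion follows the conventional trypsin rule (cleavage C-terminal to K/R,
not before P), emitting peptides with up to a configurable number of missed
cleavages and, optionally, semi-specific peptides with one non-tryptic
terminus.  Protein termini count as valid cleavage sites.  Decoys are
pseudo-reversed proteins: the sequence is reversed within each tryptic
segment so the C-terminal K/R positions are preserved, which keeps the decoy
peptide mass and cleavage-pattern distribution close to the targets'.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import fasta as _pfasta

from .chemdb import CANONICAL_RESIDUES, ModificationSpec, peptide_neutral_mass

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True, slots=True)
class Peptidoform:
    """A peptide sequence with localized modifications and protein coordinates.

    ``fixed_mods``/``variable_mods`` are tuples of (1-based position, mod id);
    positions within one peptidoform are unique across both lists.
    """

    sequence: str
    protein_accession: str
    start: int
    end: int
    missed_cleavages: int
    fixed_mods: tuple[tuple[int, str], ...] = ()
    variable_mods: tuple[tuple[int, str], ...] = ()
    neutral_mass: float = 0.0
    is_decoy: bool = False

    @property
    def mods(self) -> tuple[tuple[int, str], ...]:
        return tuple(sorted(self.fixed_mods + self.variable_mods))

    def mod_string(self, registry_by_id: dict[str, ModificationSpec]) -> str:
        """Bracket notation, e.g. ``LK[+312.089]EC[+57.022]...``."""
        out = []
        mod_at = {pos: mid for pos, mid in self.mods}
        for i, res in enumerate(self.sequence, start=1):
            out.append(res)
            if i in mod_at:
                out.append(f"[{registry_by_id[mod_at[i]].delta_mass:+.3f}]")
        return "".join(out)

    def key(self) -> tuple:
        """Peptide-level identity: sequence + full localized mod set."""
        return (self.sequence, self.mods)


def compute_mass(p: Peptidoform, registry_by_id: dict[str, ModificationSpec]) -> float:
    return peptide_neutral_mass(
        p.sequence, [(pos, registry_by_id[mid].delta_mass) for pos, mid in p.mods]
    )


def with_mass(p: Peptidoform, registry_by_id: dict[str, ModificationSpec]) -> Peptidoform:
    return replace(p, neutral_mass=compute_mass(p, registry_by_id))


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cleaves between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 3,
    min_length: int = 6,
    max_length: int = 45,
    semi: bool = False,
) -> list[Peptidoform]:
    """Tryptic digest of one protein into unmodified peptidoforms.

    Fully tryptic peptides span consecutive cleavage sites (protein termini
    included); with ``semi`` true, peptides with exactly one non-tryptic
    terminus are additionally emitted (missed cleavages counted over internal
    sites only).  Coordinates are 1-based inclusive on the protein.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    boundaries = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides: dict[tuple[int, int], Peptidoform] = {}

    def emit(start0: int, end0: int, missed: int) -> None:
        if (start0, end0) in peptides:
            return
        length = end0 - start0
        if not (min_length <= length <= max_length):
            return
        peptides[(start0, end0)] = Peptidoform(
            sequence=seq[start0:end0],
            protein_accession=protein.accession,
            start=start0 + 1,
            end=end0,
            missed_cleavages=missed,
            is_decoy=protein.is_decoy,
        )

    nb = len(boundaries)
    for i in range(nb - 1):
        for j in range(i + 1, min(i + 2 + max_missed, nb)):
            missed = j - i - 1
            start0, end0 = boundaries[i], boundaries[j]
            emit(start0, end0, missed)
            if semi:
                # one ragged terminus: shrink either end inside the segment
                for s in range(start0 + 1, end0):
                    emit(s, end0, missed)
                for e in range(start0 + 1, end0):
                    emit(start0, e, missed)
    return sorted(peptides.values(), key=lambda p: (p.start, p.end))


def enumerate_peptidoforms(
    peptide: Peptidoform,
    registry: Sequence[ModificationSpec],
    max_variable_mods: int = 3,
    cam_mode: str = "fixed",
    combinatorial_cap: int = 10_000,
) -> list[Peptidoform]:
    """All modification assignments of one peptide.

    Fixed carbamidomethylation is applied to every Cys when ``cam_mode`` is
    ``"fixed"`` (and the carbamidomethyl spec is then excluded from variable
    assignment); otherwise it participates as a variable modification.  A
    variable modification assigned to a carbamidomethylated Cys *displaces*
    the fixed modification — both alkylate the thiol, so they are mutually
    exclusive, and search engines reconsider fixed assignments the same way.
    At most one modification per residue; at most ``max_variable_mods``
    variable modifications.  Raises if the enumeration would exceed
    ``combinatorial_cap`` forms.
    """
    if max_variable_mods < 0:
        raise ValueError("max_variable_mods must be >= 0")
    registry_by_id = {m.id: m for m in registry}
    seq = peptide.sequence
    n = len(seq)

    fixed: tuple[tuple[int, str], ...] = ()
    variable_specs = list(registry)
    if cam_mode == "fixed" and "carbamidomethyl" in registry_by_id:
        fixed = tuple((i, "carbamidomethyl") for i in range(1, n + 1) if seq[i - 1] == "C")
        variable_specs = [m for m in registry if m.id != "carbamidomethyl"]
    fixed_positions = {pos for pos, _ in fixed}
    cam_delta = (
        registry_by_id["carbamidomethyl"].delta_mass
        if "carbamidomethyl" in registry_by_id
        else 0.0
    )

    # eligible (position, mod id) assignments; fixed-CAM positions stay
    # eligible and displace the CAM when chosen
    site_options: list[tuple[int, str]] = []
    for i in range(1, n + 1):
        for m in variable_specs:
            if m.applies_to(seq[i - 1], is_n_term=(i == 1), is_c_term=(i == n)):
                site_options.append((i, m.id))

    base_mass = peptide_neutral_mass(
        seq, [(pos, registry_by_id[mid].delta_mass) for pos, mid in fixed]
    )
    base = replace(peptide, fixed_mods=fixed, variable_mods=(), neutral_mass=base_mass)
    forms = [base]
    count = 1
    for k in range(1, max_variable_mods + 1):
        for combo in itertools.combinations(site_options, k):
            positions = {pos for pos, _ in combo}
            if len(positions) != k:
                continue
            count += 1
            if count > combinatorial_cap:
                raise ValueError(
                    f"peptidoform enumeration for {seq!r} exceeds cap "
                    f"{combinatorial_cap}"
                )
            displaced = positions & fixed_positions
            delta = sum(registry_by_id[mid].delta_mass for _, mid in combo)
            delta -= cam_delta * len(displaced)
            forms.append(
                replace(
                    base,
                    fixed_mods=tuple(f for f in fixed if f[0] not in displaced),
                    variable_mods=tuple(sorted(combo)),
                    neutral_mass=base_mass + delta,
                )
            )
    return forms


def pseudo_reverse(sequence: str) -> str:
    """Reverse each tryptic segment in place, keeping C-terminal K/R fixed."""
    sites = cleavage_sites(sequence)
    boundaries = [0] + [i + 1 for i in sites] + [len(sequence)]
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        segment = sequence[a:b]
        if b - 1 in sites or (b == len(sequence) and segment and segment[-1] in "KR"):
            out.append(segment[:-1][::-1] + segment[-1])
        else:
            out.append(segment[::-1])
    return "".join(out)


def make_decoys(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One pseudo-reversed decoy per target protein."""
    return [
        ProteinRecord(
            accession=DECOY_PREFIX + p.accession,
            description=f"decoy of {p.accession}",
            sequence=pseudo_reverse(p.sequence),
            is_decoy=True,
        )
        for p in proteins
        if not p.is_decoy
    ]


def flag_shared_decoy_peptides(
    target_peptides: Iterable[Peptidoform], decoy_peptides: Iterable[Peptidoform]
) -> tuple[list[Peptidoform], set[str]]:
    """Drop decoy peptides whose sequence collides with any target peptide.

    Returns (clean decoy list, set of colliding sequences).  Colliding decoys
    must not enter FDR counting, as they are indistinguishable from targets.
    """
    target_seqs = {p.sequence for p in target_peptides}
    kept, shared = [], set()
    for p in decoy_peptides:
        if p.sequence in target_seqs:
            shared.add(p.sequence)
        else:
            kept.append(p)
    return kept, shared


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA database; accession is the first whitespace token."""
    records = []
    with _pfasta.read(str(path)) as reader:
        for description, sequence in reader:
            parts = description.split(None, 1)
            accession = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            seq = sequence.strip("*").upper()
            bad = set(seq) - CANONICAL_RESIDUES
            if bad:
                warnings.warn(
                    f"{accession}: skipped (non-canonical residues {sorted(bad)})"
                )
                continue
            records.append(
                ProteinRecord(
                    accession=accession,
                    description=desc,
                    sequence=seq,
                    is_decoy=accession.startswith(DECOY_PREFIX),
                )
            )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    entries = [(f"{r.accession} {r.description}".strip(), r.sequence) for r in records]
    with open(path, "w") as fh:
        _pfasta.write(entries, fh)
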