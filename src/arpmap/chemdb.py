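"""Monoisotopic mass arithmetic and the registry of ARP-carbonyl modifications.

The aldehyde reactive probe (ARP, O-(biotinylcarbazoylmethyl)hydroxylamine,
C12H21N5O4S) condenses with aldehyde and keto groups to form an oxime, adding
its own mass minus one water to the carbonylated residue.  Every ARP adduct
mass shift in the registry therefore decomposes as

    delta = base_carbonyl_delta + (mass(ARP) - mass(H2O))

where ``base_carbonyl_delta`` is the mass change of the underlying carbonyl
modification (metal-catalysed oxidation, reactive-carbonyl-species adduct,
glycation, or cyclic imide capture) before derivatization.  The registry
stores deltas at full computed precision; three-decimal literature values are
checks, not stored truth.

All arithmetic is monoisotopic.  Element and residue masses come from
pyteomics' NIST tables.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

PROTON_MASS = 1.00727646677
WATER_MASS = _pmass.calculate_mass(formula="H2O")

#: one-letter code -> monoisotopic residue mass (Da)
RESIDUE_MASSES: dict[str, float] = dict(_pmass.std_aa_mass)
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ElementTable:
    """Element symbol -> monoisotopic mass, backed by the NIST table."""

    def __init__(self) -> None:
        self._masses = {el: iso[0][0] for el, iso in _pmass.nist_mass.items()}
        for required in ("C", "H", "N", "O", "S", "P"):
            if required not in self._masses:
                raise RuntimeError(f"element table missing {required}")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._masses[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._masses


ELEMENTS = ElementTable()


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``C12H21N5O4S``.

    Signed compositions are accepted (e.g. ``O-1`` style is not needed; use
    :func:`composition_delta` for differences).  An empty formula is mass 0.
    """
    if not formula:
        return 0.0
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    unknown = [el for el in comp if el not in ELEMENTS]
    if unknown:
        raise ValueError(f"unknown element symbol(s) {unknown} in {formula!r}")
    return _pmass.calculate_mass(composition=comp)


def composition_delta(gain: str, loss: str = "") -> float:
    """Mass difference ``mass(gain) - mass(loss)`` between two formulas."""
    return formula_mass(gain) - formula_mass(loss)


ARP_FORMULA = "C12H21N5O4S"
ARP_NEUTRAL_MASS = formula_mass(ARP_FORMULA)
#: net mass added by oxime formation with a carbonyl (ARP minus water)
OXIME_ADDITION = ARP_NEUTRAL_MASS - WATER_MASS


@dataclass(frozen=True)
class ArpConstants:
    """Diagnostic masses of the ARP tag.

    Reporter ions are singly charged fragments seen in the low-m/z region of
    CID spectra of derivatized peptides; tag losses are neutral losses from
    precursor and modified y ions.  The reporter/loss values are the standard
    literature values for this tag; the protonated-ARP reporter is also
    required to agree with ``mass(C12H21N5O4S) + proton`` within 1 mDa.
    """

    arp_neutral_formula: str = ARP_FORMULA
    oxime_addition: float = OXIME_ADDITION
    reporter_biotin_mz: float = 227.085
    reporter_arp_fragment_mz: float = 299.117
    reporter_arp_protonated_mz: float = 332.139
    tag_loss_partial: float = 227.085
    tag_loss_full: float = 331.139
    keto_loss: float = 288.126
    lockmass_reference_mz: float = 785.843

    def __post_init__(self) -> None:
        if abs(self.oxime_addition - (formula_mass(self.arp_neutral_formula) - WATER_MASS)) > 1e-3:
            raise ValueError("oxime addition inconsistent with ARP formula")
        if abs(self.reporter_arp_protonated_mz - (formula_mass(self.arp_neutral_formula) + PROTON_MASS)) > 1e-3:
            raise ValueError("[ARP+H]+ reporter inconsistent with ARP formula")


ARP = ArpConstants()


class ReporterProfile(str, Enum):
    """Which ARP diagnostic ions a modification produces under CID.

    FULL_TAG: semialdehyde-type oximes (oxidized Lys/Pro/Arg) show all three
    reporters (227.085 / 299.117 / 332.139) and partial/full tag losses
    (227.085 / 331.139 Da) from precursor and modified y ions.
    BIOTIN_ONLY: keto-type oximes (oxidized Thr/Ser) show only the biotin
    reporter plus a modification-specific 288.126 Da loss from modified y ions.
    BIOTIN_MINIMAL: only the 227.085 biotin reporter is guaranteed.
    """

    FULL_TAG = "FULL_TAG"
    BIOTIN_ONLY = "BIOTIN_ONLY"
    BIOTIN_MINIMAL = "BIOTIN_MINIMAL"


class Provenance(str, Enum):
    literature = "literature"
    formula_derived = "formula_derived"
    user = "user"


class Position(str, Enum):
    any = "any"
    peptide_c_term = "peptide_c_term"
    peptide_n_term = "peptide_n_term"


@dataclass(frozen=True)
class ModificationSpec:
    """One modification: residue specificity, mass delta, fragmentation profile.

    ``base_carbonyl_delta`` is the pre-derivatization carbonyl shift; for
    oxime-type entries (``is_arp`` true) ``delta_mass`` must equal
    ``base_carbonyl_delta + OXIME_ADDITION`` within 1 mDa.  Non-ARP entries
    (carbamidomethylation, Met oxidation) set ``is_arp`` false.
    """

    id: str
    name: str
    target_residues: frozenset[str]
    delta_mass: float
    base_carbonyl_delta: float = 0.0
    reporter_profile: ReporterProfile = ReporterProfile.BIOTIN_MINIMAL
    provenance: Provenance = Provenance.formula_derived
    is_arp: bool = True
    position: Position = Position.any

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise ValueError(f"{self.id}: empty target residue set")
        bad = self.target_residues - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: non-canonical target residues {sorted(bad)}")
        if self.is_arp and abs(
            self.delta_mass - (self.base_carbonyl_delta + OXIME_ADDITION)
        ) > 1e-3:
            raise ValueError(
                f"{self.id}: delta_mass {self.delta_mass:.4f} inconsistent with "
                f"base {self.base_carbonyl_delta:+.4f} + oxime {OXIME_ADDITION:.4f}"
            )

    def applies_to(self, residue: str, *, is_n_term: bool = False, is_c_term: bool = False) -> bool:
        if residue not in self.target_residues:
            return False
        if self.position is Position.peptide_n_term:
            return is_n_term
        if self.position is Position.peptide_c_term:
            return is_c_term
        return True


def arp_adduct_delta(base_carbonyl_delta: float) -> float:
    """Total mass shift after ARP oxime derivatization of a carbonyl.

    The derivatization adds the ARP mass minus one water on top of whatever
    the underlying carbonyl modification itself changed.
    """
    return base_carbonyl_delta + OXIME_ADDITION


def _arp(id_, name, residues, base, profile=ReporterProfile.BIOTIN_MINIMAL,
         provenance=Provenance.formula_derived, position=Position.any) -> ModificationSpec:
    return ModificationSpec(
        id=id_, name=name, target_residues=frozenset(residues),
        delta_mass=arp_adduct_delta(base), base_carbonyl_delta=base,
        reporter_profile=profile, provenance=provenance, is_arp=True,
        position=position,
    )


def builtin_registry() -> list[ModificationSpec]:
    """The shipped modification registry.

    Base carbonyl chemistries, as elemental composition changes of the residue:

    * Lys -> aminoadipic semialdehyde (allysine): side-chain NH2 -> CHO via
      -NH3 +O; also produced as a radical backbone-cleavage product on Ala/Leu.
    * Pro -> glutamic semialdehyde: ring opening, +O.
    * Arg -> glutamic semialdehyde: C6H12N4O residue -> C5H7NO2.
    * Thr -> 2-amino-3-ketobutyric acid / Ser -> keto analogue: -2H.
    * Gln/Asn cyclic imide captured by ARP with ring opening: base +0.984
      (O - NH, the deamidation shift).
    * Glu/Asp cyclic isoimide, ARP ring opening: base 0.
    * RCS Michael/aldoamine adducts on Lys: acrolein +C3H4O, crotonaldehyde
      +C4H6O, malondialdehyde/methylglyoxal +C3H4O2, acetaldehyde aldoamine
      +C2H2O; glycation (Amadori) +C6H10O5.
    * Cys: acrolein Michael adduct +C3H4O; glyoxal adduct, total composition
      +C14H21N5O5S (base +C2H2O2).
    * Met -> side-chain aldehyde (-CH4S +O).
    """
    d = composition_delta
    mods = [
        _arp("lys_semialdehyde", "Lys -> aminoadipic semialdehyde + ARP", "K",
             d("O", "NH3"), ReporterProfile.FULL_TAG),
        _arp("backbone_cleavage_semialdehyde",
             "radical N-terminal backbone cleavage product + ARP (Ala/Leu)",
             "AL", d("O", "NH3"), ReporterProfile.FULL_TAG),
        _arp("pro_glutamic_semialdehyde", "Pro -> glutamic semialdehyde + ARP", "P",
             d("O"), ReporterProfile.FULL_TAG),
        _arp("arg_glutamic_semialdehyde", "Arg -> glutamic semialdehyde + ARP", "R",
             d("C5H7NO2", "C6H12N4O"), ReporterProfile.FULL_TAG),
        _arp("thr_keto", "Thr -> 2-amino-3-ketobutyric acid + ARP", "T",
             d("", "H2"), ReporterProfile.BIOTIN_ONLY),
        _arp("ser_keto", "Ser oxidation product + ARP", "S",
             d("", "H2"), ReporterProfile.BIOTIN_ONLY),
        _arp("lys_oxidation_298", "alternative Lys oxidation product + ARP", "K",
             d("O", "CH5N")),
        _arp("leu_oxidation_313", "alternative Leu oxidation product + ARP", "L",
             d("O", "CH4")),
        _arp("gln_asn_imide", "Gln/Asn cyclic imide + ARP (ring opening)", "QN",
             d("O", "NH")),
        _arp("glu_asp_isoimide", "Glu/Asp cyclic isoimide + ARP (ring opening)", "ED",
             0.0),
        _arp("lys_glycation", "Lys Amadori glycation + ARP", "K", d("C6H10O5")),
        _arp("lys_mda", "Lys malondialdehyde/methylglyoxal Michael adduct + ARP", "K",
             d("C3H4O2")),
        _arp("lys_crotonaldehyde", "Lys crotonaldehyde Michael adduct + ARP", "K",
             d("C4H6O")),
        _arp("lys_acrolein", "Lys acrolein Michael adduct + ARP", "K", d("C3H4O")),
        _arp("lys_aldoamine", "Lys acetaldehyde aldoamine + ARP", "K", d("C2H2O")),
        _arp("cys_acrolein", "Cys acrolein Michael adduct + ARP", "C", d("C3H4O")),
        _arp("cys_glyoxal", "Cys glyoxal adduct + ARP", "C", d("C2H2O2")),
        _arp("met_oxidation_281", "Met side-chain aldehyde + ARP", "M",
             d("O", "CH4S")),
        ModificationSpec(
            id="carbamidomethyl", name="carbamidomethylation (iodoacetamide)",
            target_residues=frozenset("C"), delta_mass=formula_mass("C2H3NO"),
            base_carbonyl_delta=0.0, is_arp=False,
            provenance=Provenance.formula_derived,
        ),
        ModificationSpec(
            id="met_oxidation", name="Met oxidation (sulfoxide)",
            target_residues=frozenset("M"), delta_mass=formula_mass("O"),
            base_carbonyl_delta=0.0, is_arp=False,
            provenance=Provenance.formula_derived,
        ),
    ]
    validate_registry(mods)
    return mods


def validate_registry(registry: Sequence[ModificationSpec]) -> None:
    """Assert registry self-consistency (raises on duplicate ids).

    The per-entry oxime invariant is enforced by ModificationSpec itself.
    """
    ids = [m.id for m in registry]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate modification ids in registry")


def load_registry(path: str | Path) -> list[ModificationSpec]:
    """Load a user registry from TSV or JSON.

    TSV columns: id, name, residues, delta_mass, base_delta, profile.
    JSON: list of objects with the same keys.  Entries are marked provenance
    ``user``; an entry whose delta equals base + oxime within 1 mDa is treated
    as an ARP oxime adduct, anything else as a plain (non-ARP) modification.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    mods = []
    for row in rows:
        base = float(row.get("base_delta", 0.0))
        delta = float(row["delta_mass"])
        mods.append(ModificationSpec(
            id=row["id"], name=row.get("name", row["id"]),
            target_residues=frozenset(row["residues"]),
            delta_mass=delta, base_carbonyl_delta=base,
            reporter_profile=ReporterProfile(row.get("profile", "BIOTIN_MINIMAL")),
            provenance=Provenance.user,
            is_arp=abs(delta - (base + OXIME_ADDITION)) <= 1e-3,
        ))
    validate_registry(mods)
    return mods


def peptide_neutral_mass(sequence: str, mods: Iterable[tuple[int, float]] = ()) -> float:
    """Neutral monoisotopic mass of a peptide with localized mass deltas.

    ``mods`` is an iterable of (1-based position, delta in Da).
    """
    total = WATER_MASS
    for res in sequence:
        try:
            total += RESIDUE_MASSES[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} in {sequence!r}") from None
    n = len(sequence)
    for pos, delta in mods:
        if not 1 <= pos <= n:
            raise ValueError(f"mod position {pos} outside 1..{n} for {sequence!r}")
        total += delta
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated species: (M + z * proton) / z."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_mass`."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS


def find_isobaric_conflicts(
    registry: Sequence[ModificationSpec],
    tolerance: float = 0.005,
    max_combination: int = 2,
) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Find modification (combinations) indistinguishable by total mass.

    Compares every single modification and every unordered pair of
    modifications against every other, and reports sides whose summed deltas
    differ by at most ``tolerance`` Da.  The classic conflict in this registry
    is the Cys glyoxal ARP adduct versus carbamidomethyl-Cys plus a Gln/Asn
    imide ARP adduct, whose elemental compositions sum identically.

    Returns (ids_a, ids_b, |mass difference|) with ids sorted within each
    side; self-pairs and pairs sharing an identical multiset of ids excluded.
    """
    if not registry:
        raise ValueError("empty registry")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    combos: list[tuple[tuple[str, ...], float]] = []
    for r in range(1, max_combination + 1):
        for combo in itertools.combinations_with_replacement(registry, r):
            ids = tuple(sorted(m.id for m in combo))
            combos.append((ids, sum(m.delta_mass for m in combo)))
    conflicts = []
    for (ids_a, mass_a), (ids_b, mass_b) in itertools.combinations(combos, 2):
        if ids_a == ids_b:
            continue
        diff = abs(mass_a - mass_b)
        if diff <= tolerance:
            conflicts.append((ids_a, ids_b, diff))
    conflicts.sort(key=lambda c: (c[2], c[0], c[1]))
    return conflicts
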