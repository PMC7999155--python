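"""Bundled protein panel for the synthetic-data generator.

``HSA_FRAGMENT`` is a synthetic protein assembled from tryptic regions of
mature human serum albumin (UniProt P02768, signal/pro-peptide removed),
chosen so that the panel contains the carbonylation-hotspot peptides studied
in the ARP literature: LKCASLQK (Lys199 region), LCTVATLR (Thr79 region),
YICENQDSISSKLK and LKECCEKPLLEK (Lys276/Cys278/Cys279 region).  It is not
the full-length protein.

``STICKY_BACKGROUND`` carries an HPY motif, emulating non-derivatized
peptides that survive avidin enrichment through high-affinity binding of
that sequence motif.  The remaining background proteins are synthetic
sequences (no natural counterpart) generated once from a fixed seed.
"""

from __future__ import annotations

from .insilico import ProteinRecord

# mature-HSA tryptic regions, concatenated (synthetic assembly)
_HSA_FRAGMENT_SEQ = (
    "DAHKSEVAHRFKDLGEENFKALVLIAFAQYLQQCPFEDHVKLVNEVTEFAK"
    "SLHTLFGDKLCTVATLRETYGEMADCCAK"
    "ASSAKQRLKCASLQKFGER"
    "ADLAKYICENQDSISSKLKECCEKPLLEKSHCIAEVENDEMPADLPSLAADFVESK"
)

_STICKY_SEQ = (
    "MGSDLEHPYFSAKTLVEGNQWDRAHPYLLNKEVSTGADFKQPLMNHPYVESRGTWLDAK"
    "NSVEQFPLRGDTYAMKWESLHNPVR"
)

_BACKGROUND_SEQS = {
    "BG001": (
        "MTEVLSGNDAKWQPFHLVESRGYTDNMAKSLPEVGFDTRWNQHLESVAKGDYPTMLNSR"
        "EVFAGQWDKTLSHPNEVGRMDYFSLQAK"
    ),
    "BG002": (
        "MSVLDPETGAKFNQWYHESRLVTGMDNPAKEGSFLQVDTRYWNMHLESAKVGDPTFLQSR"
        "TEVMAGQWDKSLYHPNEVGR"
    ),
    "BG003": (
        "MAEVTLSGPDKWNQFYHLESRGVTDMNPAKSLEPVGFDTRQWNYHLESVAKDGYPTMLNSR"
        "EVFAGQWDKTLSHPNEWGR"
    ),
}


def protein_panel() -> list[ProteinRecord]:
    """The bundled panel: HSA-derived fragment + sticky + synthetic background."""
    records = [
        ProteinRecord(
            accession="HSA_FRAGMENT",
            description="synthetic assembly of mature-HSA tryptic regions",
            sequence=_HSA_FRAGMENT_SEQ,
        ),
        ProteinRecord(
            accession="STICKY_HPY",
            description="synthetic background protein with avidin-binding HPY motif",
            sequence=_STICKY_SEQ,
        ),
    ]
    for acc, seq in _BACKGROUND_SEQS.items():
        records.append(
            ProteinRecord(
                accession=acc, description="synthetic background protein", sequence=seq
            )
        )
    return records
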