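"""Translation table 4 (Mold/Protozoan/Coelenterate mitochondrial code) helpers.

Under table 4 only TAA and TAG are stop codons; TGA encodes tryptophan.
"""

from __future__ import annotations

from Bio.Data import CodonTable

TABLE_ID = 4
_TABLE = CodonTable.unambiguous_dna_by_id[TABLE_ID]

STOP_CODONS = frozenset(_TABLE.stop_codons)  # {"TAA", "TAG"}
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

NUCLEOTIDES = ("A", "C", "G", "T")


def codons_of(seq: str) -> list[str]:
    """Split into codons, discarding a trailing incomplete codon."""
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def translate(seq: str, to_stop: bool = False) -> str:
    """Translate a CDS under table 4; ambiguous codons become 'X'."""
    out = []
    for codon in codons_of(seq):
        aa = CODON_TO_AA.get(codon, "X")
        if aa == "*" and to_stop:
            break
        out.append(aa)
    return "".join(out)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """True when both codons are sense codons for the same amino acid."""
    aa, bb = CODON_TO_AA.get(codon_a), CODON_TO_AA.get(codon_b)
    return aa is not None and aa == bb and aa != "*"
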