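"""Thin wrappers around pairwise alignment with identity/coverage accounting.

Dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`; this
module owns the bookkeeping the pipeline's acceptance rules need: match
counts, alignment columns, aligned spans on each sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

# Default nucleotide scoring (megablast-like): match +2, mismatch -3,
# gap open 5, gap extend 2 (penalties).
DNA_SCORING = {"match": 2.0, "mismatch": -3.0, "gap_open": -5.0, "gap_extend": -2.0}
PROTEIN_SCORING = {"matrix": "BLOSUM62", "gap_open": -11.0, "gap_extend": -1.0}


@dataclass
class AlignmentResult:
    score: float
    matches: int
    columns: int
    a_span: tuple[int, int]  # aligned half-open span on sequence a
    b_span: tuple[int, int]

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _dna_aligner(mode: str, scoring: dict | None = None) -> Align.PairwiseAligner:
    sc = dict(DNA_SCORING)
    if scoring:
        sc.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    return aligner


def _protein_aligner(mode: str, scoring: dict | None = None) -> Align.PairwiseAligner:
    sc = dict(PROTEIN_SCORING)
    if scoring:
        sc.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(sc["matrix"])
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    return aligner


def _summarize(a: str, b: str, alignment) -> AlignmentResult:
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return AlignmentResult(score=float(alignment.score), matches=0, columns=0,
                               a_span=(0, 0), b_span=(0, 0))
    matches = 0
    aligned_cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        seg_a, seg_b = a[sa:ea], b[sb:eb]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        aligned_cols += ea - sa
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    # Columns include internal gap columns between aligned blocks.
    gap_cols = (a_span[1] - a_span[0] - aligned_cols) + (b_span[1] - b_span[0] - aligned_cols)
    return AlignmentResult(
        score=float(alignment.score),
        matches=matches,
        columns=aligned_cols + gap_cols,
        a_span=a_span,
        b_span=b_span,
    )


def local_dna(a: str, b: str, scoring: dict | None = None) -> AlignmentResult:
    """Best local (Smith–Waterman) DNA alignment of ``a`` vs ``b``."""
    aligner = _dna_aligner("local", scoring)
    alignment = next(iter(aligner.align(a, b)))
    return _summarize(a, b, alignment)


def local_protein(a: str, b: str, scoring: dict | None = None) -> AlignmentResult:
    """Best local protein alignment under BLOSUM62 (default)."""
    aligner = _protein_aligner("local", scoring)
    alignment = next(iter(aligner.align(a, b)))
    return _summarize(a, b, alignment)


def local_protein_score(a: str, b: str, scoring: dict | None = None) -> float:
    """Score only (cheaper than building the alignment path)."""
    aligner = _protein_aligner("local", scoring)
    return float(aligner.score(a, b))


def global_protein(a: str, b: str, scoring: dict | None = None):
    """Best global protein alignment; returns the Biopython alignment object."""
    aligner = _protein_aligner("global", scoring)
    return next(iter(aligner.align(a, b)))


def shares_kmer(a: str, b: str, k: int = 11) -> bool:
    """Exact shared k-mer prefilter used before quadratic alignment."""
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))
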