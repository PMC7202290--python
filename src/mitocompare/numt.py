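"""Detection of mitochondrial gene transfers into nuclear contigs (NUMTs).

Each protein-coding mitochondrial gene is translated under table 4 and
searched against all six reading frames of every nuclear contig by local
protein alignment (BLOSUM62); the rRNA genes are searched at the nucleotide
level on both strands.  A hit is reported as a putative NUMT when it shows
at least 50% identity, at least 50% coverage of the mitochondrial query,
and an expectation value below 1e-10.

Expectation values are empirical: the query is re-scored against shuffled
contig sequence, the null scores are fitted to a Gumbel (extreme value)
distribution, and E = (search-space factor) x P(score >= observed) under the
fit.  Because the three gates are conjunctive, E is only computed for
candidates that already pass the identity/coverage rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import align
from .genetics import translate
from .records import GenomeRecord, NuclearContigSet, reverse_complement

logger = logging.getLogger(__name__)

NUMT_MIN_IDENTITY = 50.0   # percent, inclusive ("at least 50%")
NUMT_MIN_COVERAGE = 50.0
NUMT_MAX_EVALUE = 1e-10
DEFAULT_NULLS = 100
DEFAULT_NULL_SUBJECT_NT = 2000  # capped null-subject length; None = full contig
PRESCREEN_K_PROTEIN = 6    # shared exact aa k-mer required before protein DP
PRESCREEN_K_NT = 14        # shared exact nt k-mer required before DNA DP


@dataclass
class NumtHit:
    gene: str
    mode: str  # "protein" or "nucleotide"
    contig: str
    contig_interval: tuple[int, int]  # nucleotide coordinates on the contig
    strand: str
    identity: float
    coverage: float
    score: float
    evalue: float | None
    flags: list[str] = field(default_factory=list)


def fit_gumbel(scores) -> tuple[float, float]:
    """Fit a right-skewed Gumbel to null scores; returns (location, scale)."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise ValueError("fit_gumbel: degenerate null (zero variance)")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(scale)


def empirical_evalue(
    score: float,
    query: str,
    contigs: NuclearContigSet,
    mode: str = "protein",
    nulls: int = DEFAULT_NULLS,
    seed: int = 0,
    null_subject_nt: int | None = DEFAULT_NULL_SUBJECT_NT,
    scoring: dict | None = None,
) -> float | None:
    """Empirical expectation value of an alignment score.

    ``nulls`` independently shuffled contig stretches are re-scored against
    the query; a Gumbel fit to the null scores gives the exceedance
    probability, scaled by the ratio of the true search space (total contig
    length, both strands / six frames) to the null subject length.
    Deterministic for a given ``seed``.  Returns ``None`` on a degenerate
    (zero-variance) null, with a warning.
    """
    if nulls < 10:
        raise ValueError("empirical_evalue: need at least 10 null shuffles")
    rng = np.random.default_rng(seed)
    concat = "".join(contigs.contigs[c] for c in sorted(contigs.contigs))
    total_nt = len(concat)
    m = total_nt if null_subject_nt is None else min(null_subject_nt, total_nt)
    base = np.frombuffer(concat.encode(), dtype=np.uint8)
    null_scores = np.empty(nulls)
    for i in range(nulls):
        start = int(rng.integers(0, max(1, total_nt - m + 1)))
        window = base[start:start + m].copy()
        rng.shuffle(window)
        subject_nt = window.tobytes().decode()
        if mode == "protein":
            subject = translate(subject_nt)
            null_scores[i] = align.local_protein_score(query, subject, scoring)
        else:
            null_scores[i] = align.local_dna(query, subject_nt, scoring).score
    try:
        loc, scale = fit_gumbel(null_scores)
    except ValueError:
        logger.warning("empirical_evalue: degenerate null; E-value undefined")
        return None
    exceed = float(stats.gumbel_r.sf(score, loc=loc, scale=scale))
    factor = 2.0 * total_nt / m  # both strands, extrapolated to the full space
    return factor * exceed


def _frames(contig: str) -> list[tuple[str, str, int]]:
    """Six-frame translations: (strand, protein, frame offset)."""
    out = []
    rc = reverse_complement(contig)
    for off in range(3):
        out.append(("+", translate(contig[off:]), off))
        out.append(("-", translate(rc[off:]), off))
    return out


def _protein_hit_interval(strand: str, offset: int, span_aa: tuple[int, int], L: int) -> tuple[int, int]:
    s_nt = offset + 3 * span_aa[0]
    e_nt = offset + 3 * span_aa[1]
    if strand == "+":
        return s_nt, e_nt
    return L - e_nt, L - s_nt


def find_numts(
    g: GenomeRecord,
    nuc: NuclearContigSet,
    nulls: int = DEFAULT_NULLS,
    seed: int = 0,
    scoring: dict | None = None,
    min_identity: float = NUMT_MIN_IDENTITY,
    min_coverage: float = NUMT_MIN_COVERAGE,
    max_evalue: float = NUMT_MAX_EVALUE,
    prescreen: bool = True,
) -> list[NumtHit]:
    """Putative NUMTs of ``g``'s core genes in nuclear contigs.

    The best hit per (gene, contig, strand/frame) is considered; hits
    passing identity >= 50, coverage >= 50 and E < 1e-10 are returned.
    If the empirical null is degenerate the E-value is reported missing
    and the hit is kept on the identity/coverage rules alone (flagged).
    """
    queries: list[tuple[str, str, str]] = []  # (gene, mode, query sequence)
    seen = set()
    for f in g.features:
        if f.kind == "protein_gene" and f.name not in seen:
            cds = g.spliced_sequence(f)
            if len(cds) < 3:
                logger.warning("%s: gene %s too short to translate; skipped", g.id, f.name)
                continue
            prot = translate(cds).rstrip("*")
            if prot:
                queries.append((f.name, "protein", prot))
                seen.add(f.name)
        elif f.kind == "rRNA" and f.name not in seen:
            queries.append((f.name, "nucleotide", g.spliced_sequence(f)))
            seen.add(f.name)
    hits: list[NumtHit] = []
    for gene, mode, query in queries:
        for cid in sorted(nuc.contigs):
            contig = nuc.contigs[cid]
            best: NumtHit | None = None
            if mode == "protein":
                for strand, prot, off in _frames(contig):
                    if not prot:
                        continue
                    if prescreen and not align.shares_kmer(query, prot, PRESCREEN_K_PROTEIN):
                        continue
                    res = align.local_protein(query, prot, scoring)
                    if res.columns == 0:
                        continue
                    cov = 100.0 * (res.a_span[1] - res.a_span[0]) / len(query)
                    cand = NumtHit(
                        gene=gene, mode=mode, contig=cid,
                        contig_interval=_protein_hit_interval(strand, off, res.b_span, len(contig)),
                        strand=strand, identity=res.identity_pct, coverage=cov,
                        score=res.score, evalue=None,
                    )
                    if best is None or cand.score > best.score:
                        best = cand
            else:
                for strand, subject in (("+", contig), ("-", reverse_complement(contig))):
                    if prescreen and not align.shares_kmer(query, subject, PRESCREEN_K_NT):
                        continue
                    res = align.local_dna(query, subject, scoring)
                    if res.columns == 0:
                        continue
                    cov = 100.0 * (res.a_span[1] - res.a_span[0]) / len(query)
                    iv = res.b_span if strand == "+" else (len(contig) - res.b_span[1],
                                                           len(contig) - res.b_span[0])
                    cand = NumtHit(
                        gene=gene, mode=mode, contig=cid, contig_interval=iv,
                        strand=strand, identity=res.identity_pct, coverage=cov,
                        score=res.score, evalue=None,
                    )
                    if best is None or cand.score > best.score:
                        best = cand
            if best is None:
                continue
            if best.identity >= min_identity and best.coverage >= min_coverage:
                best.evalue = empirical_evalue(
                    best.score, query, nuc, mode=mode, nulls=nulls, seed=seed,
                    scoring=scoring,
                )
                if best.evalue is None:
                    best.flags.append("evalue_undefined_degenerate_null")
                    hits.append(best)
                elif best.evalue < max_evalue:
                    hits.append(best)
    return hits
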