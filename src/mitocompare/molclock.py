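"""Synonymous divergence (dS) on the mitochondrion-exclusive genes and its
correlations with genome architecture.

The three genes that never transfer to the nucleus in Hypocreales —
atp8, atp9 and cox3 — are concatenated per species, codon-aligned, and
compared pairwise with the Nei–Gojobori (1986) counting method under
translation table 4, with Jukes–Cantor correction:

    dS = -(3/4) * ln(1 - (4/3) * ps),    ps = Sd / S

Synonymous site fractions per codon enumerate all nine single-nucleotide
changes; changes creating a stop codon (TAA/TAG) are excluded from the
denominator.  Codon pairs differing at two or three positions average the
synonymous/nonsynonymous step counts over all minimal mutational pathways
that avoid stop codons (equal weights; if every pathway passes through a
stop, all pathways are used).  Per-species mean dS is

    dS_bar = sum of the species' pairwise dS / (n - 1)

with saturated (undefined) pairs excluded and the denominator adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from . import align
from .genetics import NUCLEOTIDES, codons_of, is_stop, is_synonymous, translate
from .records import GenomeRecord

logger = logging.getLogger(__name__)

CLOCK_GENES = ("atp8", "atp9", "cox3")


@dataclass
class DsResult:
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    dS: float | None
    dN: float | None
    codons: int
    flags: list[str] = field(default_factory=list)


@dataclass
class MeanDs:
    species: str
    ds_bar: float
    n: int
    pairs_used: int
    flags: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    r: float | None
    p: float | None
    n: int


def concat_clock_genes(g: GenomeRecord) -> str:
    """Spliced, strand-corrected CDS of atp8 + atp9 + cox3, in that order.

    Raises ``KeyError`` naming the first missing gene; a trailing incomplete
    codon on any gene is trimmed with a warning.
    """
    parts = []
    for gene in CLOCK_GENES:
        feats = [f for f in g.features if f.kind == "protein_gene" and f.name == gene]
        if not feats:
            raise KeyError(f"{g.id}: clock gene {gene!r} missing")
        seq = g.spliced_sequence(feats[0])
        if len(seq) % 3:
            logger.warning("%s: %s length %d not divisible by 3; trimming", g.id, gene, len(seq))
            seq = seq[: len(seq) - len(seq) % 3]
        parts.append(seq)
    return "".join(parts)


def codon_align(a: str, b: str) -> tuple[str, str]:
    """Codon-aware global alignment of two in-frame CDS.

    The translated sequences are globally aligned (BLOSUM62) and the gaps
    back-mapped onto codons, so gaps only open in multiples of three at
    codon boundaries.  Returns the two gapped nucleotide strings.
    """
    if not a or not b:
        raise ValueError("codon_align: empty input")
    if len(a) % 3 or len(b) % 3:
        raise ValueError("codon_align: lengths must be divisible by 3")
    pa, pb = translate(a), translate(b)
    alignment = align.global_protein(pa, pb)
    ca, cb = codons_of(a), codons_of(b)
    out_a, out_b = [], []
    ia = ib = 0
    sa, sb = alignment[0], alignment[1]
    for x, y in zip(sa, sb):
        if x == "-":
            out_a.append("---")
        else:
            out_a.append(ca[ia])
            ia += 1
        if y == "-":
            out_b.append("---")
        else:
            out_b.append(cb[ib])
            ib += 1
    return "".join(out_a), "".join(out_b)


def syn_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3, NG86 convention).

    Per position: (synonymous single-nucleotide changes) / (changes not
    creating a stop codon).
    """
    if is_stop(codon) or any(c not in NUCLEOTIDES for c in codon):
        raise ValueError(f"syn_sites: not a sense codon: {codon!r}")
    total = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if is_stop(alt):
                continue
            possible += 1
            if is_synonymous(codon, alt):
                syn += 1
        if possible:
            total += syn / possible
    return total


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over minimal pathways.

    Pathways passing through a stop codon are excluded; if all are blocked,
    all pathways are averaged (standard NG86 fallback).
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != cb:
                blocked = True
            if is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, blk in paths if not blk]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def ng86_pairwise(aligned_a: str, aligned_b: str, pair: tuple[str, str] = ("a", "b")) -> DsResult:
    """Nei–Gojobori dS/dN from a codon-aligned pair under table 4.

    Columns containing a gap, an ambiguity or a stop codon are excluded from
    counting.  ``dS`` is ``None`` (flagged ``saturated``) when ps >= 3/4.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("ng86_pairwise: aligned lengths differ")
    S = N = Sd = Nd = 0.0
    ncodon = 0
    for ca, cb in zip(codons_of(aligned_a), codons_of(aligned_b)):
        if "-" in ca or "-" in cb:
            continue
        if any(c not in NUCLEOTIDES for c in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        ncodon += 1
        S += (syn_sites(ca) + syn_sites(cb)) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if ncodon == 0:
        raise ValueError("ng86_pairwise: no comparable codon columns")
    N = 3.0 * ncodon - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    flags = []

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None
        return -0.75 * float(np.log(1.0 - (4.0 / 3.0) * p))

    dS = jc(ps)
    dN = jc(pn)
    if dS is None:
        flags.append("saturated_dS")
    if dN is None:
        flags.append("saturated_dN")
    return DsResult(pair=pair, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                    dS=dS, dN=dN, codons=ncodon, flags=flags)


def pairwise_ds_matrix(genomes: list[GenomeRecord]) -> tuple[pd.DataFrame, dict]:
    """dS for every species pair on the concatenated clock genes.

    Species missing any clock gene are excluded with a logged reason.
    Returns a square DataFrame (NaN where undefined) and the raw results.
    """
    seqs: dict[str, str] = {}
    for g in genomes:
        sp = g.species or g.id
        try:
            seqs[sp] = concat_clock_genes(g)
        except KeyError as exc:
            logger.warning("clock: excluding %s (%s)", sp, exc)
    species = sorted(seqs)
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    results: dict[tuple[str, str], DsResult] = {}
    for sa, sb in combinations(species, 2):
        aa, ab = codon_align(seqs[sa], seqs[sb])
        res = ng86_pairwise(aa, ab, pair=(sa, sb))
        results[(sa, sb)] = res
        if res.dS is not None:
            mat.loc[sa, sb] = mat.loc[sb, sa] = res.dS
    for sp in species:
        mat.loc[sp, sp] = 0.0
    return mat, results


def mean_ds(ds_matrix: pd.DataFrame, species: str) -> MeanDs:
    """Mean pairwise dS of one species: sum of its pairwise dS over n - 1.

    Saturated/undefined pairs are excluded and the denominator adjusted
    (flagged).  Requires at least two species in the matrix.
    """
    if species not in ds_matrix.index:
        raise KeyError(f"mean_ds: unknown species {species!r}")
    n = len(ds_matrix.index)
    if n < 2:
        raise ValueError("mean_ds: need at least two species")
    others = [sp for sp in ds_matrix.index if sp != species]
    vals = ds_matrix.loc[species, others].astype(float)
    defined = vals.dropna()
    flags = []
    if len(defined) < len(others):
        flags.append(f"excluded_{len(others) - len(defined)}_undefined_pairs")
    denom = len(defined)
    if denom == 0:
        raise ValueError(f"mean_ds: no defined pairs for {species!r}")
    return MeanDs(species=species, ds_bar=float(defined.sum()) / denom,
                  n=n, pairs_used=denom, flags=flags)


def correlate(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value (t transform, n-2 df).

    Raw p-values are reported without multiplicity adjustment.  Zero
    variance in either vector leaves r undefined (``None``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("correlate: x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("correlate: need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlate: non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(variables=variables, r=None, p=None, n=len(x))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(variables=variables, r=float(r), p=float(p), n=len(x))
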