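"""Circular gene order, displaced genes, within-genome duplications and ORF
intactness.

Gene order is read by traversing the circle from the 5' end of rrnL on rrnL's
strand, so it is invariant under rotation of the underlying record and under
double reverse complement.  Duplicated gene copies are compared by local
alignment; a pair counts as a duplication when identity and coverage are both
at least 50% (coverage measured on the shorter copy).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import align
from .genetics import STOP_CODONS, codons_of
from .records import CORE_GENES, FeatureRecord, GenomeRecord

logger = logging.getLogger(__name__)

DUPLICATION_MIN_IDENTITY = 50.0  # percent, inclusive ("at least 50%")
DUPLICATION_MIN_COVERAGE = 50.0

DEFAULT_START_CODONS = ("ATG",)


@dataclass
class GeneOrder:
    genome_id: str
    order: list[str]
    fragmented: set[str] = field(default_factory=set)
    anchored_on: str = "rrnL"


@dataclass
class DuplicatePair:
    gene: str
    copy_a: str
    copy_b: str
    identity: float
    coverage: float
    intact_a: bool | None
    intact_b: bool | None


def _is_core(f: FeatureRecord) -> bool:
    return f.kind in ("protein_gene", "rRNA") and f.name in CORE_GENES


def _five_prime(f: FeatureRecord) -> int:
    s, e = f.intervals[0]
    return s if f.strand == "+" else e - 1


def _is_fragmented(f: FeatureRecord, L: int, circular: bool) -> bool:
    """More than one exon, not explained by an origin wrap on a circular map."""
    if len(f.intervals) <= 1:
        return False
    ivs = sorted(f.intervals)
    merged = 1
    for i in range(1, len(ivs)):
        if ivs[i][0] > ivs[i - 1][1]:
            merged += 1
    if circular and ivs[0][0] == 0 and ivs[-1][1] == L:
        merged -= 1  # blocks touching both ends are contiguous across the origin
    return merged > 1


def gene_order(g: GenomeRecord) -> GeneOrder:
    """Circular core-gene order anchored on the 5' end of rrnL.

    If rrnL lies on the minus strand the genome is reverse complemented
    first; if rrnL is absent the order is anchored on the lexicographically
    smallest core gene present and a warning is logged.
    """
    core = [f for f in g.features if _is_core(f)]
    if not core:
        return GeneOrder(genome_id=g.id, order=[], anchored_on="")
    rrnl = [f for f in core if f.name == "rrnL"]
    if rrnl and rrnl[0].strand == "-":
        return gene_order(g.reverse_complement())
    if rrnl:
        anchor_feat = rrnl[0]
    else:
        anchor_name = min(f.name for f in core)
        anchor_feat = min((f for f in core if f.name == anchor_name), key=_five_prime)
        logger.warning("%s: rrnL absent; gene order anchored on %s", g.id, anchor_name)
    anchor = _five_prime(anchor_feat)
    L = g.length
    ordered = sorted(core, key=lambda f: ((_five_prime(f) - anchor) % L, f.name))
    circular = g.topology == "circular"
    fragmented = {f.name for f in core if _is_fragmented(f, L, circular)}
    return GeneOrder(
        genome_id=g.id,
        order=[f.name for f in ordered],
        fragmented=fragmented,
        anchored_on=anchor_feat.name,
    )


def orf_intact(seq: str, start_codons: tuple[str, ...] = DEFAULT_START_CODONS) -> bool:
    """True iff the sequence is an intact ORF under translation table 4.

    Requires a start codon (default ATG) and no internal stop; TGA encodes
    tryptophan under table 4 so only TAA/TAG terminate.  A trailing
    incomplete codon is trimmed with a logged warning; a terminal stop codon
    is permitted.
    """
    if not seq:
        raise ValueError("orf_intact: empty sequence")
    if len(seq) % 3:
        logger.warning("orf_intact: trimming %d trailing nt of incomplete codon", len(seq) % 3)
    codons = codons_of(seq)
    if not codons or codons[0] not in start_codons:
        return False
    return not any(c in STOP_CODONS for c in codons[1:-1])


def find_duplicate_genes(
    g: GenomeRecord,
    min_identity: float = DUPLICATION_MIN_IDENTITY,
    min_coverage: float = DUPLICATION_MIN_COVERAGE,
) -> list[DuplicatePair]:
    """Within-genome duplicated core genes at >=50% identity and coverage.

    Coverage is the aligned span of the shorter copy over its length — the
    conservative reading when copies differ in size.  Protein-gene copies
    additionally carry ORF-intactness flags; rRNA copies carry ``None``.
    """
    groups: dict[str, list[FeatureRecord]] = {}
    for f in g.features:
        if _is_core(f):
            groups.setdefault(f.name, []).append(f)
    pairs: list[DuplicatePair] = []
    for name, feats in sorted(groups.items()):
        if len(feats) < 2:
            continue
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                fa, fb = feats[i], feats[j]
                sa, sb = g.spliced_sequence(fa), g.spliced_sequence(fb)
                res = align.local_dna(sa, sb)
                if res.columns == 0:
                    continue
                short_len = min(len(sa), len(sb))
                short_span = res.a_span if len(sa) <= len(sb) else res.b_span
                coverage = 100.0 * (short_span[1] - short_span[0]) / short_len
                identity = res.identity_pct
                if identity >= min_identity and coverage >= min_coverage:
                    is_cds = fa.kind == "protein_gene"
                    pairs.append(
                        DuplicatePair(
                            gene=name,
                            copy_a=fa.feature_id or f"{name}.{i}",
                            copy_b=fb.feature_id or f"{name}.{j}",
                            identity=identity,
                            coverage=coverage,
                            intact_a=orf_intact(sa) if is_cds else None,
                            intact_b=orf_intact(sb) if is_cds else None,
                        )
                    )
    return pairs


def _neighbor_sets(order: list[str]) -> dict[str, set[str]]:
    n = len(order)
    nbrs: dict[str, set[str]] = {}
    for i, name in enumerate(order):
        nbrs.setdefault(name, set()).update({order[(i - 1) % n], order[(i + 1) % n]})
    return nbrs


def compare_orders(orders: list[GeneOrder]) -> pd.DataFrame:
    """Displaced genes per genome relative to the consensus circular order.

    The consensus is the most frequent arrangement; a gene is displaced in a
    genome when its circular neighbor set differs from the consensus one.
    When every arrangement is unique the consensus is undefined: every gene
    of every genome is reported and a warning is logged.
    """
    if len(orders) < 2:
        raise ValueError("compare_orders: need at least two gene orders")
    tally = Counter(tuple(o.order) for o in orders)
    top, top_count = tally.most_common(1)[0]
    rows = []
    if top_count == 1:
        logger.warning("compare_orders: all %d arrangements unique; consensus undefined", len(orders))
        for o in orders:
            for name in dict.fromkeys(o.order):
                rows.append({"genome_id": o.genome_id, "gene": name, "consensus": False})
        return pd.DataFrame(rows, columns=["genome_id", "gene", "consensus"])
    consensus_nbrs = _neighbor_sets(list(top))
    for o in orders:
        if tuple(o.order) == top:
            continue
        nbrs = _neighbor_sets(o.order)
        for name in dict.fromkeys(o.order):
            if name not in consensus_nbrs or nbrs[name] != consensus_nbrs[name]:
                rows.append({"genome_id": o.genome_id, "gene": name, "consensus": True})
    return pd.DataFrame(rows, columns=["genome_id", "gene", "consensus"])


def orders_table(orders: list[GeneOrder]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": [o.genome_id for o in orders],
            "anchored_on": [o.anchored_on for o in orders],
            "order": [",".join(o.order) for o in orders],
            "fragmented": [",".join(sorted(o.fragmented)) for o in orders],
        }
    )
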