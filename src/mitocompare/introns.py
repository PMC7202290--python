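"""Intron similarity/sharing network and insertion-site conservation.

Two introns are *similar* when a local alignment covers more than 60% of one
of them with more than 50% identity (the rule is applied in both directions
and passes if either does).  Passing pairs form the edges of a sharing
graph whose labels record the relation of the endpoints:

* ``shared`` — the introns live in different species;
* ``translocation`` — the introns live in different host genes;
* ``duplication`` — the introns live in the same species.

Labels are not exclusive (a cross-species, cross-gene edge is both shared
and a translocation).  Insertion sites are characterized by the 11 exonic
nucleotides that precede the intron in the spliced host gene; sites whose
flanks differ by at most one substitution (Hamming distance) are grouped by
single linkage, and a group containing at least two species is a conserved
insertion-position event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from . import align
from .records import FeatureRecord, GenomeRecord

logger = logging.getLogger(__name__)

SIMILARITY_MIN_COVERAGE = 60.0  # percent, exclusive ("higher than")
SIMILARITY_MIN_IDENTITY = 50.0
FLANK_LENGTH = 11
FLANK_MAX_MISMATCH = 1


@dataclass
class IntronInfo:
    """One annotated intron lifted out of its genome for network analysis."""

    intron_id: str
    species: str
    genome_id: str
    host_gene: str | None
    intron_class: str
    sequence: str


@dataclass
class SimilarityHit:
    query: str
    subject: str
    identity: float
    coverage: float  # of the query
    coverage_subject: float
    score: float
    passed: bool


@dataclass
class FlankRecord:
    intron_id: str
    species: str
    host_gene: str
    offset: int  # exonic insertion offset from the spliced-gene 5' end
    flank: str
    padded: bool = False


def collect_introns(genomes: list[GenomeRecord]) -> list[IntronInfo]:
    """Lift every annotated intron with its context out of the genomes."""
    out = []
    for g in genomes:
        for i, f in enumerate(g.features):
            if f.kind != "intron":
                continue
            out.append(
                IntronInfo(
                    intron_id=f.feature_id or f"{g.id}.intron{i}",
                    species=g.species or g.id,
                    genome_id=g.id,
                    host_gene=f.parent,
                    intron_class=f.intron_class,
                    sequence=g.spliced_sequence(f),
                )
            )
    return out


def pairwise_similarity(
    a: str,
    b: str,
    scoring: dict | None = None,
    prefilter: bool = True,
    prefilter_k: int = 11,
    min_coverage: float = SIMILARITY_MIN_COVERAGE,
    min_identity: float = SIMILARITY_MIN_IDENTITY,
) -> SimilarityHit:
    """Local-alignment similarity of two intron sequences.

    ``coverage`` is the aligned span over the query (``a``); the acceptance
    rule (coverage > 60 and identity > 50) is evaluated on both sequences
    and passes if either direction passes.  With ``prefilter`` enabled,
    pairs without a shared exact 11-mer short-circuit to a non-hit, which
    is sound in the >50% identity regime the rule targets.
    """
    if not a or not b:
        raise ValueError("pairwise_similarity: empty sequence")
    if prefilter and not align.shares_kmer(a, b, prefilter_k):
        return SimilarityHit(query="a", subject="b", identity=0.0, coverage=0.0,
                             coverage_subject=0.0, score=0.0, passed=False)
    res = align.local_dna(a, b, scoring)
    cov_a = 100.0 * (res.a_span[1] - res.a_span[0]) / len(a)
    cov_b = 100.0 * (res.b_span[1] - res.b_span[0]) / len(b)
    ident = res.identity_pct
    passed = ((cov_a > min_coverage and ident > min_identity)
              or (cov_b > min_coverage and ident > min_identity))
    return SimilarityHit(query="a", subject="b", identity=ident, coverage=cov_a,
                         coverage_subject=cov_b, score=res.score, passed=passed)


def build_sharing_graph(
    introns: list[IntronInfo],
    scoring: dict | None = None,
    prefilter: bool = True,
    min_coverage: float = SIMILARITY_MIN_COVERAGE,
    min_identity: float = SIMILARITY_MIN_IDENTITY,
) -> nx.Graph:
    """All-vs-all similarity network over annotated introns.

    Nodes carry (species, host gene, class); edges are passing similarity
    hits with boolean labels ``shared`` / ``translocation`` / ``duplication``.
    Self-comparisons are excluded.
    """
    graph = nx.Graph()
    for it in introns:
        graph.add_node(it.intron_id, species=it.species, host_gene=it.host_gene,
                       intron_class=it.intron_class, genome_id=it.genome_id)
    for ia, ib in combinations(introns, 2):
        hit = pairwise_similarity(ia.sequence, ib.sequence, scoring, prefilter,
                                  min_coverage=min_coverage, min_identity=min_identity)
        if not hit.passed:
            continue
        graph.add_edge(
            ia.intron_id,
            ib.intron_id,
            identity=hit.identity,
            coverage=max(hit.coverage, hit.coverage_subject),
            score=hit.score,
            shared=ia.species != ib.species,
            translocation=ia.host_gene != ib.host_gene,
            duplication=ia.species == ib.species,
        )
    return graph


def sharing_tables(graph: nx.Graph) -> dict[str, pd.DataFrame]:
    """Edge list plus per-species-pair and per-gene-pair aggregate counts."""
    edge_rows, sp_counts, gene_counts = [], {}, {}
    for u, v, data in graph.edges(data=True):
        edge_rows.append({
            "intron_a": u, "intron_b": v,
            "identity": round(data["identity"], 2),
            "coverage": round(data["coverage"], 2),
            "shared": data["shared"], "translocation": data["translocation"],
            "duplication": data["duplication"],
        })
        sp = tuple(sorted((graph.nodes[u]["species"], graph.nodes[v]["species"])))
        sp_counts[sp] = sp_counts.get(sp, 0) + 1
        gp = tuple(sorted((graph.nodes[u]["host_gene"] or "-", graph.nodes[v]["host_gene"] or "-")))
        gene_counts[gp] = gene_counts.get(gp, 0) + 1
    return {
        "intron_edges": pd.DataFrame(
            edge_rows, columns=["intron_a", "intron_b", "identity", "coverage",
                                "shared", "translocation", "duplication"]),
        "species_pair_counts": pd.DataFrame(
            [{"species_a": a, "species_b": b, "edges": n} for (a, b), n in sorted(sp_counts.items())],
            columns=["species_a", "species_b", "edges"]),
        "gene_pair_counts": pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "edges": n} for (a, b), n in sorted(gene_counts.items())],
            columns=["gene_a", "gene_b", "edges"]),
    }


def shared_intron_count(graph: nx.Graph) -> int:
    """Number of introns with at least one cross-species similarity edge."""
    shared_nodes = set()
    for u, v, data in graph.edges(data=True):
        if data.get("shared"):
            shared_nodes.update((u, v))
    return len(shared_nodes)


def _host_gene_feature(g: GenomeRecord, intron: FeatureRecord) -> FeatureRecord:
    for f in g.features:
        if f.kind in ("protein_gene", "rRNA") and f.name == intron.parent:
            span = f.span()
            isp = intron.span()
            if span[0] <= isp[0] and isp[1] <= span[1]:
                return f
    # Fall back to name match only (origin-spanning hosts).
    for f in g.features:
        if f.kind in ("protein_gene", "rRNA") and f.name == intron.parent:
            return f
    raise ValueError(f"intron {intron.feature_id or intron.name}: host gene "
                     f"{intron.parent!r} not found in {g.id}")


def insertion_flank(
    g: GenomeRecord,
    intron: FeatureRecord,
    flank_len: int = FLANK_LENGTH,
) -> FlankRecord:
    """The ``flank_len`` exonic nucleotides preceding an intron insertion.

    The flank is read from the spliced host-gene sequence on the gene's
    strand, so an earlier intron in the same gene does not interrupt it
    (the flank runs across the splice junction).  When fewer than
    ``flank_len`` exonic nucleotides exist upstream, the flank is padded
    from upstream genomic sequence and flagged.
    """
    if intron.parent is None:
        raise ValueError("freestanding intron has no insertion site")
    host = _host_gene_feature(g, intron)
    spliced = g.spliced_sequence(host)
    L = g.length
    # Genomic positions of every spliced base in biological (5'->3') order;
    # works for origin-spanning multi-interval genes on either strand.
    pos_list: list[int] = []
    for s, e in host.intervals:
        pos_list.extend(range(s, e) if host.strand == "+" else range(e - 1, s - 1, -1))
    idx = {p: i for i, p in enumerate(pos_list)}
    if host.strand == "+":
        prev_base = (intron.intervals[0][0] - 1) % L
    else:
        prev_base = intron.intervals[0][1] % L
    offset = idx[prev_base] + 1 if prev_base in idx else 0
    padded = False
    if offset >= flank_len:
        flank = spliced[offset - flank_len:offset]
    else:
        need = flank_len - offset
        g5 = pos_list[0]  # genomic position of the gene's first spliced base
        if host.strand == "+":
            pad = "".join(g.sequence[(g5 - k - 1) % L] for k in range(need))[::-1]
        else:
            pad = "".join(_comp(g.sequence[(g5 + k + 1) % L]) for k in range(need))[::-1]
        flank = pad + spliced[:offset]
        padded = True
        logger.warning("intron %s: flank padded with %d genomic nt",
                       intron.feature_id or intron.name, need)
    return FlankRecord(
        intron_id=intron.feature_id or intron.name,
        species=g.species or g.id,
        host_gene=intron.parent,
        offset=offset,
        flank=flank,
        padded=padded,
    )


def _comp(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ConservationGroup:
    host_gene: str
    members: list[FlankRecord] = field(default_factory=list)

    @property
    def species(self) -> set[str]:
        return {m.species for m in self.members}

    @property
    def is_event(self) -> bool:
        """A conserved-position event spans at least two distinct species."""
        return len(self.species) >= 2


def group_conserved_positions(
    flanks: list[FlankRecord],
    max_mismatch: int = FLANK_MAX_MISMATCH,
) -> list[ConservationGroup]:
    """Single-linkage grouping of insertion flanks at Hamming distance <= 1.

    All flanks must come from the same host gene; mismatch counting is over
    substitutions only (indels are not considered).  The result is
    independent of input order: groups are returned sorted by their
    smallest member id, members sorted by id.
    """
    if not flanks:
        return []
    genes = {f.host_gene for f in flanks}
    if len(genes) > 1:
        raise ValueError(f"group_conserved_positions: mixed host genes {sorted(genes)}")
    n = len(flanks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if hamming(flanks[i].flank, flanks[j].flank) <= max_mismatch:
            parent[find(i)] = find(j)
    buckets: dict[int, list[FlankRecord]] = {}
    for i, f in enumerate(flanks):
        buckets.setdefault(find(i), []).append(f)
    groups = [
        ConservationGroup(host_gene=next(iter(genes)),
                          members=sorted(ms, key=lambda m: m.intron_id))
        for ms in buckets.values()
    ]
    return sorted(groups, key=lambda grp: grp.members[0].intron_id)


def conservation_table(genomes: list[GenomeRecord]) -> pd.DataFrame:
    """Per-gene conserved insertion-position event counts across a cohort."""
    by_gene: dict[str, list[FlankRecord]] = {}
    for g in genomes:
        for f in g.features:
            if f.kind == "intron" and f.parent is not None:
                fr = insertion_flank(g, f)
                by_gene.setdefault(fr.host_gene, []).append(fr)
    rows = []
    for gene in sorted(by_gene):
        groups = group_conserved_positions(by_gene[gene])
        rows.append({
            "gene": gene,
            "introns": len(by_gene[gene]),
            "position_groups": len(groups),
            "conserved_events": sum(1 for grp in groups if grp.is_event),
        })
    return pd.DataFrame(rows, columns=["gene", "introns", "position_groups", "conserved_events"])
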