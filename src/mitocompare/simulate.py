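"""Synthetic clades of annotated mitogenomes with full ground truth.

An ancestral circular mitogenome carrying the 17 conserved Hypocreales
elements (14 OXPHOS protein genes, rrnS, rrnL, rps3) plus tRNAs, a
configurable group I/II intron complement (some introns hosting HEG ORFs)
and uORFs is evolved along a user-supplied time-calibrated tree:

* codon-aware substitution in protein genes — synonymous and nonsynonymous
  events drawn separately (Poisson, per NG86 site counts under table 4) and
  applied by categorical proposal with rejection, so true dS is controlled;
* neutral substitution in rRNA/tRNA/intron/intergenic sequence;
* intron gain (fresh family, random exonic insertion point) and loss;
* optional horizontal intron transfer (copy, not move, so insertion-position
  conservation has positive and negative cases);
* NUMT insertion with per-base decay into per-leaf nuclear decoy contigs.

Every stochastic draw comes from one seeded generator: identical
(params, seed) give byte-identical output.  The emitted records satisfy all
parsing and composition invariants, and a :class:`TruthSet` records intron
homology groups, insertion offsets, NUMT intervals and pairwise divergence
times for use as an oracle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genetics import CODON_TO_AA, NUCLEOTIDES, STOP_CODONS, codons_of
from .molclock import syn_sites
from .records import FeatureRecord, GenomeRecord, NuclearContigSet

# Consensus element order used for the ancestor (rrnL first, per the
# conserved Hypocreales arrangement; rps3 freestanding between cox1 and nad1).
ANCESTRAL_ORDER = (
    "rrnL", "nad2", "nad3", "atp9", "cox2", "nad4L", "nad5", "cob",
    "cox1", "rps3", "nad1", "nad4", "atp8", "atp6", "rrnS", "cox3", "nad6",
)

# Approximate fungal mitochondrial gene lengths (bp of spliced CDS / rRNA).
GENE_LENGTHS = {
    "atp6": 774, "atp8": 147, "atp9": 225, "cob": 1158, "cox1": 1608,
    "cox2": 750, "cox3": 810, "nad1": 1086, "nad2": 1500, "nad3": 414,
    "nad4": 1464, "nad4L": 270, "nad5": 1980, "nad6": 600, "rps3": 1302,
    "rrnS": 1500, "rrnL": 3200,
}

INTRON_CLASS_POOL = ("IA", "IB", "IB", "IB", "IC1", "IC2", "ID", "II")

DEFAULT_TREE = (
    "((((A:0.1,B:0.1):0.15,C:0.25):0.25,(D:0.2,E:0.2):0.3):0.5,"
    "((F:0.3,G:0.3):0.35,H:0.65):0.35);"
)


@dataclass
class SimParams:
    """Simulation settings; rates are per unit branch-length time.

    Defaults give leaf mitogenomes in the mid-20-kb range, intron identity
    well above the 50% similarity threshold within the clade, and a dS
    spread of roughly 0.05-0.6 across the default 8-leaf tree.
    """

    tree: str = DEFAULT_TREE
    syn_rate: float = 0.3        # synonymous substitutions / syn site / time
    nonsyn_rate: float = 0.03    # nonsynonymous substitutions / nonsyn site / time
    intergenic_rate: float = 0.05  # neutral substitutions / site / time
    intron_gain_rate: float = 0.3  # gains / lineage / time
    intron_loss_rate: float = 0.1  # losses / intron / time
    hgt_rate: float = 1.0        # horizontal intron transfers / tree
    numt_rate: float = 1.0       # insertions / nuclear genome
    numt_decay: float = 0.05     # per-base substitution prob on inserted copies
    seed: int = 42
    n_ancestral_introns: int = 8
    intron_len_range: tuple[int, int] = (250, 900)
    heg_prob: float = 0.5        # probability an intron carries a HEG ORF
    n_uorfs: int = 2
    n_trnas: int = 12
    intergenic_mean: int = 250
    n_decoy_contigs: int = 2
    decoy_contig_len: int = 15000
    rotate_leaves: bool = True

    def __post_init__(self) -> None:
        for name in ("syn_rate", "nonsyn_rate", "intergenic_rate", "intron_gain_rate",
                     "intron_loss_rate", "hgt_rate", "numt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be >= 0")
        if not 0 <= self.numt_decay <= 1:
            raise ValueError("SimParams.numt_decay must lie in [0, 1]")


@dataclass
class NumtTruth:
    species: str
    gene: str
    contig: str
    interval: tuple[int, int]
    decay: float
    length: int


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated clade."""

    homology_groups: dict[str, list[str]]          # family id -> intron feature ids
    intron_meta: dict[str, dict]                   # feature id -> {species, gene, offset, family, hgt}
    numts: list[NumtTruth]
    divergence_time: pd.DataFrame                  # pairwise time since common ancestor
    branch_subs: dict[str, dict[str, int]]         # leaf -> realized substitution counts

    def intron_pairs(self) -> set[frozenset[str]]:
        """All unordered pairs of introns belonging to one homology group."""
        pairs: set[frozenset[str]] = set()
        for members in self.homology_groups.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset((members[i], members[j])))
        return pairs


@dataclass
class _Intron:
    family: str
    intron_class: str
    offset: int          # insertion offset in the spliced host sequence
    sequence: str
    heg: tuple[int, int, str] | None  # (offset in intron, length, family)
    hgt: bool = False


@dataclass
class _Gene:
    name: str
    kind: str            # protein_gene / rRNA
    spliced: str
    introns: list[_Intron] = field(default_factory=list)


@dataclass
class _Element:
    kind: str            # spacer / tRNA / uORF / gene
    name: str = ""
    seq: str = ""
    gene: _Gene | None = None


_NT_IDX = {c: i for i, c in enumerate(NUCLEOTIDES)}


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.3) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(NUCLEOTIDES)[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n: int) -> str:
    """Random in-frame CDS under table 4: ATG ... sense codons ... TAA."""
    sense = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    ncod = n // 3
    body = [sense[int(rng.integers(len(sense)))] for _ in range(ncod - 2)]
    return "ATG" + "".join(body) + "TAA"


def _random_orf(rng: np.random.Generator, n: int) -> str:
    return _random_cds(rng, n - n % 3)


def _mutate_neutral(rng: np.random.Generator, seq: str, rate: float, t: float) -> tuple[str, int]:
    if not seq or rate * t == 0:
        return seq, 0
    k = int(rng.poisson(rate * t * len(seq)))
    if k == 0:
        return seq, 0
    arr = list(seq)
    for _ in range(k):
        i = int(rng.integers(len(arr)))
        choices = [c for c in NUCLEOTIDES if c != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr), k


def _cds_site_counts(seq: str) -> tuple[float, float]:
    S = 0.0
    ncod = 0
    for codon in codons_of(seq):
        if codon in STOP_CODONS or any(c not in NUCLEOTIDES for c in codon):
            continue
        S += syn_sites(codon)
        ncod += 1
    return S, 3.0 * ncod - S


def _mutate_cds(
    rng: np.random.Generator, seq: str, syn_rate: float, nonsyn_rate: float, t: float
) -> tuple[str, int, int]:
    """Apply Poisson numbers of synonymous / nonsynonymous substitutions.

    Each event proposes a random (codon, position, alternative) and is
    accepted when it produces the requested class without creating or
    destroying a stop codon; the start and stop codons are left untouched.
    """
    codons = codons_of(seq)
    if len(codons) < 4:
        return seq, 0, 0
    S, N = _cds_site_counts(seq)
    ks = int(rng.poisson(syn_rate * t * S))
    kn = int(rng.poisson(nonsyn_rate * t * N))
    for want_syn, k in ((True, ks), (False, kn)):
        applied = 0
        guard = 0
        while applied < k and guard < 200 * (k + 1):
            guard += 1
            ci = int(rng.integers(1, len(codons) - 1))  # skip start and stop
            pos = int(rng.integers(3))
            cur = codons[ci]
            alt_nt = NUCLEOTIDES[int(rng.integers(4))]
            if alt_nt == cur[pos]:
                continue
            alt = cur[:pos] + alt_nt + cur[pos + 1:]
            if alt in STOP_CODONS or cur in STOP_CODONS:
                continue
            if (CODON_TO_AA[alt] == CODON_TO_AA[cur]) != want_syn:
                continue
            codons[ci] = alt
            applied += 1
    return "".join(codons), ks, kn


class _SimState:
    """Mutable per-lineage genome state evolved down the tree."""

    def __init__(self, elements: list[_Element]):
        self.elements = elements

    def clone(self) -> "_SimState":
        return _SimState(copy.deepcopy(self.elements))

    def genes(self) -> list[_Gene]:
        return [e.gene for e in self.elements if e.kind == "gene"]


def _build_ancestor(params: SimParams, rng: np.random.Generator) -> _SimState:
    genes: dict[str, _Gene] = {}
    for name, length in GENE_LENGTHS.items():
        if name in ("rrnS", "rrnL"):
            genes[name] = _Gene(name=name, kind="rRNA", spliced=_random_dna(rng, length))
        else:
            genes[name] = _Gene(name=name, kind="protein_gene", spliced=_random_cds(rng, length))
    # Ancestral intron complement, weighted toward the big intron reservoirs.
    host_pool = ["cox1", "cox1", "cob", "rrnL", "rrnL", "cox2", "cox3", "nad2", "atp9"]
    for k in range(params.n_ancestral_introns):
        host = genes[host_pool[k % len(host_pool)]]
        _gain_intron(params, rng, host, family=f"fam{k:02d}")
    elements: list[_Element] = []
    trna_slots = set(
        int(i) for i in np.linspace(1, len(ANCESTRAL_ORDER) - 1, params.n_trnas) % len(ANCESTRAL_ORDER)
    )
    trna_count = 0
    uorf_slots = {3, 9}
    for i, name in enumerate(ANCESTRAL_ORDER):
        elements.append(_Element(kind="spacer",
                                 seq=_random_dna(rng, int(rng.integers(
                                     params.intergenic_mean // 2, params.intergenic_mean * 2)))))
        if i in uorf_slots and params.n_uorfs:
            elements.append(_Element(kind="uORF", name=f"orf{i}",
                                     seq=_random_orf(rng, int(rng.integers(150, 450)))))
            elements.append(_Element(kind="spacer", seq=_random_dna(rng, params.intergenic_mean)))
        if i in trna_slots:
            for _ in range(max(1, params.n_trnas // max(1, len(trna_slots)))):
                trna_count += 1
                elements.append(_Element(kind="tRNA", name=f"trn{chr(64 + trna_count % 26 + 1)}{trna_count}",
                                         seq=_random_dna(rng, 72)))
                elements.append(_Element(kind="spacer", seq=_random_dna(rng, 60)))
        elements.append(_Element(kind="gene", name=name, gene=genes[name]))
    elements.append(_Element(kind="spacer", seq=_random_dna(rng, params.intergenic_mean)))
    return _SimState(elements)


def _gain_intron(
    params: SimParams,
    rng: np.random.Generator,
    host: _Gene,
    family: str,
    donor: _Intron | None = None,
    offset: int | None = None,
) -> _Intron:
    """Insert a new or copied intron at an exonic offset of ``host``."""
    if donor is None:
        length = int(rng.integers(*params.intron_len_range))
        heg = None
        if rng.random() < params.heg_prob and length >= 400:
            heg_len = int(rng.integers(250, min(600, length - 60)))
            heg_len -= heg_len % 3
            heg_off = int(rng.integers(20, length - heg_len - 20))
            heg_fam = "LAGLIDADG" if rng.random() < 0.64 else "GIY-YIG"
            seq = (_random_dna(rng, heg_off) + _random_orf(rng, heg_len)
                   + _random_dna(rng, length - heg_off - heg_len))
            heg = (heg_off, heg_len, heg_fam)
        else:
            seq = _random_dna(rng, length)
        cls = INTRON_CLASS_POOL[int(rng.integers(len(INTRON_CLASS_POOL)))]
    else:
        seq, heg, cls = donor.sequence, donor.heg, donor.intron_class
    if offset is None:
        lo, hi = 15, len(host.spliced) - 15
        offset = int(rng.integers(lo, hi))
    taken = {i.offset for i in host.introns}
    while offset in taken:
        offset += 1
    intron = _Intron(family=family, intron_class=cls, offset=offset, sequence=seq,
                     heg=heg, hgt=donor is not None)
    host.introns.append(intron)
    host.introns.sort(key=lambda i: i.offset)
    return intron


def _evolve_branch(state: _SimState, t: float, params: SimParams,
                   rng: np.random.Generator, fam_counter: list[int],
                   subs: dict[str, int]) -> None:
    for el in state.elements:
        if el.kind in ("spacer", "tRNA", "uORF"):
            el.seq, k = _mutate_neutral(rng, el.seq, params.intergenic_rate, t)
            subs["neutral"] = subs.get("neutral", 0) + k
        else:
            gene = el.gene
            if gene.kind == "protein_gene":
                gene.spliced, ks, kn = _mutate_cds(
                    rng, gene.spliced, params.syn_rate, params.nonsyn_rate, t)
                subs["synonymous"] = subs.get("synonymous", 0) + ks
                subs["nonsynonymous"] = subs.get("nonsynonymous", 0) + kn
            else:
                gene.spliced, k = _mutate_neutral(rng, gene.spliced, params.intergenic_rate, t)
                subs["neutral"] = subs.get("neutral", 0) + k
            kept = []
            for intr in gene.introns:
                if rng.random() < 1.0 - np.exp(-params.intron_loss_rate * t):
                    continue  # intron lost
                intr.sequence, k = _mutate_neutral(rng, intr.sequence, params.intergenic_rate, t)
                subs["neutral"] = subs.get("neutral", 0) + k
                kept.append(intr)
            gene.introns = kept
    n_gain = int(rng.poisson(params.intron_gain_rate * t))
    genes = state.genes()
    for _ in range(n_gain):
        host = genes[int(rng.integers(len(genes)))]
        fam_counter[0] += 1
        _gain_intron(params, rng, host, family=f"fam{fam_counter[0]:02d}")


def _emit_record(leaf: str, state: _SimState, rng: np.random.Generator,
                 params: SimParams) -> tuple[GenomeRecord, dict[str, dict]]:
    seq_parts: list[str] = []
    features: list[FeatureRecord] = []
    intron_meta: dict[str, dict] = {}
    pos = 0
    intron_idx = 0
    for el in state.elements:
        if el.kind == "spacer":
            seq_parts.append(el.seq)
            pos += len(el.seq)
        elif el.kind == "tRNA":
            seq_parts.append(el.seq)
            features.append(FeatureRecord(kind="tRNA", name=el.name,
                                          intervals=[(pos, pos + len(el.seq))]))
            pos += len(el.seq)
        elif el.kind == "uORF":
            seq_parts.append(el.seq)
            features.append(FeatureRecord(kind="uORF", name=el.name,
                                          intervals=[(pos, pos + len(el.seq))],
                                          feature_id=f"{leaf}.{el.name}"))
            pos += len(el.seq)
        else:
            gene = el.gene
            exon_ivs: list[tuple[int, int]] = []
            cursor = 0
            gpos = pos
            for intr in gene.introns:
                exon_len = intr.offset - cursor
                if exon_len > 0:
                    seq_parts.append(gene.spliced[cursor:intr.offset])
                    exon_ivs.append((gpos, gpos + exon_len))
                    gpos += exon_len
                cursor = intr.offset
                intron_id = f"{leaf}.i{intron_idx}"
                intron_idx += 1
                seq_parts.append(intr.sequence)
                istart = gpos
                features.append(FeatureRecord(
                    kind="intron", name=f"{gene.name}-i{intron_idx}",
                    intervals=[(istart, istart + len(intr.sequence))],
                    parent=gene.name, intron_class=intr.intron_class,
                    feature_id=intron_id))
                if intr.heg is not None:
                    ho, hl, hf = intr.heg
                    features.append(FeatureRecord(
                        kind="HEG", name=f"heg-{intron_id}",
                        intervals=[(istart + ho, istart + ho + hl)],
                        parent=intron_id, heg_family=hf,
                        feature_id=f"{intron_id}.heg"))
                intron_meta[intron_id] = {
                    "species": leaf, "gene": gene.name, "offset": intr.offset,
                    "family": intr.family, "hgt": intr.hgt,
                }
                gpos += len(intr.sequence)
            tail = gene.spliced[cursor:]
            if tail:
                seq_parts.append(tail)
                exon_ivs.append((gpos, gpos + len(tail)))
                gpos += len(tail)
            features.append(FeatureRecord(
                kind=gene.kind, name=gene.name, intervals=exon_ivs,
                feature_id=f"{leaf}.{gene.name}"))
            pos = gpos
    record = GenomeRecord(
        id=leaf, sequence="".join(seq_parts), species=leaf,
        family="Simulataceae", topology="circular", features=features,
    )
    if params.rotate_leaves:
        record = record.rotate(int(rng.integers(record.length)))
    return record, intron_meta


def insert_numts(
    contigs: NuclearContigSet,
    genes: dict[str, str],
    rate: float,
    decay: float,
    seed: int,
    species: str = "",
    min_len: int = 150,
) -> tuple[NuclearContigSet, list[NumtTruth]]:
    """Poisson-distributed insertions of mitochondrial gene copies.

    Each insertion copies one gene (full length), applies per-base
    substitution with probability ``decay``, and splices the copy into a
    random contig position.  Returns new contigs plus truth records with
    coordinates valid in the returned contigs.
    """
    if not 0 <= decay <= 1:
        raise ValueError("decay must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new = dict(contigs.contigs)
    truth: list[NumtTruth] = []
    pool = sorted(name for name, seq in genes.items() if len(seq) >= min_len)
    n = int(rng.poisson(rate)) if pool else 0
    for _ in range(n):
        gene = pool[int(rng.integers(len(pool)))]
        copy_seq = list(genes[gene])
        muts = rng.random(len(copy_seq)) < decay
        for i in np.flatnonzero(muts):
            choices = [c for c in NUCLEOTIDES if c != copy_seq[i]]
            copy_seq[i] = choices[int(rng.integers(3))]
        insert = "".join(copy_seq)
        cid = sorted(new)[int(rng.integers(len(new)))]
        at = int(rng.integers(len(new[cid]) + 1))
        for t in truth:  # shift earlier inserts on the same contig
            if t.contig == cid and t.interval[0] >= at:
                t.interval = (t.interval[0] + len(insert), t.interval[1] + len(insert))
        new[cid] = new[cid][:at] + insert + new[cid][at:]
        truth.append(NumtTruth(species=species, gene=gene, contig=cid,
                               interval=(at, at + len(insert)), decay=decay,
                               length=len(insert)))
    return NuclearContigSet(contigs=new), truth


def simulate_clade(params: SimParams) -> tuple[list[GenomeRecord], NuclearContigSet, TruthSet]:
    """Simulate a clade of annotated mitogenomes plus nuclear decoy contigs."""
    rng = np.random.default_rng(params.seed)
    try:
        tree = dendropy.Tree.get(data=params.tree, schema="newick")
    except Exception as exc:
        raise ValueError(f"invalid tree: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves) or not all(leaves):
        raise ValueError("tree leaf labels must be unique and non-empty")
    ancestor = _build_ancestor(params, rng)
    fam_counter = [params.n_ancestral_introns]
    states: dict[str, _SimState] = {}
    branch_subs: dict[str, dict[str, int]] = {}

    def descend(node, state: _SimState, subs: dict[str, int]) -> None:
        for child in node.child_nodes():
            cstate = state.clone()
            csubs = dict(subs)
            t = child.edge.length or 0.0
            _evolve_branch(cstate, t, params, rng, fam_counter, csubs)
            if child.is_leaf():
                label = child.taxon.label
                states[label] = cstate
                branch_subs[label] = csubs
            else:
                descend(child, cstate, csubs)

    descend(tree.seed_node, ancestor, {})

    # Horizontal intron transfer: copy an intron (with its class/HEG) from a
    # donor leaf into a recipient leaf, at the conserved offset in the same
    # gene half the time, otherwise into a random gene at a random offset.
    n_hgt = int(rng.poisson(params.hgt_rate))
    order = sorted(states)
    for _ in range(n_hgt):
        donors = [(lf, g, i) for lf in order for g in states[lf].genes() for i in g.introns]
        if not donors:
            break
        lf, host, intr = donors[int(rng.integers(len(donors)))]
        recipients = [o for o in order if o != lf]
        rec = recipients[int(rng.integers(len(recipients)))]
        if rng.random() < 0.5:
            target = next((g for g in states[rec].genes() if g.name == host.name), None)
            offset = min(intr.offset, len(target.spliced) - 15) if target else None
        else:
            genes = states[rec].genes()
            target = genes[int(rng.integers(len(genes)))]
            offset = None
        if target is not None:
            _gain_intron(params, rng, target, family=intr.family, donor=intr, offset=offset)

    records: list[GenomeRecord] = []
    intron_meta: dict[str, dict] = {}
    all_contigs: dict[str, str] = {}
    numt_truth: list[NumtTruth] = []
    for leaf in order:
        rec, meta = _emit_record(leaf, states[leaf], rng, params)
        records.append(rec)
        intron_meta.update(meta)
        decoys = {
            f"{leaf}_ctg{i}": _random_dna(rng, params.decoy_contig_len, gc=0.5)
            for i in range(params.n_decoy_contigs)
        }
        gene_seqs = {g.name: g.spliced for g in states[leaf].genes()}
        cset, truths = insert_numts(
            NuclearContigSet(contigs=decoys), gene_seqs, params.numt_rate,
            params.numt_decay, seed=int(rng.integers(2**31 - 1)), species=leaf,
        )
        all_contigs.update(cset.contigs)
        numt_truth.extend(truths)

    groups: dict[str, list[str]] = {}
    for iid, meta in intron_meta.items():
        groups.setdefault(meta["family"], []).append(iid)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    div = pd.DataFrame(0.0, index=order, columns=order)
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            t = pdm.patristic_distance(taxa[a], taxa[b]) / 2.0
            div.loc[a, b] = div.loc[b, a] = t
    truth = TruthSet(
        homology_groups={k: sorted(v) for k, v in sorted(groups.items())},
        intron_meta=intron_meta,
        numts=numt_truth,
        divergence_time=div,
        branch_subs=branch_subs,
    )
    return records, NuclearContigSet(contigs=all_contigs), truth
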