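"""Intron similarity network and insertion-site conservation."""

import networkx as nx
import numpy as np
import pytest

from mitocompare.introns import (
    FlankRecord,
    IntronInfo,
    build_sharing_graph,
    collect_introns,
    group_conserved_positions,
    hamming,
    insertion_flank,
    pairwise_similarity,
)
from mitocompare.simulate import SimParams, simulate_clade

from conftest import feat, make_genome
from oracles import local_affine_score


def _rand(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


def test_identical_sequences_pass_with_full_identity():
    s = _rand(500, 1)
    hit = pairwise_similarity(s, s)
    assert hit.passed
    assert hit.identity == 100.0
    assert hit.coverage == 100.0


def test_single_mismatch_ten_mer_identity_90():
    a = "ACGTACGTAC"
    b = "ACGTTCGTAC"
    # brute-force DP confirms the full-length alignment is optimal
    assert local_affine_score(a, b) == 9 * 2 - 3
    hit = pairwise_similarity(a, b, prefilter=False)
    assert hit.identity == 90.0


def test_unrelated_sequences_do_not_pass():
    assert not pairwise_similarity(_rand(500, 2), _rand(500, 3)).passed


def test_acceptance_rule_is_symmetric():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = _rand(int(rng.integers(80, 300)), int(rng.integers(1 << 30)))
        b = list(a[: int(rng.integers(40, len(a)))])
        for i in rng.integers(0, len(b), size=len(b) // 10):
            b[i] = "ACGT"[int(rng.integers(4))]
        b = "".join(b)
        assert pairwise_similarity(a, b).passed == pairwise_similarity(b, a).passed


def test_thresholds_are_strict_inequalities():
    """'Higher than 60 and 50%' excludes a pair sitting exactly on the bound."""
    s = _rand(200, 6)
    hit = pairwise_similarity(s, s, min_coverage=100.0)  # coverage == 100 is not > 100
    assert not hit.passed


def _info(iid, species, gene, seq):
    return IntronInfo(intron_id=iid, species=species, genome_id=species,
                      host_gene=gene, intron_class="IB", sequence=seq)


def test_edge_labels_cross_species_same_gene():
    s = _rand(400, 7)
    g = build_sharing_graph([_info("x", "sp1", "cox1", s), _info("y", "sp2", "cox1", s)])
    data = g.edges["x", "y"]
    assert data["shared"] and not data["duplication"] and not data["translocation"]


def test_edge_labels_same_species_cross_gene():
    s = _rand(400, 8)
    g = build_sharing_graph([_info("x", "sp1", "cox1", s), _info("y", "sp1", "cob", s)])
    data = g.edges["x", "y"]
    assert data["duplication"] and data["translocation"] and not data["shared"]


def test_graph_nodes_conserve_annotation_counts(clade42):
    genomes, _, _ = clade42
    infos = collect_introns(genomes)
    graph = build_sharing_graph(infos)
    n_annotated = sum(1 for g in genomes for f in g.features if f.kind == "intron")
    assert graph.number_of_nodes() == n_annotated == len(infos)


def test_zero_mutation_clade_components_equal_truth_groups():
    params = SimParams(
        tree="((A:0.2,B:0.2):0.2,(C:0.3,D:0.3):0.1);",
        syn_rate=0, nonsyn_rate=0, intergenic_rate=0,
        intron_gain_rate=0, intron_loss_rate=0, hgt_rate=0, numt_rate=0,
        seed=5,
    )
    genomes, _, truth = simulate_clade(params)
    graph = build_sharing_graph(collect_introns(genomes))
    components = {frozenset(c) for c in nx.connected_components(graph)}
    groups = {frozenset(m) for m in truth.homology_groups.values()}
    assert components == groups


def _one_intron_gene(flank11, offset=None):
    """Gene whose intron sits right after `flank11` in the spliced sequence."""
    head = flank11
    tail = "GGATCCGGATCCGGATCCGGA"
    intron_seq = _rand(60, 99)
    s = head + intron_seq + tail
    gene = feat("protein_gene", "cox1", [(0, len(head)), (len(head) + 60, len(s))])
    intron = feat("intron", "cox1-i1", [(len(head), len(head) + 60)],
                  parent="cox1", feature_id="i1")
    return make_genome(s + "AAAA", [gene, intron]), intron


def test_flank_direct_readoff_at_offset_11():
    g, intron = _one_intron_gene("ATGGCTAAAGC")
    fr = insertion_flank(g, intron)
    assert fr.flank == "ATGGCTAAAGC"
    assert fr.offset == 11
    assert not fr.padded


def test_flank_reads_across_splice_junction():
    """Second intron's flank spans the junction left by an earlier intron."""
    seq_exon1 = "ATGGCTAA"          # 8 nt
    i1 = _rand(100, 11)
    seq_exon2 = "AGCCTGA"           # 7 nt
    i2 = _rand(100, 12)
    seq_exon3 = "GGATCCGGATCCGGATCCGGATCCGGATCCGG"
    genomic = seq_exon1 + i1 + seq_exon2 + i2 + seq_exon3
    e1 = (0, 8)
    e2 = (8 + 100, 8 + 100 + 7)
    e3 = (e2[1] + 100, e2[1] + 100 + len(seq_exon3))
    gene = feat("protein_gene", "cox1", [e1, e2, e3])
    intron2 = feat("intron", "cox1-i2", [(e2[1], e2[1] + 100)], parent="cox1", feature_id="i2")
    intron1 = feat("intron", "cox1-i1", [(8, 108)], parent="cox1", feature_id="i1")
    g = make_genome(genomic, [gene, intron1, intron2])
    fr = insertion_flank(g, intron2)
    # manual splice-and-slice oracle: last 11 of exon1+exon2
    assert fr.flank == (seq_exon1 + seq_exon2)[-11:]
    assert fr.offset == 15
    assert not fr.padded


def test_flank_padded_from_upstream_genomic_when_short():
    upstream = "TTTTTCCCCCGG"
    head = "ATGCA"  # only 5 exonic nt upstream of the intron
    intron_seq = _rand(60, 13)
    tail = "GGATCCGGATCCGGATCC"
    genomic = upstream + head + intron_seq + tail
    off = len(upstream)
    gene = feat("protein_gene", "cox1", [(off, off + 5), (off + 5 + 60, len(genomic))])
    intron = feat("intron", "cox1-i1", [(off + 5, off + 5 + 60)], parent="cox1", feature_id="i1")
    fr = insertion_flank(make_genome(genomic, [gene, intron]), intron)
    assert fr.padded
    assert fr.flank == upstream[-6:] + head
    assert fr.offset == 5


def test_freestanding_intron_has_no_insertion_site(clade42):
    genomes, _, _ = clade42
    g = genomes[0]
    stray = feat("intron", "stray", [(0, 50)], parent=None, feature_id="s1")
    with pytest.raises(ValueError, match="freestanding"):
        insertion_flank(g, stray)


def _flank(iid, sp, flank, gene="cox1"):
    return FlankRecord(intron_id=iid, species=sp, host_gene=gene, offset=20, flank=flank)


def test_identical_flanks_two_species_one_event():
    groups = group_conserved_positions([_flank("a", "sp1", "ACGTACGTACG"),
                                        _flank("b", "sp2", "ACGTACGTACG")])
    assert len(groups) == 1
    assert groups[0].is_event


def test_hamming_two_apart_stay_separate():
    groups = group_conserved_positions([_flank("a", "sp1", "ACGTACGTACG"),
                                        _flank("b", "sp2", "TCGTACGTACT")])
    assert len(groups) == 2
    assert not any(grp.is_event for grp in groups)


def test_single_linkage_chains_through_middle_flank():
    fa, fb, fc = "ACGTACGTACG", "ACGTACGTACT", "ACGTACGTATT"
    assert hamming(fa, fb) == 1 and hamming(fb, fc) == 1 and hamming(fa, fc) == 2
    groups = group_conserved_positions([_flank("a", "sp1", fa), _flank("b", "sp2", fb),
                                        _flank("c", "sp3", fc)])
    assert len(groups) == 1
    assert len(groups[0].members) == 3


def test_grouping_is_order_independent():
    flanks = [_flank(f"i{k}", f"sp{k % 3}", f)
              for k, f in enumerate(["ACGTACGTACG", "ACGTACGTACT", "TTTTTTTTTTT",
                                     "ACGTACGTATT", "TTTTTTTTTTA"])]
    ref = group_conserved_positions(flanks)
    for perm_seed in range(5):
        rng = np.random.default_rng(perm_seed)
        shuffled = list(flanks)
        rng.shuffle(shuffled)
        got = group_conserved_positions(shuffled)
        assert [[m.intron_id for m in grp.members] for grp in got] == \
            [[m.intron_id for m in grp.members] for grp in ref]


def test_mixed_host_genes_rejected():
    with pytest.raises(ValueError, match="mixed"):
        group_conserved_positions([_flank("a", "sp1", "ACGTACGTACG", gene="cox1"),
                                   _flank("b", "sp2", "ACGTACGTACG", gene="cob")])
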