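"""Gene order, displacement, duplication and ORF intactness."""

import numpy as np
import pytest

from mitocompare import align
from mitocompare.synteny import (
    GeneOrder,
    compare_orders,
    find_duplicate_genes,
    gene_order,
    orf_intact,
)

from conftest import feat, make_genome
from oracles import local_affine_score


def _five_gene_toy():
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 500))
    feats = [
        feat("protein_gene", "cox1", [(0, 100)]),
        feat("protein_gene", "nad1", [(150, 250)]),
        feat("protein_gene", "cob", [(300, 380)]),
        feat("rRNA", "rrnL", [(400, 500)]),
    ]
    return make_genome(seq, feats, genome_id="toy5")


def test_gene_order_rotation_invariant(clade42):
    genomes, _, _ = clade42
    g = genomes[0]
    base = gene_order(g)
    assert base.order[0] == "rrnL"
    for offset in (1000, g.length // 2, g.length - 17):
        rot = gene_order(g.rotate(offset))
        assert rot.order == base.order
        assert rot.fragmented == base.fragmented


def test_gene_order_double_reverse_complement_invariant(clade42):
    genomes, _, _ = clade42
    g = genomes[1]
    assert gene_order(g.reverse_complement().reverse_complement()).order == gene_order(g).order


def test_gene_order_minus_strand_rrnl_traverses_reverse_complement():
    """Manual traversal: with rrnL on -, the circle is read on the other strand."""
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 500))
    feats = [
        feat("protein_gene", "cox1", [(0, 100)]),
        feat("protein_gene", "nad1", [(150, 250)]),
        feat("protein_gene", "cob", [(300, 380)]),
        feat("rRNA", "rrnL", [(400, 500)], strand="-"),
    ]
    g = make_genome(seq, feats, genome_id="toy-minus")
    # On the reverse complement the traversal from rrnL's 5' end meets cob,
    # then nad1, then cox1 (decreasing original coordinates).
    assert gene_order(g).order == ["rrnL", "cob", "nad1", "cox1"]


def test_gene_order_missing_rrnl_anchors_on_smallest_name():
    g = _five_gene_toy()
    g.features = [f for f in g.features if f.name != "rrnL"]
    order = gene_order(g)
    assert order.anchored_on == "cob"
    assert order.order[0] == "cob"


def test_duplicated_rps3_appears_twice_in_order():
    seq = "A" * 900
    feats = [
        feat("rRNA", "rrnL", [(0, 200)]),
        feat("protein_gene", "rps3", [(50, 150)]),   # nested in rrnL span
        feat("protein_gene", "cox1", [(250, 400)]),
        feat("protein_gene", "rps3", [(500, 600)]),  # freestanding copy
        feat("protein_gene", "nad1", [(700, 850)]),
    ]
    order = gene_order(make_genome(seq, feats, genome_id="beauveria-like"))
    assert order.order.count("rps3") == 2


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGGCTTGACCTTAA", True),   # internal TGA is Trp under table 4
        ("ATGTAACCT", False),        # internal TAA stop
        ("ATGTAA", True),            # start plus terminal stop only
        ("ATG", True),
        ("CTGGCTTAA", False),        # no ATG start
    ],
)
def test_orf_intact_table4(seq, expected):
    assert orf_intact(seq) is expected


def test_orf_intact_rejects_empty():
    with pytest.raises(ValueError):
        orf_intact("")


def _rps3_pair_genome():
    intact = "ATG" + "GCTAAAGAATTA" * 8 + "TAA"        # 102 nt, clean ORF
    broken = intact[:30] + "TAA" + intact[33:]          # internal stop knocked in
    seq = intact + "C" * 40 + broken + "C" * 40
    feats = [
        feat("protein_gene", "rps3", [(0, len(intact))], feature_id="rps3.free"),
        feat("protein_gene", "rps3",
             [(len(intact) + 40, len(intact) + 40 + len(broken))], feature_id="rps3.nested"),
    ]
    return make_genome(seq, feats, genome_id="dup")


def test_identical_copies_are_duplicates_with_full_identity():
    intact = "ATG" + "GCTAAAGAATTA" * 8 + "TAA"
    seq = intact + "C" * 40 + intact
    feats = [
        feat("protein_gene", "rps3", [(0, len(intact))], feature_id="a"),
        feat("protein_gene", "rps3", [(len(intact) + 40, len(intact) + 40 + len(intact))],
             feature_id="b"),
    ]
    (pair,) = find_duplicate_genes(make_genome(seq, feats))
    assert pair.identity == 100.0
    assert pair.coverage == 100.0


def test_disrupted_nested_copy_flagged_not_intact():
    (pair,) = find_duplicate_genes(_rps3_pair_genome())
    assert pair.intact_a is True
    assert pair.intact_b is False
    assert pair.identity > 90.0


def test_unrelated_copies_not_reported():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(list("ACGT"), 60))
    b = "".join(rng.choice(list("ACGT"), 60))
    seq = a + "C" * 20 + b
    feats = [
        feat("protein_gene", "cox2", [(0, 60)], feature_id="a"),
        feat("protein_gene", "cox2", [(80, 140)], feature_id="b"),
    ]
    assert find_duplicate_genes(make_genome(seq, feats)) == []


def test_duplication_thresholds_are_inclusive():
    """'At least 50%' admits a pair sitting exactly on the threshold."""
    g = _rps3_pair_genome()
    (pair,) = find_duplicate_genes(g)
    assert find_duplicate_genes(g, min_identity=pair.identity, min_coverage=pair.coverage)
    assert not find_duplicate_genes(g, min_identity=pair.identity + 0.01)


def test_local_aligner_matches_bruteforce_dp_scores():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(4, 11))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(4, 11))))
        assert align.local_dna(a, b).score == local_affine_score(a, b)


def _order(gid, names):
    return GeneOrder(genome_id=gid, order=list(names))


def test_identical_orders_have_no_displacements():
    names = ["rrnL", "nad2", "cox2", "cob", "cox1"]
    table = compare_orders([_order(g, names) for g in "abc"])
    assert table.empty


def test_adjacent_swap_flags_exactly_the_affected_neighborhood():
    base = ["rrnL", "nad2", "cox2", "cob", "cox1", "nad1"]
    swapped = ["rrnL", "nad2", "cob", "cox2", "cox1", "nad1"]
    table = compare_orders([_order("a", base), _order("b", base), _order("c", swapped)])
    assert set(table["genome_id"]) == {"c"}
    # Hand oracle: only the swapped pair's neighbor sets change
    # (nad2/cox1 keep their sets {rrnL,cox2}->{rrnL,cob} asymmetry included).
    assert set(table["gene"]) == {"nad2", "cox2", "cob", "cox1"}


def test_moved_cox2_flagged_only_in_the_moved_species():
    base = ["rrnL", "nad2", "cox2", "cob", "cox1", "nad1"]
    moved = ["rrnL", "nad2", "cob", "cox1", "cox2", "nad1"]
    table = compare_orders([_order(s, base) for s in "abcd"] + [_order("e", moved)])
    assert set(table["genome_id"]) == {"e"}
    assert "cox2" in set(table["gene"])


def test_all_unique_orders_reports_everything():
    o1 = _order("a", ["rrnL", "nad2", "cox2"])
    o2 = _order("b", ["rrnL", "cox2", "nad2"])
    table = compare_orders([o1, o2])
    assert len(table) == 6
    assert not table["consensus"].any()
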