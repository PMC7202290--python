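"""Nei-Gojobori dS, codon alignment, mean dS and Pearson correlations."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from mitocompare.genetics import STOP_CODONS, translate
from mitocompare.molclock import (
    codon_align,
    concat_clock_genes,
    correlate,
    mean_ds,
    ng86_pairwise,
    pairwise_ds_matrix,
    syn_sites,
)
from mitocompare.records import reverse_complement
from mitocompare.simulate import SimParams, simulate_clade

from conftest import feat, make_genome
from oracles import global_affine_score, ng86_codon_oracle, pearson_closed_form


def _cds(n, seed):
    rng = np.random.default_rng(seed)
    sense = [c for c in map("".join, product("ACGT", repeat=3)) if c not in STOP_CODONS]
    return "ATG" + "".join(rng.choice(sense, n // 3 - 2)) + "TAA"


def _clock_genome(lens=(150, 222, 810), strands=("+", "+", "+"), gid="toy"):
    seqs = [_cds(n, i) for i, n in enumerate(lens)]
    genomic = []
    feats = []
    pos = 0
    for name, s, strand in zip(("atp8", "atp9", "cox3"), seqs, strands):
        stored = s if strand == "+" else reverse_complement(s)
        genomic.append(stored)
        feats.append(feat("protein_gene", name, [(pos, pos + len(s))], strand=strand))
        pos += len(s)
        genomic.append("C" * 20)
        pos += 20
    return make_genome("".join(genomic), feats, genome_id=gid), seqs


def test_concat_is_additive_in_fixed_order():
    g, seqs = _clock_genome()
    cat = concat_clock_genes(g)
    assert len(cat) == 150 + 222 + 810
    assert cat == "".join(seqs)


def test_minus_strand_gene_contributes_reverse_complement():
    g, seqs = _clock_genome(strands=("+", "-", "+"))
    assert concat_clock_genes(g) == "".join(seqs)


def test_intron_containing_gene_spliced_before_concatenation():
    """30-nt toy gene split by an intron contributes its spliced CDS."""
    cds = "ATGGCTAAAGAATTAGCTAAAGAATTATAA"
    intron_seq = "T" * 50
    genomic = cds[:12] + intron_seq + cds[12:] + "C" * 10
    atp8 = feat("protein_gene", "atp8", [(0, 12), (62, 62 + 18)])
    intr = feat("intron", "atp8-i1", [(12, 62)], parent="atp8", feature_id="i1")
    pos = len(genomic)
    g2 = _cds(222, 10)
    g3 = _cds(810, 11)
    genomic += g2 + "C" * 5 + g3
    feats = [atp8, intr,
             feat("protein_gene", "atp9", [(pos, pos + 222)]),
             feat("protein_gene", "cox3", [(pos + 227, pos + 227 + 810)])]
    g = make_genome(genomic, feats)
    assert concat_clock_genes(g) == cds + g2 + g3


def test_missing_clock_gene_raises():
    g, _ = _clock_genome()
    g.features = [f for f in g.features if f.name != "atp9"]
    with pytest.raises(KeyError, match="atp9"):
        concat_clock_genes(g)


def test_codon_align_identical_is_gapfree():
    s = _cds(60, 3)
    a, b = codon_align(s, s)
    assert a == b == s


def test_codon_align_single_codon_deletion_gives_one_triplet_gap():
    s = _cds(60, 4)
    deleted = s[:30] + s[33:]
    a, b = codon_align(s, deleted)
    assert len(a) == len(b) == 60
    assert b.count("-") == 3
    i = b.index("-")
    assert i % 3 == 0 and b[i:i + 3] == "---"


def test_codon_align_matches_bruteforce_protein_dp():
    """5-codon toy with one substitution and one codon indel."""
    s = "ATGGCTAAAGAATTA"
    t = "ATGGCTGAATTA"  # codon 4 (AAA) deleted; no other change
    t = t[:3] + "GCG" + t[6:]  # plus one substitution in codon 2
    a, b = codon_align(s, t)
    blosum = substitution_matrices.load("BLOSUM62")
    expected = global_affine_score(
        translate(s), translate(t),
        score_fn=lambda x, y: float(blosum[x, y]),
        gap_open=-11.0, gap_extend=-1.0,
    )
    # re-score the returned alignment columns
    score = 0.0
    in_gap = False
    for ca, cb in zip([a[i:i + 3] for i in range(0, len(a), 3)],
                      [b[i:i + 3] for i in range(0, len(b), 3)]):
        if "-" in ca or "-" in cb:
            score += -1.0 if in_gap else -11.0
            in_gap = True
        else:
            score += float(blosum[translate(ca), translate(cb)])
            in_gap = False
    assert score == expected


def test_ng86_self_comparison_is_zero():
    s = _cds(90, 6)
    res = ng86_pairwise(s, s)
    assert res.Sd == res.Nd == 0
    assert res.dS == res.dN == 0.0


def test_ng86_worked_example_single_synonymous_change():
    """GGA TTT GGA vs GGG TTT GGA: S=7/3, Sd=1, dS=-0.75*ln(1-4/7)."""
    res = ng86_pairwise("GGATTTGGA", "GGGTTTGGA")
    assert res.S == pytest.approx(7 / 3)
    assert res.Sd == 1
    assert res.ps == pytest.approx(3 / 7)
    assert res.dS == pytest.approx(-0.75 * math.log(1 - 4 / 7), abs=1e-4)
    assert res.dS == pytest.approx(0.6355, abs=1e-3)
    assert res.dN == 0.0


def test_ng86_symmetric_and_site_conserving():
    rng = np.random.default_rng(8)
    for k in range(5):
        a = _cds(90, 100 + k)
        b = list(a)
        for i in rng.integers(3, 87, size=6):
            b[i] = "ACGT"[int(rng.integers(4))]
        b = "".join(b)
        if any(c in STOP_CODONS for c in (b[i:i + 3] for i in range(0, 90, 3))):
            continue
        r1, r2 = ng86_pairwise(a, b), ng86_pairwise(b, a)
        assert r1.S == pytest.approx(r2.S)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.S + r1.N == pytest.approx(3 * r1.codons)


def test_ng86_matches_exhaustive_pathway_oracle_on_sampled_codon_pairs():
    rng = np.random.default_rng(9)
    sense = [c for c in map("".join, product("ACGT", repeat=3)) if c not in STOP_CODONS]
    for _ in range(150):
        ca, cb = rng.choice(sense), rng.choice(sense)
        res = ng86_pairwise(ca, cb)
        sa, sb, sd, nd = ng86_codon_oracle(ca, cb)
        assert res.S == pytest.approx((sa + sb) / 2)
        assert res.Sd == pytest.approx(sd)
        assert res.Nd == pytest.approx(nd)


def test_saturated_ps_flagged_undefined():
    # 4-fold site pushed to ps = 1 > 3/4 by comparing a codon against three
    # synonymous variants: craft an alignment where every syn site differs.
    res = ng86_pairwise("GGAGGAGGAGGA", "GGCGGTGGGGGC")
    assert res.ps >= 0.75
    assert res.dS is None
    assert "saturated_dS" in res.flags


def _matrix(values):
    species = sorted({s for pair in values for s in pair})
    mat = pd.DataFrame(np.nan, index=species, columns=species, dtype=float)
    for (a, b), v in values.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    for s in species:
        mat.loc[s, s] = 0.0
    return mat


def test_mean_ds_formula_three_species():
    mat = _matrix({("s1", "s2"): 0.1, ("s1", "s3"): 0.3, ("s2", "s3"): 0.5})
    assert mean_ds(mat, "s1").ds_bar == pytest.approx((0.1 + 0.3) / 2) == 0.2


def test_mean_ds_all_zero():
    mat = _matrix({("s1", "s2"): 0.0, ("s1", "s3"): 0.0, ("s2", "s3"): 0.0})
    assert mean_ds(mat, "s2").ds_bar == 0.0


def test_mean_ds_four_species():
    mat = _matrix({("s1", "s2"): 0.1, ("s1", "s3"): 0.2, ("s1", "s4"): 0.6,
                   ("s2", "s3"): 0.0, ("s2", "s4"): 0.0, ("s3", "s4"): 0.0})
    assert mean_ds(mat, "s1").ds_bar == pytest.approx(0.3)


def test_mean_ds_excludes_undefined_pairs_with_adjusted_denominator():
    mat = _matrix({("s1", "s2"): 0.1, ("s1", "s3"): np.nan, ("s2", "s3"): 0.2})
    res = mean_ds(mat, "s1")
    assert res.ds_bar == pytest.approx(0.1)
    assert res.pairs_used == 1
    assert res.flags


def test_correlate_perfect_linear():
    x = np.arange(10.0)
    res = correlate(x, 2 * x)
    assert res.r == pytest.approx(1.0)


def test_correlate_closed_form_triple():
    res = correlate([1, 2, 3], [6, 4, 5])
    assert res.r == pytest.approx(-0.5)
    assert res.r == pytest.approx(pearson_closed_form([1, 2, 3], [6, 4, 5]))


def test_correlate_independent_null():
    rng = np.random.default_rng(12)
    res = correlate(rng.normal(size=1000), rng.normal(size=1000))
    assert abs(res.r) < 0.1


def test_correlate_zero_variance_undefined():
    res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert res.r is None and res.p is None


def test_two_taxon_synonymous_clock_recovers_2mut():
    """Synonymous-only evolution at rate mu on depth-t branches gives dS ~ 2*mu*t."""
    mu, t = 0.3, 0.5
    vals = []
    for seed in (41, 42, 43):
        params = SimParams(tree=f"(A:{t},B:{t});", syn_rate=mu, nonsyn_rate=0.0,
                           intergenic_rate=0.0, intron_gain_rate=0.0,
                           intron_loss_rate=0.0, hgt_rate=0.0, numt_rate=0.0,
                           seed=seed)
        genomes, _, _ = simulate_clade(params)
        mat, _ = pairwise_ds_matrix(genomes)
        vals.append(mat.loc["A", "B"])
    assert np.mean(vals) == pytest.approx(2 * mu * t, rel=0.15)


def test_syn_sites_known_codons():
    assert syn_sites("GGA") == pytest.approx(1.0)   # 4-fold third position
    assert syn_sites("TTT") == pytest.approx(1 / 3)
    assert syn_sites("ATG") == pytest.approx(0.0)   # Met is 1-fold under table 4
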