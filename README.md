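# mitocompare

Comparative analysis of fungal mitochondrial genomes, built for clades like
the Hypocreales where genome size varies four-fold (roughly 24–105 kb) while
the coding complement stays fixed.  The package takes annotated GenBank
records (plus optional nuclear contigs) and computes, as reproducible
tables:

* **Compartment accounting** — every base assigned to exactly one of four
  compartments (coding; HEG/uORF; intron; intergenic) under the precedence
  coding > HEG/uORF > intron > intergenic, plus GC content and cohort
  summaries such as the share of each group I/II intron subclass.
* **Gene order and duplication** — the circular order of the 17 conserved
  elements (14 OXPHOS genes, rrnS, rrnL, rps3) anchored on the 5′ end of
  *rrnL*, displaced genes relative to the cohort consensus, and duplicated
  gene copies (identity and coverage ≥ 50%) with ORF-intactness flags under
  translation table 4 (TGA = Trp; stops TAA/TAG only).
* **Intron sharing network** — all-vs-all local alignment of annotated
  introns; a pair is similar when coverage > 60% and identity > 50% in
  either direction.  Edges are labelled shared (cross-species),
  translocation (cross-gene) and duplication (within-species).
* **Insertion-site conservation** — each intron's insertion position is
  characterized by the 11 exonic nucleotides preceding it in the spliced
  host gene; flanks within Hamming distance 1 are grouped by single
  linkage, and groups spanning ≥ 2 species count as conserved-position
  events.
* **NUMT detection** — protein-level search of each mitochondrial gene
  (table 4 translation, BLOSUM62, six frames; rRNAs at nucleotide level)
  against nuclear contigs; hits pass at identity ≥ 50%, query coverage
  ≥ 50% and an empirical E-value < 1e-10 (Gumbel fit to shuffled-contig
  null scores).
* **Synonymous divergence** — per species pair, Nei–Gojobori (1986) dS on
  the concatenated mitochondrion-exclusive genes *atp8* + *atp9* + *cox3*
  after codon-aware alignment, with Jukes–Cantor correction
  `dS = −(3/4)·ln(1 − (4/3)·ps)`; per-species mean
  `dS̄ = Σ dS / (n − 1)`; and Pearson correlations of dS̄ against genome,
  intron, HEG/uORF and coding lengths.

A seeded clade **simulator** (`mitocompare.simulate`) generates annotated
mitogenomes evolved along a time-calibrated tree — with controlled
synonymous/nonsynonymous rates, intron gain/loss/horizontal transfer and
decayed NUMT insertions — together with a ground-truth table, so the whole
pipeline can be exercised and validated without downloading anything.

## Worked example

```python
from mitocompare.simulate import SimParams, simulate_clade
from mitocompare.composition import partition_genome, cohort_class_counts, summarize_cohort
from mitocompare.introns import collect_introns, build_sharing_graph, shared_intron_count
from mitocompare.molclock import pairwise_ds_matrix, mean_ds, correlate

genomes, contigs, truth = simulate_clade(SimParams(seed=42))
reports = [partition_genome(g) for g in genomes]
ic, hc = cohort_class_counts(genomes)
summary = summarize_cohort(reports, ic, hc)
graph = build_sharing_graph(collect_introns(genomes))
mat, _ = pairwise_ds_matrix(genomes)
```

With seed 42 this prints (see `summary`, `graph`, `mat` above):

```
n_genomes       8
length min/mean/max: 30050 30499.4 31428
genome A: L=30600 coding=64.22% intron=8.94% heg_uorf=5.4% intergenic=21.43% GC=41.6%
intron class shares: {'IC2': 31.5, 'ID': 14.8, 'IB': 38.9, 'IA': 14.8}
introns: 54 similarity edges: 170 shared introns: 52
mean dS per species: {'A': 0.3799, 'B': 0.3881, 'C': 0.4091, 'D': 0.4361,
                      'E': 0.4506, 'F': 0.5274, 'G': 0.5097, 'H': 0.5973}
Pearson r (true divergence time vs mean dS): 0.967  p=8.99e-05
```

Reading these numbers: the four compartment percentages of genome A sum to
100% of its 30,600 bp; 52 of the 54 annotated introns have a cross-species
similarity edge (they are "shared"); and the per-species mean dS increases
with each species' true average divergence time (r = 0.967), which is the
signal behind the dS̄-vs-architecture correlations on real data.

The same analyses are available from a shell:

```bash
mitocompare simulate --seed 42 --out sim/
mitocompare all --in sim/clade.gbk --nuclear sim/nuclear.fasta --out run/
```

`run/` then contains one TSV per analysis (composition, gene orders,
duplications, displacements, intron edges and per-pair counts, insertion
positions, NUMTs, dS matrix, mean dS, correlations) plus `manifest.json`
with the package version, config digest and per-stage warnings.  Reruns on
identical inputs are byte-identical.

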