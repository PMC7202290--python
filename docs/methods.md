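# Methods

## Scope and data model

`mitocompare` analyses annotated fungal mitogenomes.  A `GenomeRecord`
holds an uppercase A/C/G/T/N sequence and an ordered feature table;
coordinates are 0-based half-open everywhere inside the package, with
GenBank's 1-based inclusive convention handled only at the I/O boundary.
Features on circular genomes may span the replication origin and are then
stored as ordered multi-interval locations (never silently rotated) — the
large rRNA gene of real Hypocreales records does exactly this.  Intron
subclass (IA/IB/IC1/IC2/ID/II) and homing-endonuclease family
(LAGLIDADG/GIY-YIG) are read from feature qualifiers; an absent qualifier
yields `unknown`/`none` with a warning, never a guess, because
classification is an upstream annotation task, not something this package
infers.

## Compartment accounting

Coding regions are protein-gene exons plus rRNA and tRNA sequence;
non-coding regions are introns, HEG/uORF ORFs and intergenic DNA.  Each
base is assigned to exactly one compartment under the precedence
coding > HEG/uORF > intron > intergenic, so the four lengths always sum to
the genome length (an exact integer identity, enforced by tests).  HEGs and
uORFs are pooled into one compartment for the length breakdown while their
element counts stay separate.  GC content is computed over unambiguous
bases only; a sequence of only N has no GC value.  Fractions are rounded
half-up to two decimals and cohort shares to one decimal, matching how such
tables are conventionally printed.

## Gene order and duplications

The circular order of the 17 conserved elements is read by traversing the
circle from the 5′ end of *rrnL* on *rrnL*'s strand (the genome is reverse
complemented first when *rrnL* is on the minus strand), which makes the
order invariant under rotation and double reverse complement.  When *rrnL*
is absent the order anchors on the lexicographically smallest core gene and
warns.  Displacements are called against the most frequent arrangement by
comparing each gene's circular neighbor set with the consensus one.

Within-genome duplicate copies of a core gene are compared by local
alignment; a pair is a duplication when identity (matches / alignment
columns) and coverage are both **at least** 50%.  Coverage is measured on
the shorter copy — the conservative reading when copies differ in size.
ORF intactness (start codon ATG, no internal TAA/TAG, TGA read as Trp under
translation table 4) replaces an external coding-potential classifier; the
output is labelled "intact", which is what it measures.  Alternative start
codons can be supplied, but none are assumed by default.

## Intron similarity and insertion sites

All annotated introns are compared all-vs-all by local DNA alignment
(match +2, mismatch −3, gap open 5, gap extend 2 — megablast-like and
configurable).  A pair is similar when coverage **exceeds** 60% and
identity **exceeds** 50%; coverage is computed on the query and the rule is
applied in both directions, passing if either passes, which mirrors
unordered all-vs-all search.  Self-comparisons are excluded.  Because the
comparison is quadratic in intron count, a prefilter requires a shared
exact 11-mer before running the alignment; in the >50%-identity regime the
rule targets, a qualifying pair essentially always shares an exact 11-mer,
and the filter can be disabled (`--no-prefilter`).

Edges are labelled by the relation of their endpoints — shared
(cross-species), translocation (cross-host-gene), duplication
(within-species) — and the labels are not mutually exclusive.

An intron's insertion site is summarized by the 11 exonic nucleotides
immediately 5′ of the insertion in the **spliced** host-gene sequence, so
an earlier intron in the same gene does not interrupt the flank.  If fewer
than 11 exonic nucleotides exist upstream, the flank is padded with
upstream genomic sequence and flagged.  Flanks of one host gene are grouped
by single linkage at Hamming distance ≤ 1 (substitutions only; the
mismatch allowance is a count of nucleotide differences, and indels are
deliberately not considered).  Single linkage is the minimal closure of the
pairwise "at most one mismatch" relation; a group containing at least two
species is a conserved-position event.  Grouping is order-independent.

## NUMT detection

Each protein-coding mitochondrial gene is translated under table 4 and
searched by local protein alignment (BLOSUM62, gap open 11 / extend 1)
against all six reading frames of each nuclear contig; rRNA genes are
searched as nucleotide on both strands.  The best hit per (gene, contig) is
gated on identity ≥ 50%, coverage of the mitochondrial query ≥ 50% and
E-value < 1e-10.  "Similarity" is implemented as alignment identity.

E-values are empirical rather than analytic: the query is re-scored against
shuffled contig windows, the null scores are fitted to a Gumbel (extreme
value) distribution, and E = f · P(S ≥ s) with f the ratio of the true
search space (total contig length, both strands) to the null window length.
Null windows are capped at 2,000 nt by default (configurable, `None` for
full-length contigs) — the Gumbel extrapolation across the search-space
factor is the standard device that makes this affordable.  Because the
three gates are conjunctive, E is only computed for candidates that already
pass identity and coverage; a degenerate (zero-variance) null leaves E
missing and keeps the hit on the other two rules, with a warning.  An exact
shared-k-mer prescreen (6-mer at protein level, 14-mer at nucleotide level)
skips hopeless frame/contig combinations and can be disabled.

## Synonymous divergence

The clock uses the genes that never appear as nuclear copies in these
clades — *atp8*, *atp9*, *cox3* — concatenated in that fixed order from
spliced, strand-corrected CDS.  Pairs are codon-aligned by globally
aligning the translations (BLOSUM62) and back-mapping gaps onto codons, so
gaps open only in multiples of three at codon boundaries; an option to
supply pre-aligned sequences exists at the API level via
`ng86_pairwise` on any codon-aligned pair.

Counting follows Nei–Gojobori (1986) under table 4.  Synonymous site
fractions per codon enumerate all nine single-nucleotide changes, with
changes to the stop codons TAA/TAG excluded from the denominator; sites are
averaged over the two sequences.  Codon pairs differing at two or three
positions average synonymous/nonsynonymous step counts over all minimal
mutational pathways with equal weights, excluding pathways through stop
codons (if every pathway is blocked, all are used — the standard fallback;
exact tie handling is a documented choice here).  Jukes–Cantor correction
gives dS; ps ≥ 3/4 is saturation and dS is reported as undefined, not a
number.  Columns with gaps, ambiguities or stops are excluded.

Per species, `dS̄ = Σ pairwise dS / (n − 1)`; saturated pairs are dropped
with the denominator adjusted and the species flagged.  Correlations are
Pearson r with a two-sided p from the t transform on n − 2 degrees of
freedom, reported raw (no multiplicity adjustment).  Absolute dating
(timetrees, calibration windows) is out of scope; dS̄ itself is the
divergence proxy.

## The simulator

The simulator is the package's no-download study surface: it emulates the
processes the analyses are designed to detect, with full ground truth.

The ancestor is a circular genome carrying the 17 conserved elements in a
fixed documented order (rrnL first; rps3 freestanding between cox1 and
nad1), 12 tRNAs, 2 uORFs, AT-rich intergenic spacers (mean 250 bp), and 8
ancestral introns (250–900 nt; half carry a HEG ORF, LAGLIDADG:GIY-YIG
roughly 64:36) placed at random exonic offsets in the intron-rich genes
(cox1, cob, rrnL, ...).  Gene lengths approximate real fungal mitochondrial
genes, which puts leaf genomes near 30 kb — inside the observed 24–105 kb
range at its lower end, keeping the default run fast.

Evolution along the user tree (newick, branch lengths in time units):

* **CDS substitution** is codon-aware with separately controlled
  synonymous (0.3 / syn site / time) and nonsynonymous (0.03 / nonsyn site
  / time) rates: event counts are Poisson draws scaled by the gene's NG86
  site counts, and each event is a categorical proposal accepted only if it
  realizes the requested class without touching start/stop codons.  This
  makes true dS ≈ 2μt controllable without a full codon-model engine.
* **Neutral sequence** (rRNA, tRNA, introns, spacers, uORFs) mutates at
  0.05 / site / time, so intron identity stays far above the similarity
  threshold within the default tree (depth 1.0) while still spreading.
* **Intron gain** (0.3 / lineage / time) creates a fresh homology family at
  a random exonic offset; **loss** removes introns at 0.1 / intron / time;
  **horizontal transfer** (Poisson, 1 event / tree) copies an intron —
  never moves it — into another lineage, at the conserved offset in the
  same gene half the time and at a random position otherwise, so
  position-conservation analysis sees positive and negative cases.
* **NUMTs**: per leaf, Poisson(1) gene copies with per-base substitution
  probability 0.05 are spliced into random positions of 2 random decoy
  contigs (15 kb, GC 0.5).

Leaf records are rotated by a random offset by default, which exercises
origin-spanning multi-interval features downstream.  All randomness flows
from one seeded generator; identical (params, seed) give byte-identical
output.  The `TruthSet` records intron homology groups (ancestral vs
HGT-derived), insertion offsets, NUMT intervals, pairwise divergence times
(half the patristic distance) and realized per-branch substitution counts.

What the simulator does **not** emulate: realistic base composition
(simulated genomes sit near 42% GC, versus ~27% in real fungal
mitogenomes), indels outside codon units, tandem repeats, tRNA secondary
structure, rearrangements of the core gene order, and sequence-specific
homing-site preference.  Passing recovery tests therefore demonstrates the
correctness of the measurement machinery under the modelled processes, not
detection power on real data with annotation noise.

## Numerical and procedural conventions

* Threshold wording is implemented literally: duplication and NUMT gates
  are inclusive ("at least 50%"); intron similarity gates are strict
  ("higher than 60 and 50%").
* Rounding is half-up at the printed precision (two decimals for fractions
  and GC, one for cohort shares).
* Report tables are sorted on their columns left-to-right before writing,
  so identical inputs give byte-identical TSVs.
* Degenerate inputs: empty sequences raise; all-N sequences have undefined
  GC; freestanding introns have no insertion site (error); a species
  missing a clock gene is excluded from the dS matrix with a logged reason;
  fewer than two genomes skips the clock stage.
* Problem sizes in the test and acceptance runs (8-leaf default tree,
  ~30 kb genomes, 2×15 kb decoys per leaf, 100-shuffle nulls) were chosen
  as the smallest configuration in which every recovery property is
  comfortably measurable; the recovery seeds are 41–43.

## Known limitations

* The intron prefilter can in principle miss a qualifying pair whose
  identity hovers just above 50% with no exact 11-mer; disable it for
  exhaustive runs.
* Empirical E-values depend on the shuffled-null model (composition
  preserved, order destroyed); an analytic Karlin–Altschul mode is a
  config hook left unimplemented.
* Codon alignment is protein-guided, so it cannot represent
  frame-disrupting indels; such regions should be pre-aligned externally
  and passed in codon-aligned form.
* `compare_orders` reports neighbor-set displacements only; it is not a
  rearrangement distance.
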