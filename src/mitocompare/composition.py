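"""Genome compartment accounting.

Every base of a mitogenome is assigned to exactly one of four compartments:

* **coding** — protein-gene exons, rRNA exons and tRNAs;
* **HEG/uORF** — homing endonuclease genes and unassigned ORFs (pooled);
* **intron** — intronic bases not claimed above;
* **intergenic** — everything else.

Precedence is coding > HEG/uORF > intron > intergenic, so the four lengths
always sum exactly to the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .records import GenomeRecord

_INTERGENIC, _INTRON, _HEG_UORF, _CODING = 0, 1, 2, 3

_KIND_CODE = {
    "protein_gene": _CODING,
    "rRNA": _CODING,
    "tRNA": _CODING,
    "HEG": _HEG_UORF,
    "uORF": _HEG_UORF,
    "intron": _INTRON,
}


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CompositionReport:
    genome_id: str
    L: int
    coding_len: int
    intron_len: int
    heg_uorf_len: int
    intergenic_len: int
    gc_percent: float | None
    counts: dict[str, int] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def fraction(self, compartment: str) -> float:
        """Compartment share as a percentage of L, rounded to two decimals."""
        value = getattr(self, f"{compartment}_len")
        return round_half_up(100.0 * value / self.L, 2)


def gc_content(seq: str) -> float | None:
    """GC percentage over unambiguous bases, two decimals, half-up.

    ``N`` is excluded from numerator and denominator; a sequence of only N
    has no defined GC content and returns ``None``.
    """
    if not seq:
        raise ValueError("gc_content: empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return round_half_up(100.0 * gc / (gc + at), 2)


def partition_genome(g: GenomeRecord) -> CompositionReport:
    """Assign every base of ``g`` to one compartment and count elements.

    Overlapping protein-gene exons from distinct genes are flagged in
    ``conflicts`` but each base still counts once (as coding).
    """
    L = g.length
    code = np.zeros(L, dtype=np.int8)
    owner = np.full(L, -1, dtype=np.int32)  # index of the coding feature claiming a base
    conflicts: list[str] = []
    # Paint in ascending precedence so higher compartments overwrite lower.
    for level in (_INTRON, _HEG_UORF, _CODING):
        for idx, f in enumerate(g.features):
            if _KIND_CODE.get(f.kind) != level:
                continue
            for s, e in f.intervals:
                if level == _CODING and f.kind == "protein_gene":
                    clash = owner[s:e]
                    hit = np.unique(clash[clash >= 0])
                    for j in hit:
                        other = g.features[int(j)]
                        if other.name != f.name and other.kind == "protein_gene":
                            conflicts.append(
                                f"overlapping protein-gene exons: {other.name} / {f.name}"
                            )
                    owner[s:e] = idx
                code[s:e] = level
    counts = {
        "genes": sum(1 for f in g.features if f.kind in ("protein_gene", "rRNA")),
        "tRNAs": sum(1 for f in g.features if f.kind == "tRNA"),
        "introns": sum(1 for f in g.features if f.kind == "intron"),
        "HEGs": sum(1 for f in g.features if f.kind == "HEG"),
        "uORFs": sum(1 for f in g.features if f.kind == "uORF"),
    }
    n = np.bincount(code, minlength=4)
    return CompositionReport(
        genome_id=g.id,
        L=L,
        coding_len=int(n[_CODING]),
        intron_len=int(n[_INTRON]),
        heg_uorf_len=int(n[_HEG_UORF]),
        intergenic_len=int(n[_INTERGENIC]),
        gc_percent=gc_content(g.sequence),
        counts=counts,
        conflicts=sorted(set(conflicts)),
    )


def composition_table(reports: list[CompositionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "genome_id": r.genome_id,
                "length_bp": r.L,
                "coding_bp": r.coding_len,
                "intron_bp": r.intron_len,
                "heg_uorf_bp": r.heg_uorf_len,
                "intergenic_bp": r.intergenic_len,
                "coding_pct": r.fraction("coding"),
                "intron_pct": r.fraction("intron"),
                "heg_uorf_pct": r.fraction("heg_uorf"),
                "intergenic_pct": r.fraction("intergenic"),
                "gc_pct": r.gc_percent,
                "n_genes": r.counts.get("genes", 0),
                "n_tRNAs": r.counts.get("tRNAs", 0),
                "n_introns": r.counts.get("introns", 0),
                "n_HEGs": r.counts.get("HEGs", 0),
                "n_uORFs": r.counts.get("uORFs", 0),
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    reports: list[CompositionReport],
    intron_class_counts: dict[str, int] | None = None,
    heg_family_counts: dict[str, int] | None = None,
) -> dict:
    """Cohort-level summary: genome-length stats and class shares.

    Shares (e.g. the fraction of introns in subclass IB among all introns)
    are percentages rounded to one decimal, half-up.
    """
    if not reports:
        raise ValueError("summarize_cohort: need at least one report")
    lengths = [r.L for r in reports]
    summary: dict = {
        "n_genomes": len(reports),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "mean_length": round_half_up(sum(lengths) / len(lengths), 1),
        "totals": {
            key: sum(r.counts.get(key, 0) for r in reports)
            for key in ("genes", "tRNAs", "introns", "HEGs", "uORFs")
        },
    }
    for label, counts in (
        ("intron_class_shares", intron_class_counts),
        ("heg_family_shares", heg_family_counts),
    ):
        if counts:
            total = sum(counts.values())
            summary[label.replace("shares", "counts")] = dict(counts)
            summary[label] = {
                k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()
            }
    return summary


def cohort_class_counts(genomes) -> tuple[dict[str, int], dict[str, int]]:
    """Tally intron subclasses and HEG families across annotated genomes."""
    intron_counts: dict[str, int] = {}
    heg_counts: dict[str, int] = {}
    for g in genomes:
        for f in g.features:
            if f.kind == "intron":
                intron_counts[f.intron_class] = intron_counts.get(f.intron_class, 0) + 1
            elif f.kind == "HEG":
                heg_counts[f.heg_family] = heg_counts.get(f.heg_family, 0) + 1
    return intron_counts, heg_counts
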