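"""Core in-memory types for annotated mitogenomes.

Coordinates are 0-based half-open everywhere inside the package; the GenBank
1-based inclusive convention exists only at the I/O boundary.  Features on
circular genomes may span the origin, in which case they carry an ordered
multi-interval location (never a silently rotated sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

# The 17 conserved elements of Hypocreales mitogenomes: 14 oxidative
# phosphorylation genes, the two rRNAs and the ribosomal protein gene rps3.
CORE_PROTEIN_GENES = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
CORE_GENES = CORE_PROTEIN_GENES + ("rps3", "rrnS", "rrnL")

FEATURE_KINDS = ("protein_gene", "rRNA", "tRNA", "intron", "HEG", "uORF", "exon")
INTRON_CLASSES = ("IA", "IB", "IC1", "IC2", "ID", "II", "unknown")
HEG_FAMILIES = ("LAGLIDADG", "GIY-YIG", "none")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RecordError(ValueError):
    """Raised when a genome record or feature violates its invariants."""


@dataclass
class FeatureRecord:
    """A located genome element.

    ``intervals`` are stored in biological (5'->3') order; for a minus-strand
    feature the spliced sequence is the concatenation of the reverse
    complements of the intervals in that order.

    ``parent`` links an intron to its host gene name and a nested HEG to its
    host intron id (``None`` for freestanding elements).
    """

    kind: str
    name: str
    intervals: list[tuple[int, int]]
    strand: str = "+"
    parent: Optional[str] = None
    intron_class: str = "unknown"
    heg_family: str = "none"
    feature_id: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise RecordError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise RecordError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise RecordError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise RecordError(
                    f"feature {self.name!r}: bad interval ({s}, {e}); need 0 <= start < end"
                )
        if self.intron_class not in INTRON_CLASSES:
            raise RecordError(f"unknown intron class {self.intron_class!r}")
        if self.heg_family not in HEG_FAMILIES:
            raise RecordError(f"unknown HEG family {self.heg_family!r}")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        """5'-most genomic coordinate of the feature's first biological interval."""
        s, e = self.intervals[0]
        return s if self.strand == "+" else e - 1

    def span(self) -> tuple[int, int]:
        """Genomic bounding interval (ignores origin wrap)."""
        return min(s for s, _ in self.intervals), max(e for _, e in self.intervals)


@dataclass
class GenomeRecord:
    """One annotated mitochondrial genome with an ordered feature table."""

    id: str
    sequence: str
    species: str = ""
    family: Optional[str] = None
    topology: str = "circular"
    features: list[FeatureRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> list[str]:
        """Check record invariants; return a list of non-fatal warnings.

        Fatal violations (intervals outside [0, L), bad alphabet, intron not
        inside its host gene) raise :class:`RecordError`.
        """
        warnings: list[str] = []
        allowed = set("ACGTN")
        bad = set(self.sequence) - allowed
        if bad:
            raise RecordError(f"{self.id}: sequence contains non-ACGTN characters {sorted(bad)}")
        L = self.length
        by_name = {}
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= L):
                    raise RecordError(
                        f"{self.id}: feature {f.name!r} interval ({s}, {e}) outside [0, {L})"
                    )
            if "N" in self.spliced_sequence(f):
                if "contains_N" not in f.flags:
                    f.flags.append("contains_N")
                warnings.append(f"{self.id}: feature {f.name!r} contains ambiguous base N")
            by_name.setdefault((f.kind, f.name), []).append(f)
        gene_cover = {
            f.name: _interval_union(f.intervals, self._gene_span_intervals(f))
            for f in self.features
            if f.kind in ("protein_gene", "rRNA")
        }
        for f in self.features:
            if f.kind == "intron" and f.parent is not None:
                cover = gene_cover.get(f.parent)
                if cover is None:
                    warnings.append(
                        f"{self.id}: intron {f.feature_id or f.name} names absent host gene {f.parent!r}"
                    )
                elif not _contained(f.intervals, cover):
                    raise RecordError(
                        f"{self.id}: intron {f.feature_id or f.name} not contained in host gene "
                        f"{f.parent!r} span"
                    )
        introns = {f.feature_id: f for f in self.features if f.kind == "intron"}
        for f in self.features:
            if f.kind == "HEG" and f.parent is not None:
                host = introns.get(f.parent)
                if host is None:
                    warnings.append(
                        f"{self.id}: HEG {f.feature_id or f.name} names absent host intron {f.parent!r}"
                    )
                elif not _contained(f.intervals, _as_cover(host.intervals)):
                    raise RecordError(
                        f"{self.id}: HEG {f.feature_id or f.name} not contained in host intron {f.parent!r}"
                    )
        return warnings

    def _gene_span_intervals(self, gene: FeatureRecord) -> list[tuple[int, int]]:
        """Genomic span of a gene including its introns (handles origin wrap)."""
        ivs = sorted(gene.intervals)
        if len(ivs) == 1:
            return list(ivs)
        # Detect origin wrap: biological order jumps from high to low coordinates.
        ordered = gene.intervals if gene.strand == "+" else gene.intervals[::-1]
        wraps = any(ordered[i][0] > ordered[i + 1][0] for i in range(len(ordered) - 1))
        if wraps and self.topology == "circular":
            lo = min(s for s, _ in ivs)
            hi = max(e for _, e in ivs)
            # Span runs hi-side to origin plus origin to lo-side; approximate by
            # the two extremal blocks around the origin.
            first = ordered[0]
            last = ordered[-1]
            return [(first[0], self.length), (0, last[1])]
        return [(ivs[0][0], ivs[-1][1])]

    def spliced_sequence(self, f: FeatureRecord) -> str:
        parts = [self.sequence[s:e] for s, e in f.intervals]
        if f.strand == "-":
            return "".join(reverse_complement(p) for p in parts)
        return "".join(parts)

    def rotate(self, offset: int) -> "GenomeRecord":
        """Return the record with the origin moved to ``offset`` (circular only).

        Feature intervals are remapped; an interval crossing the new origin is
        split into an ordered two-interval location.
        """
        if self.topology != "circular":
            raise RecordError(f"{self.id}: cannot rotate a linear genome")
        L = self.length
        k = offset % L
        seq = self.sequence[k:] + self.sequence[:k]
        feats = []
        for f in self.features:
            ivs: list[tuple[int, int]] = []
            for s, e in f.intervals:
                ns, ne = (s - k) % L, (e - k) % L or L
                if ns < ne:
                    ivs.append((ns, ne))
                else:  # crosses the new origin
                    ivs.append((ns, L))
                    ivs.append((0, ne))
            feats.append(
                FeatureRecord(
                    kind=f.kind, name=f.name, intervals=ivs, strand=f.strand,
                    parent=f.parent, intron_class=f.intron_class,
                    heg_family=f.heg_family, feature_id=f.feature_id,
                    flags=list(f.flags),
                )
            )
        return GenomeRecord(
            id=self.id, sequence=seq, species=self.species, family=self.family,
            topology=self.topology, features=feats,
        )

    def reverse_complement(self) -> "GenomeRecord":
        L = self.length
        seq = reverse_complement(self.sequence)
        feats = []
        for f in self.features:
            ivs = [(L - e, L - s) for s, e in f.intervals]
            feats.append(
                FeatureRecord(
                    kind=f.kind, name=f.name, intervals=ivs,
                    strand="-" if f.strand == "+" else "+",
                    parent=f.parent, intron_class=f.intron_class,
                    heg_family=f.heg_family, feature_id=f.feature_id,
                    flags=list(f.flags),
                )
            )
        return GenomeRecord(
            id=self.id, sequence=seq, species=self.species, family=self.family,
            topology=self.topology, features=feats,
        )


@dataclass
class NuclearContigSet:
    """Nuclear contigs searched for mitochondrial gene transfers (NUMTs)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise RecordError("empty contig id")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise RecordError(f"contig {cid!r}: non-ACGTN characters {sorted(bad)}")


def _as_cover(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    return sorted(intervals)


def _interval_union(a, b) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(list(a) + list(b)):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _contained(inner, cover) -> bool:
    cover = _interval_union(cover, [])
    for s, e in inner:
        if not any(cs <= s and e <= ce for cs, ce in cover):
            return False
    return True
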