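"""GenBank / FASTA input and TSV report output.

The GenBank dialect read and written here encodes the annotation the pipeline
consumes (classification itself is upstream and out of scope):

==============  ==========================  =========================================
feature key     qualifiers                  mapped to
==============  ==========================  =========================================
CDS             /gene                       kind ``protein_gene`` (location parts = exons)
CDS             /gene /heg_family           kind ``HEG``; /parent_intron -> host intron id
CDS             /gene /orf_type="uORF"      kind ``uORF``
rRNA            /gene (rrnS, rrnL)          kind ``rRNA``
tRNA            /gene (trnX)                kind ``tRNA``
intron          /gene (host) /intron_id     kind ``intron``; /intron_class in
                                            {IA, IB, IC1, IC2, ID, II}
==============  ==========================  =========================================

Absent ``intron_class`` / ``heg_family`` qualifiers fall back to
``unknown`` / ``none`` with a logged warning, never a guess.  GenBank's
1-based inclusive coordinates are converted to 0-based half-open on read and
back on write; origin-spanning ``join(...)`` locations become ordered
multi-interval features.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import (
    FeatureRecord,
    GenomeRecord,
    NuclearContigSet,
    RecordError,
)

logger = logging.getLogger(__name__)


class ParseError(RecordError):
    """Fatal parse failure (malformed location, sequence/feature mismatch)."""


def _q(feat: SeqFeature, key: str) -> str | None:
    vals = feat.qualifiers.get(key)
    return vals[0] if vals else None


def _intervals_from_location(feat: SeqFeature, record_id: str) -> tuple[list[tuple[int, int]], str]:
    loc = feat.location
    if loc is None:
        raise ParseError(f"{record_id}: feature {feat.type} has no parseable location")
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    # Biopython orders CompoundLocation parts biologically for complement(join(..)).
    ivs = [(int(p.start), int(p.end)) for p in parts]
    for s, e in ivs:
        if s >= e:
            raise ParseError(
                f"{record_id}: feature {feat.type} has an empty or inverted interval ({s}, {e})"
            )
    return ivs, strand


def _classify(feat: SeqFeature, record_id: str) -> FeatureRecord | None:
    name = _q(feat, "gene") or _q(feat, "product") or _q(feat, "note")
    ivs, strand = _intervals_from_location(feat, record_id)
    if feat.type == "CDS":
        if _q(feat, "heg_family") is not None:
            fam = _q(feat, "heg_family")
            if fam not in ("LAGLIDADG", "GIY-YIG"):
                logger.warning("%s: unrecognized heg_family %r; using 'none'", record_id, fam)
                fam = "none"
            return FeatureRecord(
                kind="HEG", name=name or "heg", intervals=ivs, strand=strand,
                parent=_q(feat, "parent_intron"), heg_family=fam,
                feature_id=_q(feat, "locus_tag"),
            )
        if (_q(feat, "orf_type") or "").lower() == "uorf":
            return FeatureRecord(
                kind="uORF", name=name or "uorf", intervals=ivs, strand=strand,
                feature_id=_q(feat, "locus_tag"),
            )
        if name is None:
            raise ParseError(f"{record_id}: CDS feature at {ivs} lacks a /gene qualifier")
        return FeatureRecord(
            kind="protein_gene", name=name, intervals=ivs, strand=strand,
            feature_id=_q(feat, "locus_tag"),
        )
    if feat.type == "rRNA":
        if name is None:
            raise ParseError(f"{record_id}: rRNA feature at {ivs} lacks a /gene qualifier")
        return FeatureRecord(kind="rRNA", name=name, intervals=ivs, strand=strand,
                             feature_id=_q(feat, "locus_tag"))
    if feat.type == "tRNA":
        return FeatureRecord(kind="tRNA", name=name or "trn?", intervals=ivs, strand=strand,
                             feature_id=_q(feat, "locus_tag"))
    if feat.type == "intron":
        cls = _q(feat, "intron_class")
        if cls is None:
            logger.warning("%s: intron at %s lacks /intron_class; using 'unknown'", record_id, ivs)
            cls = "unknown"
        elif cls not in ("IA", "IB", "IC1", "IC2", "ID", "II"):
            logger.warning("%s: unrecognized intron_class %r; using 'unknown'", record_id, cls)
            cls = "unknown"
        return FeatureRecord(
            kind="intron", name=name or "intron", intervals=ivs, strand=strand,
            parent=_q(feat, "gene"), intron_class=cls,
            feature_id=_q(feat, "intron_id") or _q(feat, "locus_tag"),
        )
    return None  # source, gene, misc_feature etc. are ignored


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read annotated mitogenome records from a GenBank flat file.

    Returns one :class:`GenomeRecord` per LOCUS; raises :class:`ParseError`
    on malformed locations or a sequence/feature length mismatch.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        topology = rec.annotations.get("topology", "linear")
        taxonomy = rec.annotations.get("taxonomy") or []
        feats: list[FeatureRecord] = []
        for feat in rec.features:
            try:
                fr = _classify(feat, rec.id)
            except RecordError:
                raise
            if fr is not None:
                feats.append(fr)
        g = GenomeRecord(
            id=rec.id,
            sequence=seq,
            species=rec.annotations.get("organism", rec.id),
            family=taxonomy[-1] if taxonomy else None,
            topology=topology,
            features=feats,
        )
        try:
            for w in g.validate():
                logger.warning(w)
        except RecordError as exc:
            raise ParseError(str(exc)) from exc
        records.append(g)
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    return records


def _to_seqfeature(f: FeatureRecord, L: int) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    quals: dict[str, list[str]] = {}
    ftype = {"protein_gene": "CDS", "HEG": "CDS", "uORF": "CDS",
             "rRNA": "rRNA", "tRNA": "tRNA", "intron": "intron"}[f.kind]
    quals["gene"] = [f.parent if f.kind == "intron" and f.parent else f.name]
    if f.kind == "intron":
        if f.feature_id:
            quals["intron_id"] = [f.feature_id]
        if f.intron_class != "unknown":
            quals["intron_class"] = [f.intron_class]
    elif f.feature_id:
        quals["locus_tag"] = [f.feature_id]
    if f.kind == "HEG":
        quals["heg_family"] = [f.heg_family]
        if f.parent:
            quals["parent_intron"] = [f.parent]
    if f.kind == "uORF":
        quals["orf_type"] = ["uORF"]
    return SeqFeature(loc, type=ftype, qualifiers=quals)


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records back to the GenBank dialect documented in this module."""
    out = []
    for g in records:
        rec = SeqRecord(
            Seq(g.sequence),
            id=g.id,
            name=g.id[:16],
            description=g.species,
            annotations={
                "molecule_type": "DNA",
                "topology": g.topology,
                "organism": g.species,
                "taxonomy": [g.family] if g.family else [],
            },
        )
        rec.features = [_to_seqfeature(f, g.length) for f in g.features]
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


def read_fasta_contigs(path: str | Path) -> NuclearContigSet:
    """Read nuclear contigs from a FASTA file."""
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return NuclearContigSet(contigs=contigs)


def write_reports(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict:
    """Write one TSV per table plus a JSON manifest.

    Rows are sorted on the table's columns left to right (stable, documented)
    so identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": []}
    for name in sorted(tables):
        df = tables[name]
        if len(df):
            df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
        dest = outdir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, lineterminator="\n")
        manifest["tables"].append({"name": name, "file": dest.name, "rows": int(len(df))})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
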