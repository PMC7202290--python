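"""End-to-end orchestration: composition -> synteny -> introns -> numt -> clock.

Each stage contributes one or more TSV report tables; a JSON manifest records
the package version, a config digest, per-stage warnings and which stages
completed.  Reruns on identical inputs and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, composition, introns, molclock, numt, synteny
from .config import PipelineConfig
from .io import write_reports
from .records import GenomeRecord, NuclearContigSet

logger = logging.getLogger("mitocompare")


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(
    genomes: list[GenomeRecord],
    config: PipelineConfig | None = None,
    nuclear: NuclearContigSet | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the manifest.  A stage that raises is recorded as failed and the
    remaining stages still run; the manifest carries the partial-completion
    state and the caller decides the exit code.
    """
    cfg = config or PipelineConfig()
    dest = Path(outdir or cfg.outdir)
    root = logging.getLogger("mitocompare")
    collector = _WarningCollector()
    root.addHandler(collector)
    tables: dict[str, pd.DataFrame] = {}
    stages: dict[str, dict] = {}

    def stage(name: str, fn) -> None:
        before = len(collector.messages)
        try:
            fn()
            stages[name] = {"status": "ok"}
        except Exception as exc:  # recorded, not fatal to later stages
            logger.warning("stage %s failed: %s", name, exc)
            stages[name] = {"status": "failed", "error": str(exc)}
        stages[name]["warnings"] = sorted(set(collector.messages[before:]))

    def do_composition() -> None:
        reports = [composition.partition_genome(g) for g in genomes]
        tables["composition"] = composition.composition_table(reports)
        icounts, hcounts = composition.cohort_class_counts(genomes)
        summary = composition.summarize_cohort(reports, icounts, hcounts)
        tables["cohort_summary"] = pd.DataFrame(
            [{"key": k, "value": json.dumps(v) if isinstance(v, dict) else v}
             for k, v in summary.items()]
        )

    def do_synteny() -> None:
        orders = [synteny.gene_order(g) for g in genomes]
        tables["gene_orders"] = synteny.orders_table(orders)
        dups = []
        for g in genomes:
            for p in synteny.find_duplicate_genes(
                    g, cfg.duplication_min_identity, cfg.duplication_min_coverage):
                dups.append({"genome_id": g.id, "gene": p.gene, "copy_a": p.copy_a,
                             "copy_b": p.copy_b, "identity": round(p.identity, 2),
                             "coverage": round(p.coverage, 2),
                             "intact_a": p.intact_a, "intact_b": p.intact_b})
        tables["duplications"] = pd.DataFrame(
            dups, columns=["genome_id", "gene", "copy_a", "copy_b", "identity",
                           "coverage", "intact_a", "intact_b"])
        if len(orders) >= 2:
            tables["displacements"] = synteny.compare_orders(orders)

    def do_introns() -> None:
        infos = introns.collect_introns(genomes)
        graph = introns.build_sharing_graph(
            infos, scoring=cfg.dna_scoring, prefilter=cfg.prefilter,
            min_coverage=cfg.intron_min_coverage, min_identity=cfg.intron_min_identity)
        tables.update(introns.sharing_tables(graph))
        tables["insertion_positions"] = introns.conservation_table(genomes)

    def do_numt() -> None:
        rows = []
        for g in genomes:
            # The search mirrors the study design: each species' genes
            # against its own nuclear genome.  Contig ids prefixed with the
            # genome id select that genome's contigs; otherwise all contigs
            # are searched.
            own = {cid: s for cid, s in nuclear.contigs.items()
                   if cid.startswith(f"{g.id}_")}
            nuc_g = NuclearContigSet(contigs=own) if own else nuclear
            for h in numt.find_numts(
                    g, nuc_g, nulls=cfg.numt_nulls, seed=cfg.seed,
                    min_identity=cfg.numt_min_identity,
                    min_coverage=cfg.numt_min_coverage,
                    max_evalue=cfg.numt_max_evalue):
                rows.append({"genome_id": g.id, "gene": h.gene, "mode": h.mode,
                             "contig": h.contig, "start": h.contig_interval[0],
                             "end": h.contig_interval[1], "strand": h.strand,
                             "identity": round(h.identity, 2),
                             "coverage": round(h.coverage, 2),
                             "evalue": h.evalue})
        tables["numts"] = pd.DataFrame(
            rows, columns=["genome_id", "gene", "mode", "contig", "start", "end",
                           "strand", "identity", "coverage", "evalue"])

    def do_clock() -> None:
        if len(genomes) < 2:
            logger.warning("clock: skipped, need at least two genomes")
            return
        mat, _results = molclock.pairwise_ds_matrix(genomes)
        tables["ds_matrix"] = mat.reset_index(names="species")
        bars = [molclock.mean_ds(mat, sp) for sp in mat.index]
        tables["ds_bar"] = pd.DataFrame(
            [{"species": b.species, "ds_bar": round(b.ds_bar, 6),
              "pairs_used": b.pairs_used, "flags": ";".join(b.flags)} for b in bars])
        reports = {r.genome_id: r for r in (composition.partition_genome(g) for g in genomes)}
        by_species = {g.species or g.id: reports[g.id] for g in genomes}
        rows = []
        dsb = {b.species: b.ds_bar for b in bars}
        common = [sp for sp in dsb if sp in by_species]
        if len(common) >= 3:
            x = [dsb[sp] for sp in common]
            for label, getter in (
                ("genome_length", lambda r: r.L),
                ("intron_length", lambda r: r.intron_len),
                ("heg_uorf_length", lambda r: r.heg_uorf_len),
                ("coding_length", lambda r: r.coding_len),
            ):
                res = molclock.correlate(x, [getter(by_species[sp]) for sp in common],
                                         variables=("ds_bar", label))
                rows.append({"x": "ds_bar", "y": label,
                             "r": None if res.r is None else round(res.r, 4),
                             "p": None if res.p is None else round(res.p, 6),
                             "n": res.n})
        tables["correlations"] = pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])

    stage("composition", do_composition)
    stage("synteny", do_synteny)
    stage("introns", do_introns)
    if nuclear is not None:
        stage("numt", do_numt)
    stage("clock", do_clock)
    root.removeHandler(collector)

    manifest = write_reports(tables, dest)
    manifest.update({
        "version": __version__,
        "config_digest": cfg.digest(),
        "stages": stages,
        "ok": all(s["status"] == "ok" for s in stages.values()),
    })
    with open(dest / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
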