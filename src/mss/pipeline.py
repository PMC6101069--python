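"""End-to-end orchestration: select reference species, annotate contigs,
and run enrichment, writing TSV reports plus a JSON run summary.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align, enrichment as enrich_mod, taxonomy, uco
from .errors import MSSError, NoUCOContigsError, QueryNotInTaxonomyError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # selection inputs: taxonomy route and/or sequence (UCO) route
    taxdump_dir: str | None = None
    query_taxid: int | None = None
    candidates_file: str | None = None
    contigs: str | None = None
    uco_fasta: str | None = None
    proteome_dir: str | None = None
    annotation_dir: str | None = None
    de_list: str | None = None
    outdir: str = "mss_out"
    # thresholds
    aligner: str = "builtin"
    evalue_max: float = align.DEFAULT_EVALUE_MAX
    tax_min: int = taxonomy.DEFAULT_MIN_SPECIES
    tax_max: int = taxonomy.DEFAULT_MAX_SPECIES
    uco_top_k: int = 3
    alpha: float = enrich_mod.DEFAULT_ALPHA
    seed: int = 0

    def validate(self) -> None:
        if self.evalue_max <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")
        if self.tax_min > self.tax_max:
            raise ValueError(f"tax_min {self.tax_min} > tax_max {self.tax_max}")
        if self.uco_top_k < 1:
            raise ValueError("uco_top_k must be >= 1")
        has_tax = self.taxdump_dir and self.query_taxid
        has_uco = self.contigs and self.uco_fasta and self.proteome_dir
        if not (has_tax or has_uco):
            raise ValueError(
                "need either a taxonomy route (taxdump_dir + query_taxid) or "
                "a UCO route (contigs + uco_fasta + proteome_dir)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _load_proteomes(proteome_dir) -> dict[str, list[align.SequenceRecord]]:
    proteomes = {}
    for path in sorted(Path(proteome_dir).glob("*.fasta")):
        proteomes[path.stem] = align.read_fasta(path, alphabet=align.PROTEIN)
    if not proteomes:
        raise MSSError(f"no *.fasta proteomes under {proteome_dir}")
    return proteomes


def _load_tables(annotation_dir, species) -> dict[str, enrich_mod.AnnotationTable]:
    tables = {}
    adir = Path(annotation_dir) if annotation_dir else None
    for sp in species:
        go_p = adir / f"{sp}.go.tsv" if adir else None
        pw_p = adir / f"{sp}.pathway.tsv" if adir else None
        tables[sp] = enrich_mod.read_annotation_table(
            sp,
            go_path=go_p if go_p and go_p.exists() else None,
            pathway_path=pw_p if pw_p and pw_p.exists() else None)
    return tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Run select -> annotate -> merge -> enrich and write all reports.

    Returns the run report (also written as ``report.json``): selected
    species per route, per-species and merged annotation counts, and the
    significant GO terms / pathways.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": []}

    # --- selection: taxonomy route
    tax_names: dict[int, str] = {}
    if config.taxdump_dir and config.query_taxid:
        report["stages"].append("select-tax")
        tdir = Path(config.taxdump_dir)
        tree = taxonomy.parse_taxdump((tdir / "nodes.dmp").read_text(),
                                      (tdir / "names.dmp").read_text())
        candidates = [
            int(x) for x in Path(config.candidates_file).read_text().split()
        ] if config.candidates_file else [
            t for t, n in tree.nodes.items()
            if n.rank == "species" and t != config.query_taxid
        ]
        try:
            sel = taxonomy.select_by_taxonomy(
                tree, config.query_taxid, candidates,
                min_n=config.tax_min, max_n=config.tax_max)
            tax_names = sel.names
            df = pd.DataFrame(
                [(tid, sel.names[tid], score, sel.ranks[tid])
                 for tid, score in sel.ranked],
                columns=["species_id", "name", "lca_depth", "rank"])
            df.to_csv(outdir / "tax_selection.tsv", sep="\t", index=False)
            report["taxonomy_selection"] = {
                "query": sel.query,
                "ranked": [[tid, sel.names[tid], score]
                           for tid, score in sel.ranked],
                "warning": sel.warning,
            }
        except QueryNotInTaxonomyError as exc:
            logger.warning("select-tax: %s", exc)
            report["taxonomy_selection"] = {"error": str(exc)}

    # --- selection: UCO route
    selected: list[str] = []
    contig_records: list[align.SequenceRecord] = []
    if config.contigs and config.uco_fasta and config.proteome_dir:
        report["stages"].append("select-uco")
        contig_records = align.read_fasta(config.contigs, alphabet=align.NUCLEOTIDE)
        uco_refs = align.read_fasta(config.uco_fasta, alphabet=align.PROTEIN)
        proteomes = _load_proteomes(config.proteome_dir)
        profiles = uco.build_uco_profiles(uco_refs, proteomes,
                                          evalue_max=config.evalue_max)
        assignments = uco.find_uco_contigs(contig_records, uco_refs,
                                           evalue_max=config.evalue_max)
        try:
            ranking = uco.rank_species_by_uco(
                assignments, {c.id: c for c in contig_records}, profiles,
                top_k=config.uco_top_k)
            pd.DataFrame(
                [(sp, votes, ranking.distinct_ucos.get(sp, 0), i + 1)
                 for i, (sp, votes) in enumerate(ranking.ranked)],
                columns=["species_id", "mapped_uco_count", "distinct_ucos",
                         "rank"],
            ).to_csv(outdir / "uco_ranking.tsv", sep="\t", index=False)
            selected = ranking.top
            report["uco_selection"] = {
                "ranked": [[sp, votes] for sp, votes in ranking.ranked],
                "selected": selected,
                "n_uco_contigs": len(assignments),
            }
        except NoUCOContigsError as exc:
            logger.warning("select-uco: %s", exc)
            report["uco_selection"] = {"error": str(exc)}
        uco.uco_completeness_summary(profiles).to_csv(
            outdir / "uco_completeness.tsv", sep="\t", index=False)

    if not selected and tax_names:
        # fall back to taxonomy-selected species named like the proteome files
        selected = sorted(tax_names.values())
    if not selected:
        raise MSSError("no reference species could be selected by either route")
    report["selected_species"] = selected

    # --- annotation + enrichment (needs contigs and proteomes)
    if contig_records and config.proteome_dir:
        report["stages"].append("annotate")
        proteomes = _load_proteomes(config.proteome_dir)
        missing = [s for s in selected if s not in proteomes]
        if missing:
            raise MSSError(f"selected species without proteome: {missing}")
        sel_proteomes = {s: proteomes[s] for s in selected}
        tables = _load_tables(config.annotation_dir, selected)
        amap = enrich_mod.annotate_contigs(
            contig_records, sel_proteomes, tables, evalue_max=config.evalue_max)
        per_species = {
            sp: sum(1 for hits in amap.hits.values()
                    for s, _, _ in hits if s == sp)
            for sp in selected
        }
        pd.DataFrame(
            sorted(per_species.items()),
            columns=["species_id", "annotated_contigs"],
        ).to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
        report["annotation"] = {
            "n_contigs": amap.n_contigs_total,
            "n_annotated": amap.n_annotated,
            "per_species": per_species,
            "n_go_annotated": len(amap.merged_terms),
            "n_pathway_annotated": len(amap.merged_pathways),
        }

        if config.de_list:
            report["stages"].append("enrich")
            de_ids = Path(config.de_list).read_text().split()
            for kind, fname in ((enrich_mod.GO, "enrichment_go.tsv"),
                                (enrich_mod.PATHWAY, "enrichment_pathway.tsv")):
                try:
                    rows = enrich_mod.enrich(de_ids, amap, kind=kind,
                                             alpha=config.alpha)
                except ValueError as exc:
                    logger.warning("enrich %s: %s", kind, exc)
                    report[f"enrichment_{kind}"] = {"error": str(exc)}
                    continue
                enrich_mod.enrichment_frame(rows).to_csv(
                    outdir / fname, sep="\t", index=False)
                report[f"enrichment_{kind}"] = {
                    "n_terms_tested": len(rows),
                    "significant": [r.term_id for r in rows if r.significant],
                    "significant_bh": [r.term_id for r in rows
                                       if r.significant_bh],
                }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
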