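"""Annotation transfer from selected reference species and hypergeometric
GO / pathway enrichment of a differentially-expressed (DE) gene list.

Each query contig is searched (translated) against every selected species'
proteome; the best hit per species passing the E-value threshold defines a
putative ortholog, and the contig inherits the union of GO terms and
pathway ids of its orthologs across species.  Over-representation of a term
in the DE list is scored by the upper tail of the hypergeometric
distribution: P(X >= k) with N annotated background contigs, K carrying the
term, n DE contigs and k DE carriers.  Raw p < alpha follows the common
convention for calling a term significant; Benjamini-Hochberg adjusted
values are reported alongside because many terms are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from . import align
from .align import NUCLEOTIDE, SequenceRecord

logger = logging.getLogger(__name__)

GO = "GO"
PATHWAY = "pathway"
DEFAULT_ALPHA = 0.05


@dataclass
class AnnotationTable:
    """Per-species gene -> GO terms / pathway ids, loaded from TSV."""

    species_id: str
    go: dict[str, set[str]] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)

    def terms(self, gene_id: str, kind: str) -> set[str]:
        table = self.go if kind == GO else self.pathways
        return table.get(gene_id, set())


def _read_gene_term_tsv(path) -> dict[str, set[str]]:
    """Read `gene_id<TAB>term[,term...]` rows; duplicate genes merge by union."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, _, terms = line.rstrip("\n").partition("\t")
            ids = {t.strip() for t in terms.split(",") if t.strip()}
            mapping.setdefault(gene, set()).update(ids)
    return mapping


def read_annotation_table(species_id: str, go_path=None,
                          pathway_path=None) -> AnnotationTable:
    return AnnotationTable(
        species_id=species_id,
        go=_read_gene_term_tsv(go_path) if go_path else {},
        pathways=_read_gene_term_tsv(pathway_path) if pathway_path else {},
    )


def write_annotation_table(mapping: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            fh.write(f"{gene}\t{','.join(sorted(mapping[gene]))}\n")


@dataclass
class AnnotationMap:
    """Contig -> per-species best-hit orthologs plus merged term sets."""

    hits: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    merged_terms: dict[str, set[str]] = field(default_factory=dict)
    merged_pathways: dict[str, set[str]] = field(default_factory=dict)
    species: list[str] = field(default_factory=list)
    n_contigs_total: int = 0

    def merged(self, kind: str) -> dict[str, set[str]]:
        return self.merged_terms if kind == GO else self.merged_pathways

    @property
    def n_annotated(self) -> int:
        return len(self.hits)


def annotate_contigs(
    contigs: list[SequenceRecord],
    proteomes: dict[str, list[SequenceRecord]],
    tables: dict[str, AnnotationTable],
    evalue_max: float = align.DEFAULT_EVALUE_MAX,
) -> AnnotationMap:
    """Best-hit ortholog assignment of contigs against each selected species.

    Per contig and species, all six reading frames are aligned against the
    proteome; the best hit passing ``evalue_max`` is recorded (at most one
    gene per contig per species).  A species without an annotation table
    still contributes sequence-level hits, with a warning.
    """
    if not proteomes:
        raise ValueError("no reference proteomes supplied")
    for sp in sorted(proteomes):
        if sp not in tables:
            logger.warning("species %s has no annotation table; "
                           "hits recorded without terms", sp)
    amap = AnnotationMap(species=sorted(proteomes), n_contigs_total=len(contigs))
    for contig in contigs:
        if contig.alphabet != NUCLEOTIDE:
            raise ValueError(f"contig {contig.id!r} is not nucleotide")
        frames = align.six_frame_translate(contig)
        qlen = (len(contig) // 3) or 1
        for species in amap.species:
            prots = proteomes[species]
            if not prots:
                continue
            db_residues = sum(len(p) for p in prots)
            best: tuple[tuple, str, int] | None = None
            for prot in prots:
                score = max(
                    align.smith_waterman(fr, prot, score_only=True).raw_score
                    for fr in frames)
                key = (-score, prot.id)
                if best is None or key < best[0]:
                    best = (key, prot.id, score)
            _, protein_id, raw = best
            if raw <= 0:
                continue
            if align.evalue(raw, qlen, db_residues) < evalue_max:
                gene_id = protein_id
                amap.hits.setdefault(contig.id, []).append(
                    (species, gene_id, align.bit_score(raw)))
    return merge_annotations(amap, tables)


def merge_annotations(amap: AnnotationMap,
                      tables: dict[str, AnnotationTable]) -> AnnotationMap:
    """Union GO terms / pathway ids across contributing species per contig."""
    amap.merged_terms = {}
    amap.merged_pathways = {}
    for contig_id, hits in amap.hits.items():
        terms: set[str] = set()
        paths: set[str] = set()
        for species, gene_id, _ in hits:
            table = tables.get(species)
            if table is None:
                continue
            terms |= table.terms(gene_id, GO)
            paths |= table.terms(gene_id, PATHWAY)
        if terms:
            amap.merged_terms[contig_id] = terms
        if paths:
            amap.merged_pathways[contig_id] = paths
    return amap


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term-carrying genes in a draw of n from a background of N
    genes of which K carry the term.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid background: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_kind: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adjusted: float
    significant: bool      # raw p < alpha
    significant_bh: bool   # BH-adjusted p < alpha


def enrich(
    de_ids: list[str],
    amap: AnnotationMap,
    kind: str = GO,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of terms among DE contigs.

    The background universe is the set of contigs with at least one
    annotation of the requested kind.  One row per term observed in the DE
    set (k >= 1), sorted by ascending raw p then term id; adjusted p is
    Benjamini-Hochberg over the emitted rows.
    """
    if kind not in (GO, PATHWAY):
        raise ValueError(f"kind must be {GO!r} or {PATHWAY!r}")
    if not de_ids:
        raise ValueError("empty DE list")
    merged = amap.merged(kind)
    background = set(merged)
    N = len(background)
    if N == 0:
        raise ValueError(f"no contigs carry {kind} annotations")
    de = set(de_ids) & background
    dropped = len(set(de_ids)) - len(de)
    if dropped:
        logger.warning("%d DE id(s) not in the annotated background; ignored",
                       dropped)
    if not de:
        raise ValueError("no DE id overlaps the annotated background")
    n = len(de)

    term_bg: dict[str, int] = {}
    term_de: dict[str, int] = {}
    for contig, terms in merged.items():
        in_de = contig in de
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if in_de:
                term_de[t] = term_de.get(t, 0) + 1

    rows = []
    for term in sorted(term_de):
        k, K = term_de[term], term_bg[term]
        p = hypergeom_pvalue(k, K, n, N)
        rows.append([term, k, K, p])
    pvals = [r[3] for r in rows]
    padj = stats.false_discovery_control(pvals, method="bh") if rows else []
    out = [
        EnrichmentRow(term_id=term, term_kind=kind, k=k, K=K, n=n, N=N,
                      p_raw=p, p_adjusted=float(q),
                      significant=p < alpha, significant_bh=float(q) < alpha)
        for (term, k, K, p), q in zip(rows, padj)
    ]
    out.sort(key=lambda r: (r.p_raw, r.term_id))
    return out


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
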