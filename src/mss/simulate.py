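"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here with a known answer:
a random ranked taxonomy serialized in taxdump dialect; UCO proteomes
evolved along that taxonomy (uniform amino-acid replacement, per-site
substitution probability proportional to path length, so pairwise identity
decays with tree distance); query contigs as codon back-translations of
protein fragments on a random strand; and annotation tables with one term
planted at a chosen fold-enrichment in the differentially-expressed list.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .align import NUCLEOTIDE, PROTEIN, SequenceRecord, reverse_complement, write_fasta
from .taxonomy import TaxonNode, TaxonomyTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_INTERNAL_RANKS = ("class", "order", "family", "genus")


@dataclass
class FixtureTruth:
    """Planted ground truth accompanying a generated fixture."""

    seed: int
    species: list[str] = field(default_factory=list)
    species_taxids: dict[str, int] = field(default_factory=dict)
    query_taxid: int | None = None
    closest_species: str | None = None
    divergences: dict[str, float] = field(default_factory=dict)
    rate_per_edge: float | None = None
    contig_sources: dict[str, str] = field(default_factory=dict)
    planted_terms: dict[str, float] = field(default_factory=dict)  # term -> fold
    dropouts: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# taxonomy


def simulate_taxonomy(
    n_species: int,
    max_depth: int = 8,
    seed: int = 0,
    n_phyla: int = 1,
) -> tuple[TaxonomyTree, list[int]]:
    """Random rooted, ranked taxonomy with ``n_species`` species leaves.

    Every species sits under a phylum-rank node; internal chains of random
    length (ranks cycled through class/order/family/genus) keep leaf depths
    varied but below ``max_depth``.  Returns the tree and the species leaf
    taxids in creation order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    nodes: dict[int, TaxonNode] = {1: TaxonNode(1, 1, "no rank", "root")}
    depth = {1: 0}
    next_id = 2
    phyla = []
    for p in range(n_phyla):
        nodes[next_id] = TaxonNode(next_id, 1, "phylum", f"Phylum_{p + 1}")
        depth[next_id] = 1
        phyla.append(next_id)
        next_id += 1
    pool = list(phyla)  # internal nodes a new lineage may attach to
    species_ids = []
    for i in range(n_species):
        parent = int(pool[rng.integers(len(pool))])
        while depth[parent] < max_depth - 1 and rng.random() < 0.5:
            rank = _INTERNAL_RANKS[depth[parent] % len(_INTERNAL_RANKS)]
            nodes[next_id] = TaxonNode(next_id, parent, rank, f"Clade_{next_id}")
            depth[next_id] = depth[parent] + 1
            pool.append(next_id)
            parent = next_id
            next_id += 1
        nodes[next_id] = TaxonNode(next_id, parent, "species", f"Species_{i + 1}")
        depth[next_id] = depth[parent] + 1
        species_ids.append(next_id)
        next_id += 1
    tree = TaxonomyTree(nodes=nodes, root=1)
    tree.validate()
    return tree, species_ids


def write_taxdump(tree: TaxonomyTree, outdir) -> tuple[Path, Path]:
    """Serialize a tree as nodes.dmp / names.dmp in NCBI taxdump dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path, names_path = outdir / "nodes.dmp", outdir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{tid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
    with open(names_path, "w") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{tid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


# ---------------------------------------------------------------------------
# proteome evolution


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(seq: str, p: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability p, uniform over the 19 other
    amino acids (so p is the expected fraction of differing sites)."""
    if not 0 <= p <= 1:
        raise ValueError(f"substitution probability {p} outside [0, 1]")
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < p):
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_proteomes(
    tree: TaxonomyTree,
    species_taxids: list[int],
    n_uco: int,
    rate_per_edge: float,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 200),
    dropouts: dict[int, list[str]] | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[SequenceRecord]], FixtureTruth]:
    """Evolve ``n_uco`` ancestral proteins down the taxonomy to each species.

    Each edge applies ``rate_per_edge`` per-site substitution, so expected
    pairwise identity decays with topological tree distance.  Returns the
    ancestral UCO reference set, per-species proteomes (keyed by species
    name, records headed ``species|UCOid|proteinId``), and the truth.
    ``dropouts`` removes the listed UCO ids from a species' proteome.
    """
    if n_uco < 1:
        raise ValueError("need at least one UCO")
    if rate_per_edge > 1 or rate_per_edge < 0:
        raise ValueError("rate_per_edge must be in [0, 1]")
    rng = np.random.default_rng(seed)
    uco_ids = [f"UCO{i + 1:04d}" for i in range(n_uco)]
    ancestors = {u: random_protein(int(rng.integers(*length_range)), rng)
                 for u in uco_ids}
    uco_refs = [SequenceRecord(id=u, sequence=s, alphabet=PROTEIN)
                for u, s in ancestors.items()]

    # evolve along the tree from the root, memoizing per-node sequences
    node_seqs: dict[int, dict[str, str]] = {tree.root: ancestors}

    def seqs_at(tid: int) -> dict[str, str]:
        if tid not in node_seqs:
            parent = tree.nodes[tid].parent
            node_seqs[tid] = {
                u: mutate_protein(s, rate_per_edge, rng)
                for u, s in seqs_at(parent).items()
            }
        return node_seqs[tid]

    dropouts = dropouts or {}
    proteomes: dict[str, list[SequenceRecord]] = {}
    name_of = {tid: tree.nodes[tid].name for tid in species_taxids}
    for tid in species_taxids:
        name = name_of[tid]
        dropped = set(dropouts.get(tid, []))
        proteomes[name] = [
            SequenceRecord(id=f"{name}|{u}|{u}_p1", sequence=s, alphabet=PROTEIN)
            for u, s in seqs_at(tid).items() if u not in dropped
        ]
    truth = FixtureTruth(
        seed=seed,
        species=[name_of[t] for t in species_taxids],
        species_taxids={name_of[t]: t for t in species_taxids},
        rate_per_edge=rate_per_edge,
        dropouts={str(t): sorted(v) for t, v in dropouts.items()},
    )
    return uco_refs, proteomes, truth


def simulate_star_proteomes(
    divergences: dict[str, float],
    n_uco: int,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 200),
) -> tuple[list[SequenceRecord], dict[str, list[SequenceRecord]], FixtureTruth]:
    """Proteomes independently diverged from one ancestor by per-species
    substitution fractions (a star tree); the species with the smallest
    divergence is the planted closest relative of the ancestor."""
    rng = np.random.default_rng(seed)
    uco_ids = [f"UCO{i + 1:04d}" for i in range(n_uco)]
    ancestors = {u: random_protein(int(rng.integers(*length_range)), rng)
                 for u in uco_ids}
    uco_refs = [SequenceRecord(id=u, sequence=s, alphabet=PROTEIN)
                for u, s in ancestors.items()]
    proteomes = {
        sp: [SequenceRecord(id=f"{sp}|{u}|{u}_p1",
                            sequence=mutate_protein(s, d, rng),
                            alphabet=PROTEIN)
             for u, s in ancestors.items()]
        for sp, d in sorted(divergences.items())
    }
    truth = FixtureTruth(
        seed=seed,
        species=sorted(divergences),
        closest_species=min(sorted(divergences), key=divergences.get),
        divergences=dict(divergences),
    )
    return uco_refs, proteomes, truth


# ---------------------------------------------------------------------------
# transcriptome


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice under the standard genetic code."""
    return "".join(_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
                   for aa in protein)


def simulate_transcriptome(
    source_proteins: list[SequenceRecord],
    n_contigs: int,
    fragment_range: tuple[int, int] = (60, 150),
    seed: int = 0,
) -> tuple[list[SequenceRecord], FixtureTruth]:
    """Contigs as back-translated random fragments of source proteins.

    Each contig takes a random source protein, a random fragment whose
    amino-acid length is drawn from ``fragment_range`` (clipped to the
    protein length), back-translates it with uniform synonymous codons and
    flips to the reverse strand with probability 1/2.  Truth records the
    source protein of every contig.
    """
    if not source_proteins:
        raise ValueError("no source proteins")
    rng = np.random.default_rng(seed)
    lo, hi = fragment_range
    contigs = []
    truth = FixtureTruth(seed=seed)
    for i in range(n_contigs):
        src = source_proteins[rng.integers(len(source_proteins))]
        flen = min(int(rng.integers(lo, hi + 1)), len(src))
        start = int(rng.integers(0, len(src) - flen + 1))
        nt = back_translate(src.sequence[start : start + flen], rng)
        if rng.random() < 0.5:
            nt = reverse_complement(nt)
        cid = f"contig_{i + 1:05d}"
        contigs.append(SequenceRecord(id=cid, sequence=nt, alphabet=NUCLEOTIDE))
        truth.contig_sources[cid] = src.id
    return contigs, truth


# ---------------------------------------------------------------------------
# enrichment planting


def plant_enrichment(
    universe: list[str],
    n_de: int,
    seed: int = 0,
    n_background_terms: int = 20,
    prevalence: float = 0.10,
    planted_term: str = "GO:7777777",
    fold: float = 5.0,
    term_prefix: str = "GO:",
) -> tuple[dict[str, set[str]], list[str], FixtureTruth]:
    """Annotations over ``universe`` with one term enriched in the DE draw.

    Background terms are assigned independently at ``prevalence``; the
    planted term carries the same background prevalence, but the DE list is
    drawn so its carrier fraction is ``fold`` times the background fraction
    (capped by carrier and list sizes).  Returns (annotations, de_list,
    truth).
    """
    if not 2 <= n_de <= len(universe):
        raise ValueError("n_de must be between 2 and the universe size")
    rng = np.random.default_rng(seed)
    ids = sorted(universe)
    annotations: dict[str, set[str]] = {g: set() for g in ids}
    for t in range(n_background_terms):
        term = f"{term_prefix}{t + 1:07d}"
        for g in ids:
            if rng.random() < prevalence:
                annotations[g].add(term)
    n_carriers = max(2, round(prevalence * len(ids)))
    carriers = [str(g) for g in rng.choice(ids, size=n_carriers, replace=False)]
    for g in carriers:
        annotations[g].add(planted_term)
    # every gene gets at least one term so the background universe is all ids
    for g in ids:
        if not annotations[g]:
            annotations[g].add(f"{term_prefix}{1:07d}")
    k_target = min(round(fold * (n_carriers / len(ids)) * n_de), n_carriers, n_de)
    non_carriers = [g for g in ids if g not in set(carriers)]
    de = [str(g) for g in rng.choice(carriers, size=k_target, replace=False)]
    de += [str(g) for g in rng.choice(non_carriers, size=n_de - k_target,
                                      replace=False)]
    rng.shuffle(de)
    truth = FixtureTruth(seed=seed, planted_terms={planted_term: fold})
    return annotations, de, truth


# ---------------------------------------------------------------------------
# full fixture


def simulate_fixture(
    outdir,
    n_species: int = 6,
    n_uco: int = 40,
    n_contigs: int = 200,
    seed: int = 0,
    rate_per_edge: float = 0.02,
    fragment_range: tuple[int, int] = (60, 150),
    fold: float = 5.0,
) -> FixtureTruth:
    """Write a complete pipeline input set with recoverable ground truth.

    Generates a taxonomy (one species reserved as the query), proteomes
    evolved along it, the ancestral UCO reference set, query contigs
    back-translated from the query species' proteins, per-species GO and
    pathway tables in which orthologs share terms, and a DE list with one
    GO term and one pathway planted at ``fold`` enrichment.  All files are
    plain text (FASTA / taxdump / TSV / JSON) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    tree, species_taxids = simulate_taxonomy(n_species + 1, seed=int(rng.integers(2**31)))
    uco_refs, proteomes, _ = simulate_proteomes(
        tree, species_taxids, n_uco=n_uco, rate_per_edge=rate_per_edge,
        seed=int(rng.integers(2**31)))
    name_of = {tid: tree.nodes[tid].name for tid in species_taxids}

    # choose a query for which the deepest-LCA candidate is also the
    # smallest-path-distance candidate, so the taxonomy route (LCA depth)
    # and the UCO route (sequence divergence ~ path length) agree on the
    # planted closest relative
    from .taxonomy import lca_depth

    def _winners(q):
        others = [c for c in species_taxids if c != q]
        by_lca = min(others, key=lambda c: (-lca_depth(tree, q, c), c))
        dist = {c: (tree.depth(q) + tree.depth(c)
                    - 2 * lca_depth(tree, q, c)) for c in others}
        by_path = min(others, key=lambda c: (dist[c], c))
        margin = sorted(dist.values())[1] - dist[by_path]
        return by_lca, by_path, margin

    best = None
    for q in species_taxids:
        by_lca, by_path, margin = _winners(q)
        if by_lca == by_path:
            cand = (margin, -q, by_lca)
            if best is None or cand > best:
                best = cand
    if best is None:  # no coherent query; fall back to the first species
        q = species_taxids[0]
        best = (0, -q, _winners(q)[0])
    query_taxid, closest_taxid = -best[1], best[2]
    query_name = name_of[query_taxid]

    candidates = {name_of[t]: proteomes[name_of[t]]
                  for t in species_taxids if t != query_taxid}
    query_proteins = proteomes[query_name]
    contigs, ttruth = simulate_transcriptome(
        query_proteins, n_contigs, fragment_range,
        seed=int(rng.integers(2**31)))

    # orthology-consistent annotations: terms are assigned per UCO, every
    # species' copy of a UCO inherits the same term set
    uco_ids = [u.id for u in uco_refs]
    go_by_uco, _, _ = plant_enrichment(
        uco_ids, n_de=max(2, len(uco_ids) // 4),
        seed=int(rng.integers(2**31)), planted_term="GO:7777777", fold=fold)
    path_by_uco, _, _ = plant_enrichment(
        uco_ids, n_de=max(2, len(uco_ids) // 4),
        seed=int(rng.integers(2**31)), planted_term="ko77777", fold=fold,
        term_prefix="ko", n_background_terms=10)

    # DE list over contigs: contigs from planted-GO-carrier proteins oversampled
    planted_go = "GO:7777777"
    carrier_contigs = sorted(
        c for c, src in ttruth.contig_sources.items()
        if planted_go in go_by_uco[src.split("|")[1]])
    other_contigs = sorted(set(ttruth.contig_sources) - set(carrier_contigs))
    n_de = max(4, n_contigs // 5)
    bg_frac = len(carrier_contigs) / n_contigs
    k = min(round(fold * bg_frac * n_de), len(carrier_contigs), n_de)
    de = [str(c) for c in rng.choice(carrier_contigs, size=k, replace=False)]
    de += [str(c) for c in rng.choice(other_contigs, size=max(0, n_de - k),
                                      replace=False)]

    # --- write everything
    write_taxdump(tree, outdir / "taxdump")
    write_fasta(uco_refs, outdir / "uco.fasta")
    write_fasta(contigs, outdir / "contigs.fasta")
    prot_dir = outdir / "proteomes"
    prot_dir.mkdir(exist_ok=True)
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    from .enrichment import write_annotation_table
    for sp, prots in candidates.items():
        write_fasta(prots, prot_dir / f"{sp}.fasta")
        go_map = {p.id: go_by_uco[p.id.split("|")[1]] for p in prots}
        path_map = {p.id: path_by_uco[p.id.split("|")[1]] for p in prots}
        write_annotation_table(go_map, ann_dir / f"{sp}.go.tsv")
        write_annotation_table(path_map, ann_dir / f"{sp}.pathway.tsv")
    with open(outdir / "de_list.txt", "w") as fh:
        fh.write("\n".join(sorted(de)) + "\n")
    with open(outdir / "candidates.txt", "w") as fh:
        fh.write("\n".join(str(t) for t in sorted(species_taxids)
                           if t != query_taxid) + "\n")

    truth = FixtureTruth(
        seed=seed,
        species=sorted(candidates),
        species_taxids={name_of[t]: t for t in species_taxids},
        query_taxid=query_taxid,
        closest_species=name_of[closest_taxid],
        rate_per_edge=rate_per_edge,
        contig_sources=ttruth.contig_sources,
        planted_terms={planted_go: fold, "ko77777": fold},
    )
    truth.to_json(outdir / "truth.json")
    return truth
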