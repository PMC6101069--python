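"""Taxonomy parsing and lowest-common-ancestor (LCA) scoring.

The NCBI-style taxonomy is a rooted tree with named, ranked nodes but no
branch lengths, so relatedness between a query species and each candidate
reference species is scored purely topologically: the depth (edges from the
root, root = 0) of the LCA of the two lineages.  Deeper LCAs mean the pair
shares a longer prefix of their classification and are therefore treated as
more closely related.  Candidate species are additionally required to share
the query's phylum-rank ancestor when the query lineage has one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import (
    ParseError,
    QueryNotInTaxonomyError,
    StructuralError,
    UnknownTaxonError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPECIES = 3
DEFAULT_MAX_SPECIES = 5


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: mapping taxid -> node, with exactly one self-parented root."""

    nodes: dict[int, TaxonNode]
    root: int

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(f"taxon {taxid} not in tree") from None

    def lineage(self, taxid: int) -> "Lineage":
        return lineage(self, taxid)

    def depth(self, taxid: int) -> int:
        return lineage(self, taxid).depth

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """Taxid of the ancestor (or self) with the given rank, or None."""
        for tid in lineage(self, taxid).path:
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def validate(self) -> None:
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {sorted(roots)}")
        if roots[0] != self.root:
            raise StructuralError(f"root mismatch: {roots[0]} != {self.root}")
        for tid, n in self.nodes.items():
            if n.parent not in self.nodes:
                raise StructuralError(f"taxon {tid} has missing parent {n.parent}")
        # cycle check: following parents must reach the root in <= |nodes| steps
        limit = len(self.nodes)
        for tid in self.nodes:
            cur, steps = tid, 0
            while cur != self.root:
                cur = self.nodes[cur].parent
                steps += 1
                if steps > limit:
                    raise StructuralError(f"cycle detected from taxon {tid}")


@dataclass(frozen=True)
class Lineage:
    """Root-to-node path; depth counts edges, so the root has depth 0."""

    path: tuple[int, ...]

    @property
    def depth(self) -> int:
        return len(self.path) - 1


@dataclass
class TaxSelectionResult:
    query: int
    ranked: list[tuple[int, int]]  # (candidate taxid, lca depth score), best first
    min_n: int
    max_n: int
    phylum: int | None
    warning: str | None = None
    names: dict[int, str] = field(default_factory=dict)
    ranks: dict[int, str] = field(default_factory=dict)


def _split_dmp_row(line: str) -> list[str]:
    # taxdump rows are pipe-delimited with optional tab padding and an
    # optional trailing delimiter; accept both "1\t|\t1\t|\t..." and "1|1|...".
    row = line.rstrip("\n").rstrip()
    if row.endswith("|"):
        row = row[:-1]
    return [f.strip("\t ") for f in row.split("|")]


def parse_taxdump(nodes_text: str, names_text: str = "") -> TaxonomyTree:
    """Parse NCBI taxdump-dialect nodes.dmp / names.dmp text into a tree.

    Only the first three fields of nodes.dmp (taxid, parent, rank) and the
    "scientific name" class rows of names.dmp are used.  Taxa without a
    scientific name are named by their stringified id.
    """
    names: dict[int, str] = {}
    for i, line in enumerate(names_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_row(line)
        if len(fields) < 4:
            raise ParseError(f"names row needs >=4 fields, got {len(fields)}", line=i)
        try:
            taxid = int(fields[0])
        except ValueError:
            raise ParseError(f"bad taxid {fields[0]!r} in names", line=i) from None
        if fields[3] == "scientific name":
            names[taxid] = fields[1]

    nodes: dict[int, TaxonNode] = {}
    for i, line in enumerate(nodes_text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_row(line)
        if len(fields) < 3:
            raise ParseError(f"nodes row needs >=3 fields, got {len(fields)}", line=i)
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise ParseError(f"bad taxid/parent in {fields[:2]!r}", line=i) from None
        if taxid in nodes:
            raise ParseError(f"duplicate taxon {taxid}", line=i)
        nodes[taxid] = TaxonNode(taxid, parent, fields[2], names.get(taxid, str(taxid)))

    if not nodes:
        raise StructuralError("empty nodes file")
    roots = [t for t, n in nodes.items() if n.parent == t]
    if len(roots) != 1:
        raise StructuralError(f"expected exactly one root, found {sorted(roots)}")
    tree = TaxonomyTree(nodes=nodes, root=roots[0])
    tree.validate()
    return tree


def lineage(tree: TaxonomyTree, taxid: int) -> Lineage:
    """Root-to-node taxid path for one taxon."""
    if taxid not in tree.nodes:
        raise UnknownTaxonError(f"taxon {taxid} not in tree")
    path = [taxid]
    while path[-1] != tree.root:
        path.append(tree.nodes[path[-1]].parent)
    return Lineage(path=tuple(reversed(path)))


def lca_depth(tree: TaxonomyTree, a: int, b: int) -> int:
    """Depth (edges from root) of the lowest common ancestor of a and b."""
    pa, pb = lineage(tree, a).path, lineage(tree, b).path
    depth = -1
    for x, y in zip(pa, pb):
        if x != y:
            break
        depth += 1
    return depth


def select_by_taxonomy(
    tree: TaxonomyTree,
    query: int,
    candidates: list[int],
    min_n: int = DEFAULT_MIN_SPECIES,
    max_n: int = DEFAULT_MAX_SPECIES,
) -> TaxSelectionResult:
    """Rank candidate reference species by LCA depth relative to the query.

    Candidates not sharing the query's phylum-rank ancestor are dropped
    (skipped with a warning if the query lineage carries no phylum node, as
    happens for some protists).  The top ``max_n`` by LCA depth are returned,
    ties broken by ascending taxid; falling short of ``min_n`` sets a warning
    rather than failing.
    """
    if query not in tree.nodes:
        raise QueryNotInTaxonomyError(
            f"query taxon {query} absent from taxonomy; use UCO-based selection"
        )
    if not candidates:
        raise ValueError("candidate list is empty")
    if min_n > max_n:
        raise ValueError(f"min_n {min_n} > max_n {max_n}")
    for c in candidates:
        if c not in tree.nodes:
            raise UnknownTaxonError(f"candidate taxon {c} not in tree")

    warning = None
    phylum = tree.rank_ancestor(query, "phylum")
    pool = sorted(set(candidates))
    if phylum is None:
        warning = "query lineage has no phylum-rank node; phylum constraint skipped"
        logger.warning(warning)
    else:
        pool = [c for c in pool if tree.rank_ancestor(c, "phylum") == phylum]

    scored = sorted(((c, lca_depth(tree, query, c)) for c in pool),
                    key=lambda cs: (-cs[1], cs[0]))
    ranked = scored[:max_n]
    if len(ranked) < min_n:
        warning = (
            f"only {len(ranked)} candidate(s) satisfy the constraints "
            f"(minimum requested: {min_n})"
        )
        logger.warning(warning)
    return TaxSelectionResult(
        query=query,
        ranked=ranked,
        min_n=min_n,
        max_n=max_n,
        phylum=phylum,
        warning=warning,
        names={c: tree.nodes[c].name for c, _ in ranked},
        ranks={c: tree.nodes[c].rank for c, _ in ranked},
    )
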