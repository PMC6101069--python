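# Methods

## Taxonomy scoring

The taxonomy is the NCBI taxdump dialect (`nodes.dmp` / `names.dmp`,
pipe-delimited with optional tab padding); only taxid, parent and rank are
used, plus the "scientific name" class of the names file. Depth counts
edges from the root (root = 0) — the format itself never defines an
origin, so this is fixed here explicitly. A candidate's score is the depth
of its lowest common ancestor with the query. This is a purely topological
relatedness measure: the tree has no branch lengths, so two candidates at
equal LCA depth are indistinguishable to this route (the UCO route exists
for exactly that case). Ties break by ascending taxid for reproducibility.
Candidates outside the query's phylum-rank ancestor are excluded; when the
query lineage carries no phylum node (some protist lineages), the
constraint is skipped with a warning rather than failing. Selection keeps
the top five by default and warns — does not error — when fewer than three
qualify.

A caveat worth knowing: the deepest-LCA candidate is not always the
candidate at the smallest path distance (LCA depth ignores how far below
the LCA each species sits). Sequence-based ranking tracks path distance,
so the two routes can legitimately disagree on trees with very unbalanced
leaf depths.

## Alignment and significance

The aligner is exact local Smith–Waterman under affine gaps via
Biopython's `PairwiseAligner` (BLOSUM62; gap of length L costs 11 + L, the
classic protein-search default). Residues outside the BLOSUM62 alphabet
map to X. Percent identity is identities over aligned columns, internal
gap columns included. Significance uses the ungapped Karlin–Altschul form
E = K·m·n·e^(−λS) with K = 0.041, λ = 0.267 — an approximation to a
heuristic gapped search's statistics, adequate because downstream logic
only consumes the "E < 10⁻¹⁰" threshold. Word size and other heuristic
search parameters have no counterpart here: every comparison is exhaustive.
Six-frame translation uses the standard genetic code and keeps stop codons
as `*` (local alignment lets stops score negatively instead of splitting
frames). A 12-column tabular (outfmt-6) parser lets an external search
engine's output substitute for the built-in aligner.

## UCO profiling and voting

Per species, each UCO maps to its best-scoring proteome protein when the
E-value against the whole proteome passes the threshold; the best hit's
sequence is stored as the species' representative for that UCO. Query
contigs are assigned at most one UCO (best bit score over six frames × all
UCOs). Each assigned contig votes for the species whose representative
scores highest; a t-way score tie contributes 1/t to each tied species, so
votes always sum to the number of voting contigs. Votes are counts, not
summed bit scores, for robustness to length variation; the output reports
both raw votes and distinct UCO ids per species since the two can differ
when several contigs hit one UCO. Top-3 selection is the default.

## Mantel correlation

Distances are 1 − pident/100 from pairwise alignment of representative
UCO proteins — not from a multiple alignment; at the scale this package
targets, pairwise identity is a faithful, dependency-free stand-in.
Matrices are restricted to shared species (minimum three), and r is the
Pearson correlation of the strict upper triangles: standardizing the
m = n(n−1)/2 entries with divisor m − 1 is the only normalization that
makes r(x, x) = 1 exactly, which the intended "closer to 1 means
consistent" reading requires. The permutation test permutes rows and
columns of one matrix simultaneously; p is one-tailed (greater) and counts
the observed statistic, so p ≥ 1/(permutations + 1). In batch mode
(`all_pairs_correlation`) pairs with under three shared species or a
constant triangle get r = NaN instead of raising. When all matrices share
one species panel, all C(m, 2) correlations reduce to a single matrix
product of standardized triangle vectors; the full 357-UCO panel
(63,546 pairs) evaluates in well under a second this way.

## Annotation transfer and enrichment

Per contig and selected species, the best translated hit passing the
threshold defines one putative ortholog (at most one gene per species per
contig); merged GO/pathway sets are unions across species, with no
orthology arbitration between conflicting gene ids — union semantics make
annotation monotone in the reference set, which is the property users rely
on when adding species. The enrichment background is the set of contigs
with at least one annotation of the tested kind (standard practice; using
all contigs would deflate p for every term). The test is upper-tail
hypergeometric only (over-representation); raw p < 0.05 is the primary
significance flag, with Benjamini–Hochberg adjusted values and a second
flag reported because dozens to thousands of terms are tested. GO terms
are used as given — no propagation to ancestor terms.

## Synthetic data

The generator emulates the pipeline's inputs, not sequencing reality:

- Proteins are uniform random over the 20 amino acids; substitution is
  uniform replacement among the other 19, with per-edge probability
  applied along the taxonomy, so expected pairwise identity decays with
  topological distance. There is no rate matrix, no site heterogeneity and
  no indels — sufficient to order identities by tree distance, which is
  all the pipeline exploits.
- Contigs are codon back-translations (uniform synonymous choice, standard
  code) of random protein fragments on a random strand; there are no
  sequencing errors, chimeras or untranslated regions.
- Enrichment planting assigns background terms at 10 % prevalence and
  draws the DE list so the planted term's carrier fraction is a chosen
  multiple (default 5×) of background, capped by carrier count.
- The full fixture picks as query a species whose deepest-LCA candidate is
  also its smallest-path-distance candidate, so both selection routes
  share one planted answer.

Passing tests on these fixtures demonstrates the machinery (scoring,
voting, counting, statistics) is correct; it does not demonstrate
robustness to real-data artifacts such as fragmented or misassembled
contigs, paralog interference, or biased codon usage.

## Defaults and problem sizes

| Parameter | Default | Why |
|---|---|---|
| E-value threshold | 1e-10 | ortholog-identification stringency used throughout |
| substitution matrix / gaps | BLOSUM62, 11/1 | standard protein-search scoring |
| Karlin–Altschul K, λ | 0.041, 0.267 | ungapped BLOSUM62 constants |
| taxonomy min/max species | 3 / 5 | balance of coverage vs. annotation noise |
| UCO top-k | 3 | compromise between cost and accuracy |
| enrichment α | 0.05 | conventional raw-p cut; BH flag reported too |
| Mantel permutations | 999 | p resolution of 10⁻³ |
| simulated divergences | 2 / 10 / 30 % | well-separated recovery conditions |
| edge substitution rate | 0.02 | weak per-edge drift; ordering still recoverable |

Test and acceptance runs use deliberately small problem sizes (tens of
UCOs of 80–200 residues, tens of contigs, 3–6 species): the algorithms
are exact, so correctness properties are scale-free, and simulations stay
fast enough to repeat across many seeds.

## Known limitations

- The built-in aligner is exhaustive O(mn) per pair — appropriate for UCO
  panels and small proteomes, not for searching millions of sequences; the
  outfmt-6 adapter exists for that regime.
- E-values are ungapped approximations; absolute values near the threshold
  differ from a gapped search engine's, though rankings agree.
- LCA-depth scoring cannot separate candidates below the same ancestor and
  can disagree with sequence distance on unbalanced trees (see above).
- Enrichment treats contigs as independent genes; multiple contigs from
  one transcript inflate counts unless the input is deduplicated upstream.
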