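import numpy as np
import pytest

from mss.align import NUCLEOTIDE, PROTEIN, SequenceRecord, smith_waterman
from mss.enrichment import (
    GO,
    PATHWAY,
    AnnotationMap,
    AnnotationTable,
    annotate_contigs,
    enrich,
    hypergeom_pvalue,
    merge_annotations,
    read_annotation_table,
    write_annotation_table,
)
from mss.simulate import back_translate, plant_enrichment, simulate_star_proteomes

from .oracles import hypergeom_pmf_sum, hypergeom_upper_tail


class TestHypergeomPvalue:
    def test_zero_successes_gives_one(self):
        assert hypergeom_pvalue(0, 5, 5, 10) == 1.0

    def test_all_marked_drawn(self):
        # drawing all 5 marked genes in 5 draws from 10: 1 / C(10,5)
        assert hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-15)

    def test_matches_factorial_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                hypergeom_upper_tail(k, K, n, N), abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeom_pvalue(k, 10, 12, 40) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pmf_sums_to_one(self):
        for (K, n, N) in [(5, 5, 10), (3, 7, 12), (10, 10, 30)]:
            assert hypergeom_pmf_sum(K, n, N) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("args", [(6, 5, 5, 10), (2, 11, 5, 10),
                                      (-1, 5, 5, 10), (2, 5, 11, 10)])
    def test_bounds_violations_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_pvalue(*args)


class TestAnnotationTable:
    def test_duplicate_gene_rows_merge_by_union(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("g1\tGO:0000001,GO:0000002\ng1\tGO:0000003\n")
        table = read_annotation_table("sp", go_path=p)
        assert table.terms("g1", GO) == {"GO:0000001", "GO:0000002",
                                         "GO:0000003"}

    def test_write_read_round_trip(self, tmp_path):
        mapping = {"g1": {"GO:1", "GO:2"}, "g2": {"GO:3"}}
        p = tmp_path / "t.tsv"
        write_annotation_table(mapping, p)
        assert read_annotation_table("sp", go_path=p).go == mapping


def _species_data(n_uco=5, seed=3):
    """Two divergent species with orthology-consistent annotations."""
    uco_refs, proteomes, _ = simulate_star_proteomes(
        {"spA": 0.05, "spB": 0.15}, n_uco=n_uco, seed=seed,
        length_range=(70, 110))
    tables = {}
    for sp, prots in proteomes.items():
        go = {p.id: {f"GO:{p.id.split('|')[1]}", f"GO:shared_{sp}"}
              for p in prots}
        pw = {p.id: {f"ko_{p.id.split('|')[1]}"} for p in prots}
        tables[sp] = AnnotationTable(species_id=sp, go=go, pathways=pw)
    return uco_refs, proteomes, tables


class TestAnnotateContigs:
    def test_back_translated_contig_maps_to_source_gene(self, rng):
        _, proteomes, tables = _species_data()
        src = proteomes["spA"][0]
        contig = SequenceRecord(id="c1",
                                sequence=back_translate(src.sequence, rng),
                                alphabet=NUCLEOTIDE)
        amap = annotate_contigs([contig], proteomes, tables)
        assert ("spA", src.id) in {(sp, g) for sp, g, _ in amap.hits["c1"]}

    def test_random_contig_stays_unannotated(self, rng):
        _, proteomes, tables = _species_data()
        junk = SequenceRecord(id="junk",
                              sequence="".join(rng.choice(list("ACGT"), 150)),
                              alphabet=NUCLEOTIDE)
        amap = annotate_contigs([junk], proteomes, tables)
        assert amap.hits == {}
        assert amap.n_annotated == 0

    def test_matches_brute_force_best_hit_per_species(self):
        from mss.align import six_frame_translate

        _, proteomes, tables = _species_data()
        rng = np.random.default_rng(31)
        contigs = []
        for i, src in enumerate(proteomes["spA"][:4]):
            frag = src.sequence[: 60 + int(rng.integers(20))]
            contigs.append(SequenceRecord(id=f"c{i}",
                                          sequence=back_translate(frag, rng),
                                          alphabet=NUCLEOTIDE))
        amap = annotate_contigs(contigs, proteomes, tables)
        for contig in contigs:
            frames = six_frame_translate(contig)
            got = {sp: g for sp, g, _ in amap.hits.get(contig.id, [])}
            for sp, prots in proteomes.items():
                scored = [(max(smith_waterman(fr, p, score_only=True).raw_score
                               for fr in frames), p.id) for p in prots]
                best_score = max(s for s, _ in scored)
                expected = min(pid for s, pid in scored if s == best_score)
                if sp in got:
                    assert got[sp] == expected

    def test_species_without_table_still_hits(self, rng, caplog):
        _, proteomes, tables = _species_data()
        del tables["spB"]
        src = proteomes["spB"][0]
        contig = SequenceRecord(id="c1",
                                sequence=back_translate(src.sequence, rng),
                                alphabet=NUCLEOTIDE)
        amap = annotate_contigs([contig], proteomes, tables)
        assert any(sp == "spB" for sp, _, _ in amap.hits["c1"])


class TestMergeAnnotations:
    def test_single_species_merged_equals_own_sets(self, rng):
        _, proteomes, tables = _species_data()
        src = proteomes["spA"][0]
        contig = SequenceRecord(id="c1",
                                sequence=back_translate(src.sequence, rng),
                                alphabet=NUCLEOTIDE)
        amap = annotate_contigs([contig], {"spA": proteomes["spA"]},
                                {"spA": tables["spA"]})
        assert amap.merged_terms["c1"] == tables["spA"].terms(src.id, GO)

    def test_union_across_species(self):
        amap = AnnotationMap(hits={"c1": [("A", "g1", 50.0),
                                          ("B", "g2", 40.0)]})
        tables = {
            "A": AnnotationTable("A", go={"g1": {"GO:1"}}),
            "B": AnnotationTable("B", go={"g2": {"GO:1", "GO:2"}}),
        }
        merged = merge_annotations(amap, tables)
        assert merged.merged_terms["c1"] == {"GO:1", "GO:2"}

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_species_never_shrinks_annotation(self, seed):
        uco_refs, proteomes, tables = _species_data(seed=seed)
        rng = np.random.default_rng(seed + 100)
        contigs = [SequenceRecord(id=f"c{i}",
                                  sequence=back_translate(
                                      p.sequence[:80], rng),
                                  alphabet=NUCLEOTIDE)
                   for i, p in enumerate(proteomes["spA"])]
        one = annotate_contigs(contigs, {"spA": proteomes["spA"]},
                               {"spA": tables["spA"]})
        both = annotate_contigs(contigs, proteomes, tables)
        assert both.n_annotated >= one.n_annotated
        for cid, terms in one.merged_terms.items():
            assert both.merged_terms[cid] >= terms


class TestEnrich:
    def test_de_equal_to_background_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        annotations, _, _ = plant_enrichment(universe, n_de=5, seed=1)
        amap = AnnotationMap(merged_terms=annotations)
        rows = enrich(universe, amap, kind=GO)
        assert all(r.p_raw == pytest.approx(1.0) for r in rows)
        assert all(r.k == r.K for r in rows)

    def test_planted_fivefold_term_attains_min_p(self):
        universe = [f"g{i}" for i in range(300)]
        annotations, de, truth = plant_enrichment(universe, n_de=40, seed=7,
                                                  fold=5.0)
        amap = AnnotationMap(merged_terms=annotations)
        rows = enrich(de, amap, kind=GO)
        (planted,) = truth.planted_terms
        assert rows[0].term_id == planted
        assert rows[0].significant and rows[0].significant_bh

    def test_counts_match_set_algebra_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            universe = [f"g{i}" for i in range(40)]
            annotations = {
                g: {f"GO:{rng.integers(6)}" for _ in range(rng.integers(1, 4))}
                for g in universe}
            de = [str(g) for g in
                  rng.choice(universe, size=12, replace=False)]
            amap = AnnotationMap(merged_terms=annotations)
            rows = enrich(de, amap, kind=GO)
            for r in rows:
                assert r.N == len(universe)
                assert r.n == len(set(de))
                assert r.K == sum(1 for g in universe
                                  if r.term_id in annotations[g])
                assert r.k == sum(1 for g in set(de)
                                  if r.term_id in annotations[g])

    def test_rows_sorted_by_raw_p(self):
        universe = [f"g{i}" for i in range(100)]
        annotations, de, _ = plant_enrichment(universe, n_de=20, seed=2)
        rows = enrich(de, AnnotationMap(merged_terms=annotations), kind=GO)
        ps = [r.p_raw for r in rows]
        assert ps == sorted(ps)

    def test_pathway_kind_uses_pathway_sets(self):
        amap = AnnotationMap(
            merged_terms={"c1": {"GO:1"}},
            merged_pathways={"c1": {"ko1"}, "c2": {"ko1", "ko2"}})
        rows = enrich(["c1"], amap, kind=PATHWAY)
        assert {r.term_id for r in rows} == {"ko1"}

    def test_empty_de_list_rejected(self):
        with pytest.raises(ValueError):
            enrich([], AnnotationMap(merged_terms={"c": {"GO:1"}}), kind=GO)

    def test_de_outside_background_ignored_with_warning(self, caplog):
        amap = AnnotationMap(merged_terms={"c1": {"GO:1"}, "c2": {"GO:1"}})
        rows = enrich(["c1", "ghost"], amap, kind=GO)
        assert rows[0].n == 1
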