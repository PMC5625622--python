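import numpy as np
import pytest

from rdfacets import (FacetSelection, QueryContractError, QueryEngine,
                      QuerySpec, RetentionPolicy, SeparatorCollisionError,
                      Store, TableSource, build_index, convert_table,
                      generate_random_table, parse_structure_config,
                      validate_subject_contract)

from oracle_utils import (expected_facet_counts, expected_subjects,
                          random_selections, random_text_token)

SNP_NS = "https://example.org/snps/"

#: Retention wide enough that the cap never binds on toy tables, so the
#: subject-set oracle is exact.
WIDE = RetentionPolicy(search_limit=1000, score_ratio=0.25)


def subjects_of(result):
    return {h.subject for h in result.hits}


def make_engine(table, structure, with_index=True):
    graph, _ = convert_table(table, structure)
    index = build_index(graph, structure) if with_index else None
    return QueryEngine(Store.local(graph), structure, index=index)


class TestKeyQueryConstruction:
    def test_any_and_all_selections_compose_conjunctively(self, snp_engine):
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["TERT", "MLL4"]), "any"),
            FacetSelection("chromosome", frozenset(["chr5"]), "all")])
        got = subjects_of(snp_engine.execute_key_query(spec))
        assert got == {SNP_NS + "1", SNP_NS + "2"}

    def test_all_mode_with_two_values_on_single_valued_facet_is_empty(
            self, snp_engine):
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["TERT", "MLL4"]), "all")])
        assert subjects_of(snp_engine.execute_key_query(spec)) == set()

    def test_free_text_only_emits_templated_query_with_search_limit(
            self, snp_engine):
        q = snp_engine.build_key_query(QuerySpec(free_text="TERT"))
        assert "text#query" in q and "LIMIT 300" in q

    def test_single_selection_equals_brute_force_row_filter(
            self, snp_engine, snp_table, snp_structure):
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["TERT"]), "any")])
        got = subjects_of(snp_engine.execute_key_query(spec))
        assert got == expected_subjects(snp_table, snp_structure,
                                        spec.selections)
        assert got == {SNP_NS + "1", SNP_NS + "2", SNP_NS + "5"}

    def test_dependent_facet_values_select_by_prefixed_form(self, snp_engine):
        spec = QuerySpec(selections=[
            FacetSelection("coordinate", frozenset(["chr5:1253"]), "any")])
        assert subjects_of(snp_engine.execute_key_query(spec)) == {SNP_NS + "1"}

    def test_empty_spec_is_rejected(self, snp_engine):
        with pytest.raises(QueryContractError):
            snp_engine.execute_key_query(QuerySpec())


class TestRawSparql:
    def test_query_must_project_the_subject_variable(self):
        with pytest.raises(QueryContractError, match="subject"):
            validate_subject_contract("SELECT ?s WHERE { ?s ?p ?o }")

    def test_malformed_query_raises_a_syntax_error(self):
        with pytest.raises(Exception):
            validate_subject_contract("SELECT WHERE {{{")

    def test_raw_subquery_combines_with_selections(self, snp_engine):
        raw = (f"SELECT ?subject WHERE {{ ?subject <{SNP_NS}gene> ?g . "
               f'FILTER(?g = "TERT") }}')
        spec = QuerySpec(raw_sparql=raw, selections=[
            FacetSelection("chromosome", frozenset(["chrX"]), "any")])
        assert subjects_of(snp_engine.execute_key_query(spec)) == {SNP_NS + "5"}

    def test_prefixed_raw_query_is_hoisted_into_the_key_query(self, snp_engine):
        raw = ("PREFIX s: <" + SNP_NS + ">\n"
               'SELECT ?subject WHERE { ?subject s:gene "MLL4" }')
        spec = QuerySpec(raw_sparql=raw)
        assert subjects_of(snp_engine.execute_key_query(spec)) == {SNP_NS + "3"}
        # facet counting embeds the same query as a subquery
        counts = snp_engine.facet_counts(spec)
        assert any(c.value == "MLL4" and c.query_count == 1 for c in counts)


class TestBrowseMode:
    def test_database_class_with_no_conditions_returns_all_rows(
            self, snp_engine, snp_table):
        spec = QuerySpec(database="snps")
        got = subjects_of(snp_engine.execute_key_query(spec))
        assert got == {SNP_NS + str(i)
                       for i in range(1, len(snp_table.rows) + 1)}


class TestFreeText:
    def test_free_text_results_match_direct_index_search(self, snp_engine):
        spec = QuerySpec(free_text="TERT", policy=WIDE)
        got = subjects_of(snp_engine.execute_key_query(spec))
        hits, _ = snp_engine.index.search("TERT", WIDE)
        assert got == {h.subject for h in hits}

    def test_free_text_hits_are_score_ordered(self, snp_engine):
        result = snp_engine.execute_key_query(
            QuerySpec(free_text="TERT chr5", policy=WIDE))
        scores = [h.score for h in result.hits]
        assert scores == sorted(scores, reverse=True)
        assert all(s > 0 for s in scores)

    def test_text_and_selection_intersect(self, snp_engine, snp_table,
                                          snp_structure):
        spec = QuerySpec(free_text="TERT", policy=WIDE, selections=[
            FacetSelection("chromosome", frozenset(["chr5"]), "any")])
        got = subjects_of(snp_engine.execute_key_query(spec))
        assert got == expected_subjects(snp_table, snp_structure,
                                        spec.selections, text_token="tert")


class TestFacetCounts:
    def test_unconstrained_counts_equal_column_histograms(
            self, snp_engine, snp_table, snp_structure):
        spec = QuerySpec(database="snps")
        counts = {(c.facet, c.value): c.query_count
                  for c in snp_engine.facet_counts(spec)}
        subjects = expected_subjects(snp_table, snp_structure)
        assert counts == expected_facet_counts(snp_table, snp_structure,
                                               subjects)

    def test_baseline_equals_query_count_for_unconstrained_query(
            self, snp_engine):
        for c in snp_engine.facet_counts(QuerySpec(database="snps")):
            assert c.baseline_count == c.query_count

    def test_hidden_facets_are_excluded_unless_requested(self, snp_engine):
        spec = QuerySpec(database="snps")
        assert not any(c.facet.endswith("/bin")
                       for c in snp_engine.facet_counts(spec))
        with_hidden = snp_engine.facet_counts(spec, include_hidden=True)
        assert any(c.facet.endswith("/bin") for c in with_hidden)

    def test_absent_values_appear_only_on_request_with_zero_count(
            self, snp_engine):
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["TERT"]), "any")])
        present = snp_engine.facet_counts(spec)
        assert not any(c.query_count == 0 for c in present)
        full = snp_engine.facet_counts(spec, include_absent=True)
        absent = [c for c in full if c.query_count == 0]
        assert any(c.value == "MLL4" for c in absent)
        for c in absent:
            assert c.baseline_count > 0

    def test_empty_result_yields_empty_facet_list(self, snp_engine):
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["NOSUCHGENE"]), "any")])
        assert snp_engine.facet_counts(spec) == []

    def test_selecting_a_value_preserves_its_own_count(self, snp_engine):
        base = snp_engine.facet_counts(QuerySpec(database="snps"))
        for c in base:
            if not c.facet.endswith("/gene"):
                continue
            spec = QuerySpec(selections=[
                FacetSelection("gene", frozenset([c.value]), "any")])
            after = {(x.facet, x.value): x.query_count
                     for x in snp_engine.facet_counts(spec)}
            assert after[(c.facet, c.value)] == c.query_count

    def test_separator_collision_is_detected(self, snp_structure):
        table = TableSource(
            "snps", ["SNP_Name"], [{"SNP_Name": "bad⟂|⟂value"}])
        engine = make_engine(table, snp_structure, with_index=False)
        with pytest.raises(SeparatorCollisionError):
            engine.facet_counts(QuerySpec(database="snps"))


class TestEngineOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_queryspecs_match_brute_force(self, seed):
        table, structure = generate_random_table(seed, max_rows=60)
        engine = make_engine(table, structure)
        rng = np.random.default_rng(1000 + seed)
        for _ in range(3):
            selections = random_selections(rng, table, structure)
            token = (random_text_token(rng, table, structure)
                     if rng.random() < 0.4 else None)
            if not selections and token is None:
                selections = random_selections(rng, table, structure, 3) or []
            spec = QuerySpec(free_text=token, selections=selections,
                             policy=WIDE,
                             database=table.database_name)
            result = engine.execute_key_query(spec)
            want = expected_subjects(table, structure, selections,
                                     text_token=token)
            assert subjects_of(result) == want
            counts = {(c.facet, c.value): c.query_count
                      for c in engine.facet_counts(spec)}
            assert counts == expected_facet_counts(table, structure, want)

    @pytest.mark.parametrize("seed", [3, 7])
    def test_adding_a_selection_never_enlarges_the_result(self, seed):
        table, structure = generate_random_table(seed, max_rows=60)
        engine = make_engine(table, structure, with_index=False)
        rng = np.random.default_rng(seed)
        base_sel = random_selections(rng, table, structure, 1)
        extra = None
        while extra is None:
            extra = random_selections(rng, table, structure, 1) or None
        spec_a = QuerySpec(selections=base_sel, database=table.database_name)
        spec_b = QuerySpec(selections=base_sel + extra,
                           database=table.database_name)
        assert subjects_of(engine.execute_key_query(spec_b)) <= \
               subjects_of(engine.execute_key_query(spec_a))

    def test_all_mode_with_one_value_equals_any_mode(self, snp_engine):
        for mode_pair in [("any", "all")]:
            got = [subjects_of(snp_engine.execute_key_query(QuerySpec(
                selections=[FacetSelection("gene", frozenset(["TERT"]), m)])))
                for m in mode_pair]
            assert got[0] == got[1]


class TestFetchRecords:
    def test_hidden_predicates_are_dropped(self, snp_engine):
        result = snp_engine.execute_key_query(QuerySpec(selections=[
            FacetSelection("SNP_Name", frozenset(["rs100"]), "any")]))
        rec = snp_engine.fetch_records(result.hits)[0]
        names = [d for d, _, _ in rec.entries]
        assert "Bin" not in names and len(rec.entries) == 5

    def test_entries_follow_display_order_and_names(self, snp_engine):
        result = snp_engine.execute_key_query(QuerySpec(selections=[
            FacetSelection("SNP_Name", frozenset(["rs100"]), "any")]))
        rec = snp_engine.fetch_records(result.hits)[0]
        assert [d for d, _, _ in rec.entries] == [
            "Name of the SNP", "Gene", "Chromosome", "Coordinate", "P value"]

    def test_entity_types_are_attached(self, snp_engine):
        result = snp_engine.execute_key_query(QuerySpec(selections=[
            FacetSelection("SNP_Name", frozenset(["rs100"]), "any")]))
        rec = snp_engine.fetch_records(result.hits)[0]
        by_name = {d: t for d, _, t in rec.entries}
        assert by_name["Name of the SNP"] == "snp"
        assert by_name["Gene"] == "gene"
        assert by_name["Chromosome"] is None

    def test_out_of_order_display_orders_are_sorted(self):
        config = ("databases:\n  - name: t\n    namespace: https://t/\n"
                  "    columns:\n"
                  "      - column: A\n        display_order: 2\n"
                  "      - column: B\n        display_order: 0\n"
                  "      - column: C\n        display_order: 1\n")
        structure = parse_structure_config(config)
        table = TableSource("t", ["A", "B", "C"],
                            [{"A": "a", "B": "b", "C": "c"}])
        engine = make_engine(table, structure, with_index=False)
        result = engine.execute_key_query(QuerySpec(database="t"))
        rec = engine.fetch_records(result.hits)[0]
        assert [v for _, v, _ in rec.entries] == ["b", "c", "a"]

    def test_absent_subject_is_omitted(self, snp_engine):
        from rdfacets import SubjectHit
        ghost = SubjectHit(SNP_NS + "999", 0.0, "snps")
        assert snp_engine.fetch_records([ghost]) == []


class TestRemoteEndpoint:
    def test_remote_endpoint_matches_local_execution(
            self, snp_engine, snp_structure, sparql_endpoint):
        url = sparql_endpoint(snp_engine.store.graph)
        remote = QueryEngine(Store.remote(url), snp_structure)
        spec = QuerySpec(selections=[
            FacetSelection("gene", frozenset(["TERT"]), "any")])
        assert subjects_of(remote.execute_key_query(spec)) == \
               subjects_of(snp_engine.execute_key_query(spec))
        assert remote.facet_counts(spec) == snp_engine.facet_counts(spec)

    def test_unreachable_endpoint_reports_its_identity(self, snp_structure):
        from rdfacets import TransportError
        remote = QueryEngine(
            Store.remote("http://127.0.0.1:9/sparql"), snp_structure)
        with pytest.raises(TransportError, match="127.0.0.1"):
            remote.execute_key_query(QuerySpec(database="snps"))
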