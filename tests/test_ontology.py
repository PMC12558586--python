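"""GO DAG parsing, annotation propagation, information content, Relevance
similarity (against an exhaustive-ancestor oracle), and redundancy
reduction."""

import math

import numpy as np
import pytest

from conftest import make_ontology
from regswitch.ontology import (
    information_content, parse_obo, propagate_annotations, reduce_redundancy,
    relevance_similarity,
)

OBO_CHAIN = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
alt_id: GO:0999999
is_a: GO:0000002 ! mid

[Term]
id: GO:0000004
name: obsolete thing
namespace: biological_process
is_obsolete: true
"""


class TestParseObo:
    def test_chain_parses_to_dag(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_CHAIN)
        onto = parse_obo(p)
        assert onto.graph.number_of_edges() == 2
        assert "GO:0000004" not in onto.graph  # obsolete dropped
        assert onto.ancestors("GO:0000003") == \
            {"GO:0000003", "GO:0000002", "GO:0000001"}

    def test_alt_id_resolves_to_canonical(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_CHAIN)
        onto = parse_obo(p)
        propagate_annotations(onto, [("geneA", "GO:0999999")])
        assert onto.annotation_count("GO:0000003") == 1
        assert onto.annotation_count("GO:0000001") == 1

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: a\nnamespace: biological_process\n"
            "is_a: GO:0000002 ! b\n\n"
            "[Term]\nid: GO:0000002\nname: b\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! a\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(p)


class TestPropagation:
    def test_leaf_annotation_reaches_root(self):
        onto = make_ontology({"leaf": ["root"]}, {"g1": ["leaf"]})
        assert onto.annotation_count("leaf") == 1
        assert onto.annotation_count("root") == 1

    def test_two_genes_counted(self):
        onto = make_ontology({"leaf": ["root"]},
                             {"g1": ["leaf"], "g2": ["leaf"]})
        assert onto.annotation_count("leaf") == 2
        assert onto.annotation_count("root") == 2

    def test_gene_annotated_to_child_and_parent_counts_once(self):
        onto = make_ontology({"child": ["parent"], "parent": ["root"]},
                             {"g1": ["child", "parent"]})
        assert onto.annotation_count("parent") == 1

    def test_unknown_term_skipped_with_warning(self, caplog):
        onto = make_ontology({"leaf": ["root"]})
        propagate_annotations(onto, [("g1", "leaf"), ("g2", "GO:404")])
        # g2's only annotation was skipped, so it never enters the corpus
        assert onto.total_annotated == 1
        assert onto.annotation_count("leaf") == 1
        assert "skipped 1 annotation" in caplog.text


class TestInformationContent:
    def test_root_ic_zero(self):
        onto = make_ontology({"leaf": ["root"]}, {"g1": ["leaf"]})
        assert information_content(onto, "root") == 0.0

    def test_leaf_one_of_ten(self):
        anns = {f"g{i}": ["other"] for i in range(9)}
        anns["g9"] = ["leaf"]
        onto = make_ontology({"leaf": ["root"], "other": ["root"]}, anns)
        assert information_content(onto, "leaf") == pytest.approx(math.log(10))

    def test_unannotated_term_is_error(self):
        onto = make_ontology({"leaf": ["root"], "bare": ["root"]},
                             {"g1": ["leaf"]})
        with pytest.raises(ValueError, match="IC undefined"):
            information_content(onto, "bare")


def brute_force_similarity(onto, a, b):
    """Exhaustive search over all common ancestors (independent oracle)."""
    common = [t for t in onto.ancestors(a) & onto.ancestors(b)
              if onto.annotation_count(t) > 0]
    if not common:
        return 0.0
    best = max(onto.ic(t) for t in common)
    p_best = min(onto.p(t) for t in common if onto.ic(t) == best)
    denom = onto.ic(a) + onto.ic(b)
    if denom == 0:
        return 0.0
    return (2 * best / denom) * (1 - p_best)


def random_dag_ontology(rng, n_terms=15, n_genes=12):
    """A random annotated DAG: each non-root term gets 1-2 random parents
    among earlier terms."""
    terms = [f"T{i:02d}" for i in range(n_terms)]
    parents = {}
    for i, t in enumerate(terms[1:], 1):
        k = int(rng.integers(1, min(3, i + 1)))
        idx = rng.choice(i, size=k, replace=False)
        parents[t] = [terms[j] for j in idx]
    anns = {
        f"g{i}": [terms[int(j)] for j in
                  rng.choice(n_terms, size=int(rng.integers(1, 4)),
                             replace=False)]
        for i in range(n_genes)
    }
    return make_ontology(parents, anns)


class TestRelevanceSimilarity:
    def test_self_similarity_is_one_minus_p(self):
        anns = {f"g{i}": ["t"] for i in range(2)}
        anns.update({f"h{i}": ["u"] for i in range(18)})
        onto = make_ontology({"t": ["root"], "u": ["root"]}, anns)
        # p(t) = 2/20 = 0.1
        assert relevance_similarity(onto, "t", "t").score == \
            pytest.approx(0.9)

    def test_root_similarity_is_zero(self):
        onto = make_ontology({"t": ["root"]}, {"g": ["t"]})
        assert relevance_similarity(onto, "root", "t").score == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(5)
        onto = random_dag_ontology(rng)
        annotated = [t for t in onto.graph if onto.annotation_count(t) > 0]
        for _ in range(30):
            a, b = rng.choice(annotated, size=2)
            s1 = relevance_similarity(onto, a, b).score
            s2 = relevance_similarity(onto, b, a).score
            assert s1 == s2
            assert 0.0 <= s1 <= 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_ancestor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        onto = random_dag_ontology(rng, n_terms=int(rng.integers(8, 21)))
        annotated = [t for t in onto.graph if onto.annotation_count(t) > 0]
        for _ in range(25):
            a, b = (str(x) for x in rng.choice(annotated, size=2))
            got = relevance_similarity(onto, a, b).score
            want = brute_force_similarity(onto, a, b)
            assert got == pytest.approx(want, abs=1e-12)

    def test_ic_monotone_toward_root(self):
        rng = np.random.default_rng(2)
        onto = random_dag_ontology(rng)
        for child, parent in onto.graph.edges:
            if onto.annotation_count(child) and onto.annotation_count(parent):
                assert onto.ic(child) >= onto.ic(parent) - 1e-12


class TestReduceRedundancy:
    def _chain_onto(self):
        # parent/child with high similarity: child's genes are most of
        # parent's, so MICA(parent) has high IC relative to both
        anns = {"g1": ["child"], "g2": ["child"], "g3": ["parent"],
                **{f"h{i}": ["far"] for i in range(17)}}
        return make_ontology({"child": ["parent"], "parent": ["root"],
                              "far": ["root"]}, anns)

    def test_duplicate_term_collapses(self):
        onto = self._chain_onto()
        survivors, mapping = reduce_redundancy(onto, ["child", "child"], 0.5)
        assert survivors == ["child"]

    def test_disjoint_branches_both_survive(self):
        onto = self._chain_onto()
        survivors, _ = reduce_redundancy(onto, ["child", "far"], 0.5)
        assert survivors == ["child", "far"]

    def test_similar_parent_child_keeps_higher_ic_child(self):
        onto = self._chain_onto()
        sim = relevance_similarity(onto, "child", "parent").score
        assert sim >= 0.5  # precondition of the scenario
        survivors, mapping = reduce_redundancy(onto, ["child", "parent"], 0.5)
        assert survivors == ["child"]
        assert mapping["parent"] == "child"

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(7)
        onto = random_dag_ontology(rng)
        annotated = [t for t in onto.graph if onto.annotation_count(t) > 0]
        s1, m1 = reduce_redundancy(onto, annotated, 0.4)
        shuffled = list(annotated)
        rng.shuffle(shuffled)
        s2, m2 = reduce_redundancy(onto, shuffled, 0.4)
        assert s1 == s2 and m1 == m2

    def test_survivors_all_below_cutoff(self):
        rng = np.random.default_rng(8)
        onto = random_dag_ontology(rng)
        annotated = [t for t in onto.graph if onto.annotation_count(t) > 0]
        survivors, mapping = reduce_redundancy(onto, annotated, 0.4)
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                assert relevance_similarity(onto, a, b).score < 0.4
        # every removed term maps to a survivor
        assert set(mapping.values()) <= set(survivors)
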