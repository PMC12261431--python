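import json

import numpy as np
import pytest

from branchfit.trees import (
    Cohort,
    ISA,
    RELAXED,
    MutationTree,
    TreeError,
    augment_tree,
    cohort_from_dict,
    cohort_to_dict,
    compute_genotypes,
    prune_unobserved,
    to_newick,
    union_tree,
    validate_rule,
)


def make(edges, counts=None, **meta):
    return MutationTree.from_edges(edges, counts, **meta)


class TestGenotypes:
    def test_union_along_path(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])])
        assert t.genotype_of("b") == frozenset({1, 2})
        assert t.genotype_of("a") == frozenset({1})

    def test_root_only_empty_genotype(self):
        t = make([(None, "r", [])])
        assert t.genotype_of("r") == frozenset()

    def test_repeated_mutation_on_lineage_raises_under_isa(self):
        with pytest.raises(TreeError, match="ISA"):
            make([(None, "r", []), ("r", "a", [1]), ("a", "b", [1])])

    def test_idempotent_and_order_independent(self):
        edges = [(None, "r", []), ("r", "a", [2]), ("a", "b", [1]), ("r", "c", [3])]
        t1 = make(edges)
        t2 = make([edges[0], edges[3], edges[1], edges[2]])
        again = compute_genotypes(t1)
        for nid in t1.nodes:
            assert t1.genotype_of(nid) == t2.genotype_of(nid)
            assert again.genotype_of(nid) == t1.genotype_of(nid)

    def test_cycle_detection(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])])
        t.parents["a"] = "b"  # corrupt: a <-> b cycle, disconnected from root
        with pytest.raises(TreeError):
            t.topological_order()


class TestValidateRule:
    def test_parallel_mutation_flagged_under_isa_only(self):
        t = make([(None, "r", []), ("r", "a", [3]), ("r", "b", [3])])
        violations = validate_rule(t, ISA)
        assert len(violations) == 1 and violations[0].mutation == 3
        assert validate_rule(t, RELAXED) == []

    def test_clean_chain_has_no_violations(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])])
        assert validate_rule(t, ISA) == []


class TestPrune:
    def test_zero_count_leaf_removed(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])], {"a": 5})
        p = prune_unobserved(t)
        assert "b" not in p.nodes and "a" in p.nodes

    def test_internal_zero_node_retained(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])], {"b": 3})
        p = prune_unobserved(t)
        assert "a" in p.nodes

    def test_all_positive_unchanged_and_idempotent(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])],
                 {"a": 2, "b": 3})
        p = prune_unobserved(t)
        assert set(p.nodes) == set(t.nodes)
        assert set(prune_unobserved(p).nodes) == set(p.nodes)

    def test_cascading_removal(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])])
        p = prune_unobserved(t)
        assert set(p.nodes) == {"r"}


class TestAugment:
    def test_single_mutation_tree_n2(self):
        t = make([(None, "r", []), ("r", "a", [1])], {"a": 4})
        aug = augment_tree(t, ISA, max_mutations=2, n=2)
        genos = {aug.genotype_of(nid) for nid in aug.nodes}
        assert genos == {frozenset(), frozenset({1}), frozenset({2}),
                         frozenset({1, 2})}
        added = [n for n in aug.nodes.values() if n.is_augmented]
        assert all(n.count == 0 for n in added) and len(added) == 2

    def test_max_mutations_one(self):
        t = make([(None, "r", []), ("r", "a", [1])], {"a": 4})
        aug = augment_tree(t, ISA, max_mutations=1, n=2)
        genos = {aug.genotype_of(nid) for nid in aug.nodes}
        assert genos == {frozenset(), frozenset({1}), frozenset({2})}

    def test_root_only_n3_brute_force(self):
        # expected: all genotypes of size <= 2 over 3 mutations, each once
        from itertools import combinations

        t = make([(None, "r", [])])
        aug = augment_tree(t, ISA, max_mutations=2, n=3)
        genos = {aug.genotype_of(nid) for nid in aug.nodes if nid != "r"}
        expected = {frozenset(c) for k in (1, 2)
                    for c in combinations((1, 2, 3), k)}
        assert genos == expected
        assert len(aug.nodes) == 1 + 3 + 3

    def test_augment_then_prune_restores_original(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])],
                 {"a": 2, "b": 3})
        aug = augment_tree(t, ISA, max_mutations=2, n=4)
        assert set(prune_unobserved(aug).nodes) == set(t.nodes)

    def test_used_mutations_not_reintroduced(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("r", "b", [2])],
                 {"a": 1, "b": 1})
        aug = augment_tree(t, ISA, max_mutations=2, n=2)
        # both mutations used elsewhere: nothing admissible
        assert set(aug.nodes) == set(t.nodes)


class TestUnionTree:
    def trees(self):
        t1 = make([(None, "r", []), ("r", "a", [1])], {"a": 1}, patient_id="p1")
        t2 = make([(None, "r", []), ("r", "b", [2])], {"b": 1}, patient_id="p2")
        return t1, t2

    def test_idempotent_on_identical_trees(self):
        t1, _ = self.trees()
        u = union_tree(Cohort(trees=[t1, t1], n=2))
        assert len(u.nodes) == len(t1.nodes)

    def test_disjoint_children_both_present(self):
        t1, t2 = self.trees()
        u = union_tree(Cohort(trees=[t1, t2], n=2))
        genos = {u.genotype_of(nid) for nid in u.nodes}
        assert genos == {frozenset(), frozenset({1}), frozenset({2})}

    def test_node_count_equals_distinct_genotypes_plus_root(self):
        t1 = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])],
                  {"a": 1, "b": 1})
        t2 = make([(None, "r", []), ("r", "a", [1]), ("a", "c", [3])],
                  {"a": 1, "c": 1})
        cohort = Cohort(trees=[t1, t2], n=3)
        distinct = {t.genotype_of(nid) for t in cohort for nid in t.mutant_nodes()}
        u = union_tree(cohort)
        assert len(u.nodes) == len(distinct) + 1

    def test_incompatible_lineages_raise(self):
        t1 = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])],
                  {"a": 1, "b": 1})
        t2 = make([(None, "r", []), ("r", "b", [2]), ("b", "a", [1])],
                  {"a": 1, "b": 1})
        with pytest.raises(TreeError, match="incompatible"):
            union_tree(Cohort(trees=[t1, t2], n=2))


class TestCohortIO:
    def cohort(self):
        t = make([(None, "r", []), ("r", "a", [1]), ("a", "b", [2])],
                 {"a": 60, "b": 40}, patient_id="p1", sampling_time=42.0,
                 c_tumor=1e9)
        return Cohort(trees=[t], n=3, mutations=["TP53", "KRAS", "NRAS"])

    def test_round_trip_identity(self, tmp_path):
        from branchfit.trees import read_cohort, write_cohort

        path = tmp_path / "cohort.json"
        write_cohort(self.cohort(), path)
        back = read_cohort(path)
        assert back.n == 3 and len(back) == 1
        t = back.trees[0]
        assert t.sampling_time == 42.0 and t.c_seq == 100
        assert t.genotype_of("b") == frozenset({1, 2})

    def test_missing_sampling_time_is_none(self):
        d = cohort_to_dict(self.cohort())
        del d["trees"][0]["sampling_time"]
        back = cohort_from_dict(d)
        assert back.trees[0].sampling_time is None

    def test_negative_count_rejected(self):
        d = cohort_to_dict(self.cohort())
        d["trees"][0]["nodes"][1]["count"] = -1
        with pytest.raises(TreeError, match="negative"):
            cohort_from_dict(d)

    def test_count_sum_must_match_c_seq(self):
        d = cohort_to_dict(self.cohort())
        d["trees"][0]["C_seq"] = 999
        with pytest.raises(TreeError, match="C_seq"):
            cohort_from_dict(d)

    def test_newick_export_contains_annotations(self):
        t = self.cohort().trees[0]
        nwk = to_newick(t)
        assert nwk.endswith(";") and "genotype={1,2}" in nwk and "count=40" in nwk
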