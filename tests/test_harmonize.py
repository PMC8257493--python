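from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

import helpers
from scn2a_pheno.harmonize import (
    ConflictError,
    build_phenotype_matrix,
    compare_term_frequencies,
    harmonize_cohort,
    harmonize_individual,
    propagate_negative,
    propagate_positive,
    prune_negative,
    to_long_table,
)
from scn2a_pheno.io import read_annotations, write_annotations
from scn2a_pheno.ontology import term_frequencies
from scn2a_pheno.synthetic_data import CohortConfig, generate_cohort, generate_ontology


class TestPositivePropagation:
    def test_leaf_expands_to_full_ancestor_chain(self, mini_ontology):
        got = propagate_positive(mini_ontology, {"HP:0012469"})
        assert got == {
            "HP:0012469", "HP:0011097", "HP:0001250", "HP:0012638",
            "HP:0000707", "HP:0000118", "HP:0000001",
        }

    def test_empty_base_stays_empty(self, mini_ontology):
        assert propagate_positive(mini_ontology, set()) == frozenset()

    def test_superset_of_base_and_idempotent(self, mini_cohort):
        for a in mini_cohort.values():
            assert a.base_pos <= a.prop_pos


class TestNegativePropagation:
    def test_leaf_negative_stays_leaf(self, mini_ontology):
        assert propagate_negative(mini_ontology, {"HP:0002072"}) == {"HP:0002072"}

    def test_node_with_two_children_no_positives(self, mini_ontology):
        # movement-abnormality subtree: node plus its two leaf children
        got = propagate_negative(mini_ontology, {"HP:0100022"})
        assert got == {"HP:0100022", "HP:0002072", "HP:0001337"}

    def test_positive_descendant_blocks_branch(self, mini_ontology):
        # negative Seizure with Infantile spasms asserted positive below it:
        # Seizure and Epileptic spasm subsume the positive and must vanish;
        # the seizure branches without positives below survive.  (With a fully
        # ancestor-closed positive set the same input is a curation conflict
        # instead, tested below.)
        got = propagate_negative(mini_ontology, {"HP:0001250"}, {"HP:0012469"})
        assert got == {"HP:0002197", "HP:0007359", "HP:0002133"}

    def test_ancestor_conflict_with_closed_positives_is_error(self, mini_ontology):
        # a negative at an ancestor of an asserted positive contradicts it
        prop_pos = propagate_positive(mini_ontology, {"HP:0012469"})
        with pytest.raises(ConflictError):
            propagate_negative(mini_ontology, {"HP:0001250"}, prop_pos)

    def test_direct_conflict_is_error_naming_term(self, mini_ontology):
        prop_pos = propagate_positive(mini_ontology, {"HP:0001250"})
        with pytest.raises(ConflictError, match="HP:0001250"):
            propagate_negative(mini_ontology, {"HP:0001250"}, prop_pos)

    def test_conflict_error_names_individual(self, mini_ontology):
        with pytest.raises(ConflictError, match="P9"):
            harmonize_individual(mini_ontology, "P9", {"HP:0001250"}, {"HP:0001250"})

    def test_max_depth_limits_expansion(self, mini_ontology):
        got = propagate_negative(mini_ontology, {"HP:0012638"}, max_depth=1)
        # depth 1: the term and its direct children only
        assert got == {"HP:0012638"} | set(mini_ontology.children("HP:0012638"))


class TestPruning:
    def test_chain_keeps_only_apex(self, mini_ontology):
        chain = {"HP:0012638", "HP:0001250", "HP:0011097", "HP:0012469"}
        assert prune_negative(mini_ontology, chain) == {"HP:0012638"}

    def test_two_disjoint_regions_keep_two_apexes(self, mini_ontology):
        full = propagate_negative(mini_ontology, {"HP:0100022", "HP:0012443"})
        assert prune_negative(mini_ontology, full) == {"HP:0100022", "HP:0012443"}

    def test_single_leaf_unchanged(self, mini_ontology):
        assert prune_negative(mini_ontology, {"HP:0002072"}) == {"HP:0002072"}

    def test_empty_input_empty_output(self, mini_ontology):
        assert prune_negative(mini_ontology, set()) == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_propagate_prune_repropagate_roundtrip(self, seed):
        """Pruning is lossless: re-propagating the apexes recovers the full set."""
        ont = generate_ontology(45, depth=5, branching=2.0, extra_parent_p=0.2, seed=seed)
        rng = np.random.default_rng(seed)
        terms = [t for t in ont if t != ont.root]
        pos_base = set(rng.choice(terms, size=4, replace=False))
        prop_pos = propagate_positive(ont, pos_base)
        neg_candidates = [t for t in terms
                          if t not in prop_pos and not (ont.descendants(t) & prop_pos)]
        if len(neg_candidates) < 2:
            pytest.skip("no negative-compatible terms under this seed")
        base_neg = set(rng.choice(neg_candidates, size=min(3, len(neg_candidates)),
                                  replace=False))
        full = propagate_negative(ont, base_neg, prop_pos)
        pruned = prune_negative(ont, full)
        assert pruned <= full
        assert propagate_negative(ont, pruned, prop_pos) == full


@pytest.fixture(scope="module")
def cohort():
    ont = generate_ontology(120, seed=3)
    ann, _, _ = generate_cohort(CohortConfig(n_missense=60, n_ptv=15, n_other=2,
                                             recurrent_groups=((5, 3, 0.9),),
                                             seed=3), ont)
    return ont, harmonize_cohort(ont, ann)


class TestCohortInvariants:
    def test_no_term_both_positive_and_negative(self, cohort):
        _, sets = cohort
        for a in sets.values():
            assert not (a.prop_pos & a.prop_neg_full)
            assert not (a.prop_pos & a.prop_neg_pruned)
            assert a.prop_neg_pruned <= a.prop_neg_full

    def test_propagated_at_least_base(self, cohort):
        _, sets = cohort
        assert all(len(a.prop_pos) >= len(a.base_pos) for a in sets.values())

    def test_ancestor_frequency_equals_base_descendant_recount(self, cohort):
        """After propagation an ancestor's count is exactly the number of
        individuals with at least one base descendant of it."""
        ont, sets = cohort
        parents = helpers.parent_map(ont)
        table = term_frequencies({i: a.prop_pos for i, a in sets.items()})
        rng = np.random.default_rng(0)
        for t in rng.choice(table.index.to_numpy(), size=15, replace=False):
            desc = helpers.brute_descendants(parents, t)
            recount = sum(1 for a in sets.values() if a.base_pos & desc)
            assert table.loc[t, "count"] == recount


class TestCompareTermFrequencies:
    def test_identical_counts_not_significant(self):
        base = pd.DataFrame({"count": [5]}, index=["HP:1"])
        prop = pd.DataFrame({"count": [5]}, index=["HP:1"])
        out = compare_term_frequencies(base, prop, n=100)
        assert out.loc["HP:1", "p"] == 1.0
        assert not out.loc["HP:1", "significant"]

    def test_large_shift_matches_enumeration_oracle(self):
        base = pd.DataFrame({"count": [5]}, index=["HP:1"])
        prop = pd.DataFrame({"count": [200]}, index=["HP:1"])
        out = compare_term_frequencies(base, prop, n=413)
        assert out.loc["HP:1", "p"] == pytest.approx(
            helpers.fisher_p_enum(5, 408, 200, 213), rel=1e-9)
        assert out.loc["HP:1", "significant"]

    def test_count_exceeding_cohort_rejected(self):
        base = pd.DataFrame({"count": [500]}, index=["HP:1"])
        with pytest.raises(ValueError):
            compare_term_frequencies(base, base, n=413)


class TestMatrixAndIO:
    def test_matrix_has_positive_and_np_columns(self, mini_cohort):
        X = build_phenotype_matrix(mini_cohort)
        assert X.dtypes.unique().tolist() == [np.dtype(bool)]
        assert any(c.startswith("NP:") for c in X.columns)  # P3's negative seizure
        assert X.loc["P1", "HP:0001250"]
        # P3 asserted "no seizures": pruned negative apex is the seizure term
        assert X.loc["P3", "NP:0001250"]

    def test_min_count_filter(self, mini_cohort):
        all_cols = build_phenotype_matrix(mini_cohort, min_count=1).shape[1]
        shared = build_phenotype_matrix(mini_cohort, min_count=2)
        assert shared.shape[1] < all_cols
        assert (shared.sum(axis=0) >= 2).all()

    def test_annotation_io_roundtrip_with_np_shorthand(self, tmp_path):
        df = pd.DataFrame({
            "individual_id": ["A", "A", "B"],
            "term": ["HP:0001250", "HP:0000717", "HP:0001250"],
            "polarity": ["positive", "negative", "positive"],
        })
        path = tmp_path / "ann.tsv"
        write_annotations(df, path)
        text = path.read_text()
        assert "NP:0000717" in text
        back = read_annotations(path)
        pd.testing.assert_frame_equal(back, df)

    def test_malformed_curie_rejected(self):
        bad = io.StringIO("individual_id\tterm\nA\tseizure\n")
        with pytest.raises(ValueError, match="CURIE"):
            read_annotations(bad)

    def test_long_table_states(self, mini_cohort):
        long = to_long_table(mini_cohort)
        assert set(long["state"]) == {"base", "propagated"}
        base_rows = long[(long.individual_id == "P1") & (long.state == "base")
                         & (long.polarity == "positive")]
        assert set(base_rows["term"]) == set(mini_cohort["P1"].base_pos)
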