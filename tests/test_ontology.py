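from __future__ import annotations

import io

import numpy as np
import pytest

import helpers
from scn2a_pheno.ontology import (
    Ontology,
    OntologyError,
    Term,
    UnknownTermError,
    ancestor_closure,
    descendant_closure,
    mica,
    parse_obo,
    term_frequencies,
)
from scn2a_pheno.synthetic_data import generate_ontology

TWO_TERM = """format-version: 1.2
ontology: t

[Term]
id: HP:0000001
name: A

[Term]
id: HP:0000002
name: B
is_a: HP:0000001 ! A
"""


def _obo(text: str):
    return parse_obo(io.StringIO(text))


class TestParseObo:
    def test_two_term_edge(self):
        ont = _obo(TWO_TERM)
        assert len(ont) == 2
        assert ont.parents("HP:0000002") == {"HP:0000001"}
        assert ont.root == "HP:0000001"

    def test_multiple_parents_retained(self):
        text = TWO_TERM + (
            "\n[Term]\nid: HP:0000003\nname: C\nis_a: HP:0000001 ! A\n"
            "\n[Term]\nid: HP:0000004\nname: D\nis_a: HP:0000002 ! B\nis_a: HP:0000003 ! C\n"
        )
        ont = _obo(text)
        assert ont.parents("HP:0000004") == {"HP:0000002", "HP:0000003"}

    def test_cycle_is_hard_error(self):
        text = (
            "format-version: 1.2\nontology: t\n"
            "\n[Term]\nid: HP:0000001\nname: R\n"
            "\n[Term]\nid: HP:0000002\nname: A\nis_a: HP:0000003 ! B\nis_a: HP:0000001 ! R\n"
            "\n[Term]\nid: HP:0000003\nname: B\nis_a: HP:0000002 ! A\n"
        )
        with pytest.raises(OntologyError, match="cycl"):
            _obo(text)

    def test_dangling_parent_is_hard_error(self):
        text = TWO_TERM + "\n[Term]\nid: HP:0000005\nname: E\nis_a: HP:0009999 ! ghost\n"
        with pytest.raises(OntologyError):
            _obo(text)

    def test_obsolete_retained_but_excluded_from_closures(self):
        text = TWO_TERM + "\n[Term]\nid: HP:0000006\nname: old\nis_obsolete: true\n"
        ont = _obo(text)
        assert len(ont) == 2  # active terms only
        assert "HP:0000006" in ont.terms
        with pytest.raises(UnknownTermError, match="obsolete"):
            ancestor_closure(ont, ["HP:0000006"])

    def test_alt_id_canonicalized(self, mini_ontology):
        assert mini_ontology.canonical("HP:0002279") == "HP:0001250"
        closure = ancestor_closure(mini_ontology, ["HP:0002279"])
        assert "HP:0001250" in closure

    def test_mini_fixture_shape(self, mini_ontology):
        assert len(mini_ontology) == 30
        assert mini_ontology.root == "HP:0000001"
        assert not helpers.has_cycle(helpers.parent_map(mini_ontology))

    def test_restrict_to_subtree(self, mini_ontology):
        sub = mini_ontology.restrict("HP:0012638")
        assert sub.root == "HP:0012638"
        assert "HP:0001250" in sub and "HP:0000708" not in sub


class TestClosures:
    def test_root_closure_is_itself(self, mini_ontology):
        root = mini_ontology.root
        assert ancestor_closure(mini_ontology, [root]) == {root}

    def test_chain_leaf_collects_whole_chain(self, mini_ontology):
        # Infantile spasms -> Epileptic spasm -> Seizure -> physiology -> nervous -> 118 -> root
        got = ancestor_closure(mini_ontology, ["HP:0012469"])
        assert got == {
            "HP:0012469", "HP:0011097", "HP:0001250", "HP:0012638",
            "HP:0000707", "HP:0000118", "HP:0000001",
        }

    def test_diamond_counts_each_node_once(self, mini_ontology):
        # Autism has two parents whose paths rejoin at the nervous-system term
        got = ancestor_closure(mini_ontology, ["HP:0000717"])
        assert got == helpers.brute_ancestors(helpers.parent_map(mini_ontology), "HP:0000717")

    def test_descendant_leaf_and_chain(self, mini_ontology):
        assert descendant_closure(mini_ontology, "HP:0002072") == {"HP:0002072"}
        assert descendant_closure(mini_ontology, "HP:0011097") == {"HP:0011097", "HP:0012469"}

    def test_unknown_term_listed_in_error(self, mini_ontology):
        with pytest.raises(UnknownTermError, match="HP:9999999"):
            ancestor_closure(mini_ontology, ["HP:0001250", "HP:9999999"])

    @pytest.mark.parametrize("seed", range(5))
    def test_closures_match_bruteforce_on_random_dags(self, seed):
        ont = generate_ontology(40, depth=5, branching=2.0, extra_parent_p=0.2, seed=seed)
        parents = helpers.parent_map(ont)
        rng = np.random.default_rng(seed)
        terms = list(ont)
        for t in rng.choice(terms, size=10, replace=False):
            assert ont.ancestors(t) == helpers.brute_ancestors(parents, t)
            assert ont.descendants(t) == helpers.brute_descendants(parents, t)

    def test_closure_monotone_in_query_set(self, mini_ontology):
        small = {"HP:0002072"}
        large = {"HP:0002072", "HP:0012469", "HP:0000717"}
        assert ancestor_closure(mini_ontology, small) <= ancestor_closure(mini_ontology, large)

    def test_idempotent(self, mini_ontology):
        once = ancestor_closure(mini_ontology, ["HP:0012469", "HP:0000717"])
        assert ancestor_closure(mini_ontology, once) == once


class TestFrequencies:
    def test_ubiquitous_term_has_zero_ic(self):
        table = term_frequencies([{"HP:1"}] * 413)
        assert table.loc["HP:1", "f"] == 1.0
        assert table.loc["HP:1", "ic"] == 0.0

    def test_singleton_in_413_cohort_gives_max_ic(self):
        sets = [{"HP:1"}] + [{"HP:2"}] * 412
        table = term_frequencies(sets)
        assert table.loc["HP:1", "count"] == 1
        assert round(table.loc["HP:1", "ic"], 2) == 8.69

    def test_quarter_frequency_is_two_bits(self):
        table = term_frequencies([{"A"}, {"A"}, set(), set(), set(), set(), set(), set()])
        assert table.loc["A", "ic"] == 2.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            term_frequencies([], n=0)

    def test_propagated_parent_at_least_as_frequent_as_child(self, mini_ontology, mini_cohort):
        table = term_frequencies({i: a.prop_pos for i, a in mini_cohort.items()})
        for t in table.index:
            for p in mini_ontology.parents(t):
                assert table.loc[p, "f"] >= table.loc[t, "f"]
                assert table.loc[p, "ic"] <= table.loc[t, "ic"]


class TestMica:
    def test_ancestor_is_its_own_mica(self, mini_ontology, mini_freqs):
        term, ic = mica(mini_ontology, mini_freqs, "HP:0001250", "HP:0012469")
        assert term == "HP:0001250"
        assert ic == pytest.approx(mini_freqs.loc["HP:0001250", "ic"])

    def test_siblings_meet_at_parent(self, mini_ontology, mini_freqs):
        term, _ = mica(mini_ontology, mini_freqs, "HP:0002197", "HP:0007359")
        assert term == "HP:0001250"

    def test_self_mica(self, mini_ontology, mini_freqs):
        term, ic = mica(mini_ontology, mini_freqs, "HP:0002072", "HP:0002072")
        assert term == "HP:0002072"
        assert ic == pytest.approx(mini_freqs.loc["HP:0002072", "ic"])

    def test_symmetric(self, mini_ontology, mini_freqs):
        pairs = [("HP:0012469", "HP:0002521"), ("HP:0000717", "HP:0001263")]
        for a, b in pairs:
            assert mica(mini_ontology, mini_freqs, a, b) == mica(mini_ontology, mini_freqs, b, a)

    def test_missing_frequency_is_hard_error(self, mini_ontology, mini_freqs):
        with pytest.raises(OntologyError, match="missing"):
            mica(mini_ontology, mini_freqs, "HP:0000252", "HP:0001250")  # never observed

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration_on_random_dags(self, seed):
        ont = generate_ontology(35, depth=5, branching=2.0, extra_parent_p=0.25, seed=seed)
        rng = np.random.default_rng(100 + seed)
        terms = list(ont)
        # random complete frequency table: deeper terms rarer
        counts = {t: int(rng.integers(1, 50)) for t in terms}
        # enforce monotone counts so the table resembles a propagated data set
        for t in terms:
            for p in ont.parents(t):
                counts[p] = max(counts[p], counts[t])
        import pandas as pd
        f = pd.DataFrame({
            "count": pd.Series(counts),
            "f": pd.Series({t: c / 50 for t, c in counts.items()}),
        })
        f["ic"] = -np.log2(f["f"])
        f.index.name = "term"
        parents = helpers.parent_map(ont)
        ic = f["ic"].to_dict()
        for _ in range(30):
            t1, t2 = rng.choice(terms, size=2)
            got = mica(ont, f, t1, t2)
            expected = helpers.brute_mica(parents, ic, t1, t2)
            assert got[0] == expected[0]
            assert got[1] == pytest.approx(expected[1])
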