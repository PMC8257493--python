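from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import helpers
from scn2a_pheno.ontology import term_frequencies
from scn2a_pheno.similarity import (
    CohortSimilarity,
    SimilarityEngine,
    group_similarity_test,
    individual_similarity,
    phenogram,
    run_similarity_suite,
)
from scn2a_pheno.synthetic_data import generate_ontology
from scn2a_pheno.variants import VariantRecord


@pytest.fixture(scope="module")
def engine(request):
    mini_ontology = request.getfixturevalue("mini_ontology")
    mini_freqs = request.getfixturevalue("mini_freqs")
    return SimilarityEngine(mini_ontology, mini_freqs)


class TestIndividualSimilarity:
    def test_self_similarity_is_total_ic(self, engine, mini_cohort, mini_freqs):
        a = mini_cohort["P1"].prop_pos
        expected = sum(mini_freqs.loc[t, "ic"] for t in a)
        assert engine.similarity(a, a) == pytest.approx(expected)

    def test_disjoint_branches_share_only_root(self, engine, mini_cohort):
        # P5 carries only brain-morphology terms; P3 only behavior terms.
        # Their sets meet at nervous-system-level terms carried by everyone
        # (f=1, IC 0), so the score is exactly 0.
        a = mini_cohort["P5"].prop_pos
        b = mini_cohort["P3"].prop_pos
        assert engine.similarity(a, b) == 0.0

    def test_symmetry(self, engine, mini_cohort):
        a = mini_cohort["P1"].prop_pos
        b = mini_cohort["P6"].prop_pos
        assert engine.similarity(a, b) == pytest.approx(engine.similarity(b, a))

    def test_empty_set_scores_zero(self, engine, mini_cohort):
        assert engine.similarity(set(), mini_cohort["P1"].prop_pos) == 0.0

    def test_adding_root_never_changes_score(self, engine, mini_cohort, mini_ontology):
        a = mini_cohort["P1"].prop_pos
        b = mini_cohort["P4"].prop_pos
        with_root = set(b) | {mini_ontology.root}
        assert engine.similarity(a, with_root) == pytest.approx(engine.similarity(a, b))

    def test_directional_score_bounded_by_self_similarity(self, engine, mini_cohort):
        for x in ("P1", "P3", "P6"):
            for y in ("P2", "P4", "P5"):
                a, b = mini_cohort[x].prop_pos, mini_cohort[y].prop_pos
                assert engine.similarity(a, b) <= max(
                    engine.similarity(a, a), engine.similarity(b, b)) + 1e-12

    def test_matches_double_loop_oracle_on_mini(self, engine, mini_cohort,
                                                mini_ontology, mini_freqs):
        parents = helpers.parent_map(mini_ontology)
        ic = mini_freqs["ic"].to_dict()
        inds = list(mini_cohort)
        for x in inds:
            for y in inds:
                got = engine.similarity(mini_cohort[x].prop_pos, mini_cohort[y].prop_pos)
                want = helpers.brute_similarity(
                    mini_cohort[x].prop_pos, mini_cohort[y].prop_pos, parents, ic)
                assert got == pytest.approx(want), (x, y)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle_on_random_dags(self, seed):
        ont = generate_ontology(40, depth=5, branching=2.0, extra_parent_p=0.2, seed=seed)
        rng = np.random.default_rng(seed)
        terms = [t for t in ont if t != ont.root]
        sets = []
        for _ in range(12):
            base = set(rng.choice(terms, size=int(rng.integers(1, 5)), replace=False))
            closed = set()
            for t in base:
                closed |= ont.ancestors(t)
            sets.append(closed)
        freqs = term_frequencies(sets)
        eng = SimilarityEngine(ont, freqs)
        parents = helpers.parent_map(ont)
        ic = freqs["ic"].to_dict()
        for _ in range(12):
            i, j = rng.integers(len(sets), size=2)
            got = eng.similarity(sets[i], sets[j])
            want = helpers.brute_similarity(sets[i], sets[j], parents, ic)
            assert got == pytest.approx(want)

    def test_sum_symmetrization_is_config_option(self, mini_ontology, mini_freqs,
                                                 mini_cohort):
        a, b = mini_cohort["P1"].prop_pos, mini_cohort["P6"].prop_pos
        mean_v = individual_similarity(a, b, mini_ontology, mini_freqs)
        sum_v = individual_similarity(a, b, mini_ontology, mini_freqs, symmetrize="sum")
        assert sum_v == pytest.approx(2 * mean_v)


@pytest.fixture(scope="module")
def cohort(mini_ontology, mini_freqs, mini_cohort):
    engine = SimilarityEngine(mini_ontology, mini_freqs)
    return CohortSimilarity(engine, {i: a.prop_pos for i, a in mini_cohort.items()})


class TestGroupPermutationTest:
    def test_p_matches_addone_formula_exactly(self, cohort):
        # the null includes the group's own members, so clone pairs can be
        # redrawn and tie the observed score; p must follow the add-one rule
        res = cohort.group_test(["P1", "P2"], n_permutations=200, seed=1, label="clones")
        null = cohort.null_medians(2, 200, seed=1)
        assert res.p == (1 + (null >= res.observed).sum()) / 201
        assert res.observed > 0
        assert res.observed >= null.max()  # clones top every draw (ties allowed)

    def test_observed_above_all_nulls_attains_minimal_p(self, mini_ontology):
        # two clones with a rare deep phenotype in a 400-individual cohort:
        # redrawing the exact pair in 300 draws has probability ~0.4%, so the
        # observed median tops every null draw and p hits its floor 1/(N+1)
        clone_terms = frozenset({"HP:0012469", "HP:0011097", "HP:0001250",
                                 "HP:0012638", "HP:0000707", "HP:0000118",
                                 "HP:0000001"})
        filler = frozenset({"HP:0000707", "HP:0000118", "HP:0000001"})
        sets = {"C1": clone_terms, "C2": clone_terms}
        sets.update({f"F{i}": filler for i in range(398)})
        freqs = term_frequencies(sets)
        eng = SimilarityEngine(mini_ontology, freqs)
        cohort = CohortSimilarity(eng, sets)
        null = cohort.null_medians(2, 300, seed=3)
        res = cohort.group_test(["C1", "C2"], n_permutations=300, seed=3)
        assert (null >= res.observed).sum() == 0
        assert res.p == pytest.approx(1 / 301)

    def test_p_formula_lower_bound(self, cohort):
        res = cohort.group_test(["P1", "P2"], n_permutations=50, seed=2)
        assert res.p >= 1 / 51

    def test_identical_seed_identical_result(self, cohort):
        r1 = cohort.group_test(["P1", "P3", "P4"], n_permutations=500, seed=9)
        r2 = cohort.group_test(["P1", "P3", "P4"], n_permutations=500, seed=9)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)

    def test_too_small_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            cohort.group_test(["P1"], n_permutations=10)

    def test_whole_cohort_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            cohort.group_test([f"P{i}" for i in range(1, 7)], n_permutations=10)

    def test_wrapper_equivalent(self, mini_ontology, mini_freqs, mini_cohort):
        eng = SimilarityEngine(mini_ontology, mini_freqs)
        sets = {i: a.prop_pos for i, a in mini_cohort.items()}
        res = group_similarity_test(["P1", "P2"], sets, eng, n_permutations=200, seed=1,
                                    label="clones")
        direct = CohortSimilarity(eng, sets).group_test(
            ["P1", "P2"], n_permutations=200, seed=1, label="clones")
        assert res == direct


class TestPhenogram:
    def test_equal_frequencies_not_highlighted(self, mini_cohort):
        sets = {i: a.prop_pos for i, a in mini_cohort.items()}
        out = phenogram(["P1", "P2"], sets)
        root_row = out.loc["HP:0000001"]
        assert root_row["p"] == 1.0
        assert not root_row["highlight"]

    def test_planted_group_term_highlighted(self, mini_ontology):
        sets = {f"G{i}": frozenset({"HP:0002072", "HP:0100022"}) for i in range(6)}
        sets.update({f"R{i}": frozenset({"HP:0000238"}) for i in range(14)})
        out = phenogram([f"G{i}" for i in range(6)], sets)
        assert out.loc["HP:0002072", "highlight"]
        assert out.loc["HP:0002072", "freq_group"] == 1.0
        assert out.loc["HP:0002072", "freq_rest"] == 0.0

    def test_group_equal_to_cohort_rejected(self, mini_cohort):
        sets = {i: a.prop_pos for i, a in mini_cohort.items()}
        with pytest.raises(ValueError):
            phenogram(list(sets), sets)


class TestSuite:
    def _records(self):
        recs = []
        for i in range(4):
            recs.append(VariantRecord(f"A{i}", "p.R853Q", "missense", broad="missense"))
        for i in range(2):
            recs.append(VariantRecord(f"B{i}", "p.L1342P", "missense", broad="missense"))
        recs.append(VariantRecord("C0", "p.R102*", "nonsense", broad="PTV"))
        recs.append(VariantRecord("C1", "p.V261M", "missense", broad="missense"))
        return recs

    def test_recurrent_variant_bookkeeping(self, mini_ontology, mini_cohort):
        from scn2a_pheno.similarity import _suite_groups

        groups = _suite_groups(self._records())
        recurrent = {g: m for g, m in groups.items() if g.startswith("variant")}
        assert set(recurrent) == {"variant p.R853Q", "variant p.L1342P"}
        assert len(recurrent["variant p.R853Q"]) == 4
        at_least_3 = [g for g, m in recurrent.items() if len(m) >= 3]
        assert at_least_3 == ["variant p.R853Q"]

    def test_suite_runs_and_skips_small_groups(self, mini_ontology, mini_freqs,
                                               mini_cohort):
        sets = {i: a.prop_pos for i, a in mini_cohort.items()}
        recs = [
            VariantRecord("P1", "p.R853Q", "missense", broad="missense"),
            VariantRecord("P2", "p.R853Q", "missense", broad="missense"),
            VariantRecord("P3", "p.R102*", "nonsense", broad="PTV"),
            VariantRecord("P4", "p.V261M", "missense", broad="missense"),
            VariantRecord("P5", "p.E999K", "missense", broad="missense"),
            VariantRecord("P6", "p.M1545V", "missense", broad="missense"),
        ]
        eng = SimilarityEngine(mini_ontology, mini_freqs)
        out = run_similarity_suite(sets, recs, eng, n_permutations=200, seed=0)
        assert "variant p.R853Q" in set(out["group"])
        # the lone-PTV class group cannot be tested
        assert "class: PTV" not in set(out["group"])
        clone = out.set_index("group").loc["variant p.R853Q"]
        # the P1/P2 clone pair is the most homogeneous group; its p is small
        # but bounded away from the floor by redraws of the pair itself
        assert clone["p"] < 0.2
        assert clone["p"] == out["p"].min()
        assert (out["p"] >= 1 / 201).all()
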