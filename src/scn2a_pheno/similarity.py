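"""Resnik-style phenotypic similarity and permutation tests for subgroups.

The similarity of two terms is the information content of their most
informative common ancestor (MICA) under the *propagated* cohort frequencies.
The similarity of two individuals is the best-match average of their
propagated positive term sets:

    s(A -> B) = sum over a in A of max over b in B of IC(MICA(a, b))
    sim(A, B) = (s(A -> B) + s(B -> A)) / 2

so sim is symmetric, sim(A, A) = sum of IC(a), and terms whose only shared
ancestor has frequency 1 (IC 0) contribute nothing.

Whether a subgroup (carriers of one recurrent variant, variants in one channel
domain, ...) is phenotypically more homogeneous than chance is assessed by a
permutation test: the observed statistic is the median of all within-group
pairwise similarities; the null repeatedly draws the same number of
individuals uniformly without replacement from the whole cohort and recomputes
the median.  The reported p uses the add-one rule p = (1 + #{null >= obs}) /
(N + 1), so p is never exactly zero and is bounded below by 1/(N+1).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import fisher_2x2
from .ontology import Ontology
from .variants import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityEngine",
    "CohortSimilarity",
    "SimilarityResult",
    "individual_similarity",
    "group_similarity_test",
    "phenogram",
    "plot_phenogram",
    "run_similarity_suite",
]


class SimilarityEngine:
    """Precomputed term-pair MICA information content over a term universe.

    The universe is the index of the propagated frequency table; every term of
    every compared set, and every common ancestor that can act as a MICA, must
    carry a frequency there (in a propagated data set this holds by
    construction).
    """

    def __init__(self, ontology: Ontology, freqs: pd.DataFrame, symmetrize: str = "mean"):
        if symmetrize not in ("mean", "sum"):
            raise ValueError("symmetrize must be 'mean' or 'sum'")
        self.symmetrize = symmetrize
        self.ontology = ontology
        self.terms: list[str] = list(freqs.index)
        self._pos = {t: i for i, t in enumerate(self.terms)}
        self.ic = freqs["ic"].to_numpy(dtype=float)
        n = len(self.terms)
        anc = np.zeros((n, n), dtype=bool)
        for i, t in enumerate(self.terms):
            for a in ontology.ancestors(t):
                j = self._pos.get(a)
                if j is not None:
                    anc[i, j] = True
        self._anc = anc
        self._pair_ic: np.ndarray | None = None

    @property
    def pair_ic(self) -> np.ndarray:
        """Dense term × term matrix of IC(MICA(t_i, t_j)) over the universe."""
        if self._pair_ic is None:
            n = len(self.terms)
            weighted = self._anc * self.ic  # row i: IC of each ancestor of t_i
            out = np.empty((n, n))
            for i in range(n):
                # max over common ancestors u: anc[i,u] & anc[j,u] -> ic[u]
                out[i] = np.where(self._anc, weighted[i], 0.0).max(axis=1)
            self._pair_ic = out
        return self._pair_ic

    def encode(self, terms: Iterable[str]) -> np.ndarray:
        idx = []
        unknown = []
        for t in terms:
            j = self._pos.get(t)
            if j is None:
                unknown.append(t)
            else:
                idx.append(j)
        if unknown:
            raise KeyError(
                f"terms missing from the similarity universe (propagated "
                f"frequency table): {sorted(unknown)[:5]}"
            )
        return np.asarray(sorted(idx), dtype=int)

    def similarity(self, set_a: Collection[str], set_b: Collection[str]) -> float:
        """Best-match-average similarity of two propagated positive term sets."""
        if not set_a or not set_b:
            logger.warning("similarity of an empty term set is 0")
            return 0.0
        ia, ib = self.encode(set_a), self.encode(set_b)
        sub = self.pair_ic[np.ix_(ia, ib)]
        s_ab = float(sub.max(axis=1).sum())
        s_ba = float(sub.max(axis=0).sum())
        total = s_ab + s_ba
        return total / 2.0 if self.symmetrize == "mean" else total

    def cohort_matrix(self, sets: Sequence[Collection[str]]) -> np.ndarray:
        """Symmetric n × n matrix of pairwise similarities (diagonal = self-sim)."""
        encoded = [self.encode(s) if s else np.empty(0, dtype=int) for s in sets]
        n = len(encoded)
        M = self.pair_ic
        out = np.zeros((n, n))
        half = self.symmetrize == "mean"
        for i in range(n):
            ia = encoded[i]
            if ia.size == 0:
                continue
            for j in range(i, n):
                ib = encoded[j]
                if ib.size == 0:
                    continue
                sub = M[np.ix_(ia, ib)]
                val = sub.max(axis=1).sum() + sub.max(axis=0).sum()
                out[i, j] = out[j, i] = val / 2.0 if half else val
        return out


def individual_similarity(
    set_a: Collection[str],
    set_b: Collection[str],
    ontology: Ontology,
    freqs: pd.DataFrame,
    symmetrize: str = "mean",
) -> float:
    """One-off similarity of two individuals (builds a throwaway engine).

    For repeated queries construct a :class:`SimilarityEngine` once.
    """
    return SimilarityEngine(ontology, freqs, symmetrize=symmetrize).similarity(set_a, set_b)


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of one group permutation test."""

    group: str
    members: tuple[str, ...]
    n: int
    observed: float
    n_permutations: int
    p: float
    seed: int


class CohortSimilarity:
    """All pairwise similarities of a cohort, shared across group tests.

    Null draws only ever index into this matrix, so a suite of permutation
    tests costs one matrix construction plus cheap resampling.
    """

    def __init__(self, engine: SimilarityEngine, sets: Mapping[str, Collection[str]]):
        self.ids: list[str] = list(sets)
        self._pos = {ind: i for i, ind in enumerate(self.ids)}
        self.empty = frozenset(i for i in self.ids if not sets[i])
        if self.empty:
            logger.warning(
                "%d individual(s) have empty propagated term sets; they score 0 "
                "and are excluded from group memberships", len(self.empty)
            )
        self.matrix = engine.cohort_matrix([sets[i] for i in self.ids])

    def _median_pairwise(self, idx: np.ndarray) -> float:
        sub = self.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(np.median(sub[iu]))

    def null_medians(self, n: int, n_permutations: int, seed: int) -> np.ndarray:
        """Null distribution: median pairwise similarity of *n* individuals
        drawn uniformly without replacement from the whole cohort (the test
        group's own members included), *n_permutations* times."""
        if not 2 <= n < len(self.ids):
            raise ValueError("need 2 <= n < cohort size")
        rng = np.random.default_rng(seed)
        n_cohort = len(self.ids)
        iu = np.triu_indices(n, k=1)
        out = np.empty(n_permutations)
        chunk = max(1, int(4_000_000 // max(n_cohort, n * n)))
        done = 0
        while done < n_permutations:
            m = min(chunk, n_permutations - done)
            # uniform n-subsets without replacement: smallest-n trick on uniforms
            keys = rng.random((m, n_cohort))
            draws = np.argpartition(keys, n - 1, axis=1)[:, :n]
            sub = self.matrix[draws[:, :, None], draws[:, None, :]]
            out[done:done + m] = np.median(sub[:, iu[0], iu[1]], axis=1)
            done += m
        return out

    def group_test(
        self,
        member_ids: Collection[str],
        n_permutations: int = 100_000,
        seed: int = 0,
        label: str = "",
    ) -> SimilarityResult:
        """Permutation test of within-group median pairwise similarity.

        Members with empty term sets are dropped (with a warning) before the
        test; the null resamples from the entire cohort, including the group's
        own members.
        """
        members = [m for m in member_ids if m not in self.empty]
        dropped = set(member_ids) - set(members)
        if dropped:
            logger.warning("group %r: dropping %d member(s) with empty term sets",
                           label, len(dropped))
        unknown = [m for m in members if m not in self._pos]
        if unknown:
            raise KeyError(f"group members not in cohort: {sorted(unknown)[:5]}")
        n = len(members)
        if n < 2:
            raise ValueError(f"group {label!r} needs >= 2 members with phenotypes, got {n}")
        if n > len(self.ids):
            raise ValueError("group larger than cohort")
        if n == len(self.ids):
            raise ValueError("group must be a proper subset of the cohort")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

        idx = np.asarray(sorted(self._pos[m] for m in members), dtype=int)
        observed = self._median_pairwise(idx)
        null = self.null_medians(n, n_permutations, seed)
        p = (1 + int((null >= observed).sum())) / (n_permutations + 1)
        return SimilarityResult(
            group=label or ",".join(sorted(members)[:3]) + ("..." if n > 3 else ""),
            members=tuple(sorted(members)),
            n=n,
            observed=observed,
            n_permutations=n_permutations,
            p=p,
            seed=seed,
        )


def group_similarity_test(
    member_ids: Collection[str],
    sets: Mapping[str, Collection[str]],
    engine: SimilarityEngine,
    n_permutations: int = 100_000,
    seed: int = 0,
    label: str = "",
) -> SimilarityResult:
    """Convenience wrapper building a :class:`CohortSimilarity` for one test."""
    return CohortSimilarity(engine, sets).group_test(
        member_ids, n_permutations=n_permutations, seed=seed, label=label
    )


def phenogram(
    group_ids: Collection[str],
    sets: Mapping[str, Collection[str]],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term frequency comparison of a subgroup against the cohort remainder.

    For every propagated term, the frequency among group members and among the
    remaining individuals, a two-sided Fisher exact p, and a highlight flag at
    the *uncorrected* threshold (phenograms are descriptive companions to the
    permutation test, not a corrected association analysis).
    """
    group = set(group_ids)
    unknown = group - set(sets)
    if unknown:
        raise KeyError(f"group members not in cohort: {sorted(unknown)[:5]}")
    if not group:
        raise ValueError("empty group")
    rest = [i for i in sets if i not in group]
    if not rest:
        raise ValueError("group must be a proper subset of the cohort")
    n_g, n_r = len(group), len(rest)
    terms = sorted({t for s in sets.values() for t in s})
    rows = []
    for t in terms:
        a = sum(1 for i in group if t in sets[i])
        c = sum(1 for i in rest if t in sets[i])
        p = fisher_2x2(a, n_g - a, c, n_r - c, ci=False).p
        rows.append((t, a / n_g, c / n_r, p, p < threshold))
    return pd.DataFrame(
        rows, columns=["term", "freq_group", "freq_rest", "p", "highlight"]
    ).set_index("term")


def plot_phenogram(table: pd.DataFrame, path, title: str = "") -> None:
    """Minimal frequency-vs-frequency scatter of a phenogram table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    hot = table["highlight"].astype(bool)
    ax.scatter(table.loc[~hot, "freq_rest"], table.loc[~hot, "freq_group"],
               s=12, c="tab:blue", label="p >= 0.05")
    ax.scatter(table.loc[hot, "freq_rest"], table.loc[hot, "freq_group"],
               s=16, c="tab:red", label="p < 0.05")
    ax.plot([0, 1], [0, 1], lw=0.5, c="gray")
    ax.set_xlabel("frequency, rest of cohort")
    ax.set_ylabel("frequency, group")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _suite_groups(records: Sequence[VariantRecord]) -> dict[str, set[str]]:
    """Group definitions for the standard similarity suite."""
    groups: dict[str, set[str]] = {}
    missense = {r.individual_id for r in records if r.broad == "missense"}
    ptv = {r.individual_id for r in records if r.broad == "PTV"}
    groups["class: missense"] = missense
    groups["class: PTV"] = ptv
    pore: set[str] = set()
    for r in records:
        if r.broad != "missense" or r.location is None:
            continue
        loc = r.location
        if loc.domain:
            groups.setdefault(f"domain {loc.domain}", set()).add(r.individual_id)
        if loc.segment:
            groups.setdefault(f"segment {loc.segment}", set()).add(r.individual_id)
        if loc.pore_loop:
            pore.add(r.individual_id)
    groups["pore loop"] = pore
    groups["missense excl. pore loop"] = missense - pore
    by_label: dict[str, set[str]] = {}
    for r in records:
        by_label.setdefault(r.label, set()).add(r.individual_id)
    for label, members in by_label.items():
        if len(members) >= 2:
            groups[f"variant {label}"] = members
    return groups


def run_similarity_suite(
    sets: Mapping[str, Collection[str]],
    records: Sequence[VariantRecord],
    engine: SimilarityEngine,
    n_permutations: int = 100_000,
    seed: int = 0,
    min_group: int = 2,
) -> pd.DataFrame:
    """Permutation tests for the standard subgroup families.

    Tested groups: broad variant classes, each channel domain, each segment
    class pooled across domains, pore-loop carriers, missense excluding
    pore-loop carriers, and every recurrent variant carried by >= *min_group*
    individuals.  Each group gets an independent, reproducible random stream
    spawned from *seed*.
    """
    cohort = CohortSimilarity(engine, sets)
    groups = _suite_groups(records)
    ss = np.random.SeedSequence(seed)
    seeds = {label: int(s.generate_state(1)[0] % (2**31)) for label, s in
             zip(sorted(groups), ss.spawn(len(groups)))}
    rows = []
    for label in sorted(groups):
        members = {m for m in groups[label] if m in cohort._pos} - cohort.empty
        if len(members) < max(2, min_group):
            logger.info("similarity group %r skipped (n=%d)", label, len(members))
            continue
        if len(members) >= len(cohort.ids):
            logger.info("similarity group %r skipped (covers whole cohort)", label)
            continue
        res = cohort.group_test(
            members, n_permutations=n_permutations, seed=seeds[label], label=label
        )
        rows.append((label, res.n, res.observed, res.n_permutations, res.p, res.seed))
    return pd.DataFrame(
        rows, columns=["group", "n", "observed_median", "n_permutations", "p", "seed"]
    )
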