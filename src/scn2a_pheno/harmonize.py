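"""Harmonization of positive and negative phenotype annotations.

Clinical descriptions differ in granularity: one report records "Infantile
spasms", another only "Seizure".  Propagation fixes this by closing every
individual's positive annotations upward over ``is_a`` edges ("base" terms
become "propagated" terms), so cohort frequencies compare like with like.

Explicitly *absent* phenotypes (negative annotations) carry the opposite
logic: absence of a general phenotype implies absence of every more specific
one, so negatives propagate **downward**.  Because downward closure explodes
into large term sets, the full negative set is compressed by *pruning*: only
the apex of each negative region is retained (a negative term whose parent is
also negative adds no information).  Pruning is lossless — re-running the
downward propagation on the pruned set recovers the full set.

A positive assertion always dominates: downward propagation is blocked at any
term that is itself positive or has a positive descendant, so no individual
ever carries a term as both present and absent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .association import bh_fdr, fisher_2x2
from .ontology import Ontology, ancestor_closure, term_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "ConflictError",
    "propagate_positive",
    "propagate_negative",
    "prune_negative",
    "harmonize_individual",
    "harmonize_cohort",
    "annotation_frequencies",
    "build_phenotype_matrix",
    "compare_term_frequencies",
    "to_long_table",
]

NEGATIVE_PREFIX = "NP:"


class ConflictError(ValueError):
    """A phenotype is asserted both present and absent for one individual."""


@dataclass(frozen=True)
class AnnotationSet:
    """Base and harmonized annotation sets for one individual.

    Invariants: ``base_pos ⊆ prop_pos`` and ``prop_pos`` is ancestor-closed;
    ``prop_neg_pruned ⊆ prop_neg_full``; ``prop_pos ∩ prop_neg_full = ∅``.
    """

    individual_id: str
    base_pos: frozenset[str]
    base_neg: frozenset[str]
    prop_pos: frozenset[str]
    prop_neg_full: frozenset[str]
    prop_neg_pruned: frozenset[str]


def propagate_positive(ontology: Ontology, base_pos: Iterable[str]) -> frozenset[str]:
    """Upward closure of base positive terms (idempotent)."""
    return ancestor_closure(ontology, base_pos)


def propagate_negative(
    ontology: Ontology,
    base_neg: Iterable[str],
    prop_pos: Iterable[str] = (),
    max_depth: int | None = None,
) -> frozenset[str]:
    """Downward propagation of negative terms, blocked by positive assertions.

    Returns the union of descendant closures of *base_neg*, minus any term that
    is in *prop_pos* and minus any term with a descendant in *prop_pos* — a
    negative assertion never contradicts or subsumes a positive one.

    Parameters
    ----------
    max_depth:
        Optional cap on the propagation depth below each base negative term
        (``None`` = unlimited), to control term explosion on large ontologies.

    Raises
    ------
    ConflictError
        If a base negative term itself appears in *prop_pos*.
    """
    base = ontology.canonicalize(base_neg)
    pos = frozenset(prop_pos)
    conflicts = base & pos
    if conflicts:
        raise ConflictError(
            f"term(s) asserted both positive and negative: {sorted(conflicts)}"
        )
    full: set[str] = set()
    for t in base:
        if max_depth is None:
            full |= ontology.descendants(t)
        else:
            frontier = {t}
            for _ in range(max_depth + 1):
                if not frontier:
                    break
                full |= frontier
                frontier = {c for x in frontier for c in ontology.children(x)} - full
    blocked = {t for t in full if t in pos or ontology.descendants(t) & pos}
    return frozenset(full - blocked)


def prune_negative(ontology: Ontology, neg_full: Iterable[str]) -> frozenset[str]:
    """Apex-only compression of a propagated negative set.

    A term is retained iff no parent of it is also negative, i.e. it is an apex
    of its negative region.  Re-running :func:`propagate_negative` on the
    pruned set (with the same positive blocks) recovers the full set exactly.
    """
    neg = frozenset(neg_full)
    return frozenset(t for t in neg if not (ontology.parents(t) & neg))


def harmonize_individual(
    ontology: Ontology,
    individual_id: str,
    base_pos: Iterable[str],
    base_neg: Iterable[str],
    max_neg_depth: int | None = None,
) -> AnnotationSet:
    """Produce the full :class:`AnnotationSet` for one individual."""
    base_pos = ontology.canonicalize(base_pos)
    base_neg = ontology.canonicalize(base_neg)
    prop_pos = propagate_positive(ontology, base_pos)
    try:
        neg_full = propagate_negative(ontology, base_neg, prop_pos, max_depth=max_neg_depth)
    except ConflictError as err:
        raise ConflictError(f"individual {individual_id!r}: {err}") from None
    return AnnotationSet(
        individual_id=individual_id,
        base_pos=base_pos,
        base_neg=base_neg,
        prop_pos=prop_pos,
        prop_neg_full=neg_full,
        prop_neg_pruned=prune_negative(ontology, neg_full),
    )


def harmonize_cohort(
    ontology: Ontology,
    annotations: pd.DataFrame,
    max_neg_depth: int | None = None,
) -> dict[str, AnnotationSet]:
    """Harmonize a long-format annotation table.

    *annotations* must have columns ``individual_id``, ``term`` and
    ``polarity`` ('positive'/'negative'); see :mod:`scn2a_pheno.io` for the
    on-disk dialect (which also accepts the ``NP:`` shorthand).
    """
    required = {"individual_id", "term", "polarity"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing column(s): {sorted(missing)}")
    out: dict[str, AnnotationSet] = {}
    for ind, sub in annotations.groupby("individual_id", sort=True):
        pos = sub.loc[sub["polarity"] == "positive", "term"]
        neg = sub.loc[sub["polarity"] == "negative", "term"]
        out[str(ind)] = harmonize_individual(
            ontology, str(ind), pos, neg, max_neg_depth=max_neg_depth
        )
    return out


_STATES = ("base_pos", "base_neg", "prop_pos", "prop_neg_full", "prop_neg_pruned")


def annotation_frequencies(
    sets: Mapping[str, AnnotationSet] | Iterable[AnnotationSet],
    which: str = "prop_pos",
    n: int | None = None,
) -> pd.DataFrame:
    """Frequency/IC table over one annotation state (see ``AnnotationSet`` fields)."""
    if which not in _STATES:
        raise ValueError(f"which must be one of {_STATES}")
    records = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    return term_frequencies([getattr(a, which) for a in records], n=n)


def build_phenotype_matrix(
    sets: Mapping[str, AnnotationSet] | Iterable[AnnotationSet],
    positive: bool = True,
    negative: bool = True,
    min_count: int = 1,
) -> pd.DataFrame:
    """Individuals × terms binary matrix for association testing and PCA.

    Positive columns are propagated positive terms under their ``HP:`` ids;
    negative columns come from the *pruned* negative set and are prefixed
    ``NP:``.  Columns carried by fewer than *min_count* individuals are
    dropped.
    """
    records = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    ids = [a.individual_id for a in records]
    columns: dict[str, set[str]] = {}
    for a in records:
        if positive:
            for t in a.prop_pos:
                columns.setdefault(t, set()).add(a.individual_id)
        if negative:
            for t in a.prop_neg_pruned:
                columns.setdefault(NEGATIVE_PREFIX + t.split(":", 1)[1], set()).add(
                    a.individual_id
                )
    keep = sorted(c for c, carriers in columns.items() if len(carriers) >= min_count)
    data = np.zeros((len(ids), len(keep)), dtype=bool)
    pos_of = {ind: i for i, ind in enumerate(ids)}
    for j, c in enumerate(keep):
        for ind in columns[c]:
            data[pos_of[ind], j] = True
    return pd.DataFrame(data, index=pd.Index(ids, name="individual_id"), columns=keep)


def compare_term_frequencies(
    base: pd.DataFrame,
    propagated: pd.DataFrame,
    n: int,
    q: float = 0.10,
) -> pd.DataFrame:
    """Per-term shift in cohort frequency caused by propagation.

    For every base term, a two-sided Fisher exact test compares the base count
    against the propagated count (each versus the cohort remainder), with
    Benjamini–Hochberg control at FDR *q* across all base terms.  A large,
    significant shift means the broader phenotype was implicit in many
    individuals' descriptions but rarely recorded explicitly.
    """
    for name, table in (("base", base), ("propagated", propagated)):
        if (table["count"] > n).any():
            raise ValueError(f"{name} counts exceed cohort size n={n}")
    rows = []
    for term in base.index:
        b = int(base.loc[term, "count"])
        p_count = int(propagated.loc[term, "count"]) if term in propagated.index else 0
        if p_count < b:
            raise ValueError(
                f"propagated count below base count for {term!r}; "
                "tables come from different cohorts?"
            )
        res = fisher_2x2(b, n - b, p_count, n - p_count, ci=False)
        rows.append((term, b, p_count, res.p))
    out = pd.DataFrame(rows, columns=["term", "base_count", "propagated_count", "p"])
    out["significant"] = bh_fdr(out["p"].to_numpy(), q) if len(out) else []
    return out.set_index("term")


def to_long_table(sets: Mapping[str, AnnotationSet] | Iterable[AnnotationSet]) -> pd.DataFrame:
    """Long-format export: individual_id, term, polarity, state (base/propagated)."""
    records = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    rows = []
    for a in records:
        for t in sorted(a.base_pos):
            rows.append((a.individual_id, t, "positive", "base"))
        for t in sorted(a.prop_pos - a.base_pos):
            rows.append((a.individual_id, t, "positive", "propagated"))
        for t in sorted(a.base_neg):
            rows.append((a.individual_id, t, "negative", "base"))
        for t in sorted(a.prop_neg_pruned - a.base_neg):
            rows.append((a.individual_id, t, "negative", "propagated"))
    return pd.DataFrame(rows, columns=["individual_id", "term", "polarity", "state"])
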