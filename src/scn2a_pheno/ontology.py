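"""Ontology layer: OBO parsing, ancestor/descendant closures, term frequencies,
information content, and the most informative common ancestor (MICA).

The Human Phenotype Ontology (HPO) is a rooted directed acyclic graph of
phenotype terms linked by ``is_a`` edges.  Everything downstream of this module
— annotation propagation, Resnik similarity, association testing — is built on
four primitives defined here:

* the transitive *ancestor closure* of a term set (a term plus every
  higher-level term up to the root),
* the *descendant closure* (a term plus every more specific term below it),
* per-term cohort frequencies ``f`` and information content ``IC = -log2(f)``
  in bits, so rarer terms are more informative, and
* the MICA of two terms: the common ancestor with maximal IC.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "Ontology",
    "OntologyError",
    "UnknownTermError",
    "parse_obo",
    "ancestor_closure",
    "descendant_closure",
    "term_frequencies",
    "information_content",
    "mica",
]


class OntologyError(ValueError):
    """Structural problem with an ontology (cycle, dangling edge, no root)."""


class UnknownTermError(OntologyError):
    """A queried term identifier cannot be resolved in the loaded ontology."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` holds direct ``is_a`` parents only; use :meth:`Ontology.ancestors`
    for the transitive closure.  Obsolete terms are retained so that identifiers
    remain resolvable, but they are excluded from closure queries and carry no
    children.
    """

    id: str
    name: str
    parents: frozenset[str]
    obsolete: bool = False


class Ontology:
    """A rooted DAG of terms with cached closure queries.

    Parameters
    ----------
    terms:
        Mapping from term id to :class:`Term`.  Parent references must resolve
        to non-obsolete terms in the mapping.
    alt_ids:
        Optional mapping from alternate (merged) identifiers to canonical ids.
    """

    def __init__(self, terms: Mapping[str, Term], alt_ids: Mapping[str, str] | None = None):
        self._terms: dict[str, Term] = dict(terms)
        self._alt_ids: dict[str, str] = dict(alt_ids or {})
        self._active = {t.id for t in self._terms.values() if not t.obsolete}

        self._parents: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] = {tid: set() for tid in self._active}
        for tid in self._active:
            term = self._terms[tid]
            for p in term.parents:
                if p not in self._active:
                    kind = "obsolete" if p in self._terms else "undefined"
                    raise OntologyError(
                        f"term {tid!r} has is_a parent {p!r} which is {kind}"
                    )
                self._children[p].add(tid)
            self._parents[tid] = frozenset(term.parents)
        for tid, term in self._terms.items():
            if term.obsolete and self._children.get(tid):
                raise OntologyError(f"obsolete term {tid!r} has children")

        graph = nx.DiGraph()
        graph.add_nodes_from(self._active)
        graph.add_edges_from((c, p) for c, ps in self._parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"cyclic is_a relations: {path}")
        self._graph = graph

        roots = sorted(t for t in self._active if not self._parents[t])
        if len(roots) != 1:
            raise OntologyError(f"expected a single root term, found {roots or 'none'}")
        self.root: str = roots[0]

        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] | None = None

    # -- basic queries -------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._active or term in self._alt_ids

    def __len__(self) -> int:
        """Number of non-obsolete terms."""
        return len(self._active)

    def __iter__(self):
        return iter(sorted(self._active))

    @property
    def terms(self) -> Mapping[str, Term]:
        return self._terms

    @property
    def alt_ids(self) -> Mapping[str, str]:
        return self._alt_ids

    def name(self, term: str) -> str:
        return self._terms[self.canonical(term)].name

    def canonical(self, term: str) -> str:
        """Resolve *term*, following alt_id merges, to its canonical id."""
        if term in self._active:
            return term
        if term in self._alt_ids:
            return self._alt_ids[term]
        if term in self._terms:  # obsolete
            raise UnknownTermError(f"term {term!r} is obsolete and excluded from queries")
        raise UnknownTermError(f"unknown term {term!r}")

    def canonicalize(self, terms: Iterable[str]) -> frozenset[str]:
        """Canonicalize a collection of ids, raising one error listing all unknowns."""
        out, bad = set(), []
        n_alt = 0
        for t in terms:
            try:
                c = self.canonical(t)
            except UnknownTermError:
                bad.append(t)
                continue
            if c != t:
                n_alt += 1
            out.add(c)
        if bad:
            raise UnknownTermError(f"unknown or obsolete terms: {sorted(bad)}")
        if n_alt:
            logger.info("canonicalized %d annotation(s) given as alt_id", n_alt)
        return frozenset(out)

    def parents(self, term: str) -> frozenset[str]:
        return self._parents[self.canonical(term)]

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[self.canonical(term)])

    def depth(self, term: str) -> int:
        """Length of the longest path from the root (root has depth 0)."""
        if self._depth_cache is None:
            depths: dict[str, int] = {}
            for tid in nx.topological_sort(self._graph.reverse(copy=False)):
                ps = self._parents[tid]
                depths[tid] = 0 if not ps else 1 + max(depths[p] for p in ps)
            self._depth_cache = depths
        return self._depth_cache[self.canonical(term)]

    def leaves(self) -> frozenset[str]:
        return frozenset(t for t in self._active if not self._children[t])

    # -- closures ------------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive ``is_a`` ancestors of *term*, **including the term itself**."""
        term = self.canonical(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        # iterative post-order so deep chains do not hit the recursion limit
        stack = [term]
        order: list[str] = []
        seen = set()
        while stack:
            t = stack.pop()
            if t in seen or t in self._anc_cache:
                continue
            seen.add(t)
            order.append(t)
            stack.extend(self._parents[t])
        for t in reversed(order):
            if t in self._anc_cache:
                continue
            acc = {t}
            for p in self._parents[t]:
                acc |= self._anc_cache[p] if p in self._anc_cache else self.ancestors(p)
            self._anc_cache[t] = frozenset(acc)
        return self._anc_cache[term]

    def descendants(self, term: str) -> frozenset[str]:
        """Transitive ``is_a`` descendants of *term*, including the term itself."""
        term = self.canonical(term)
        cached = self._desc_cache.get(term)
        if cached is not None:
            return cached
        acc = {term}
        frontier = list(self._children[term])
        while frontier:
            t = frontier.pop()
            if t in acc:
                continue
            acc.add(t)
            frontier.extend(self._children[t])
        result = frozenset(acc)
        self._desc_cache[term] = result
        return result

    # -- derived ontologies --------------------------------------------------

    def restrict(self, term: str) -> "Ontology":
        """Sub-ontology rooted at *term* (e.g. the phenotypic-abnormality subtree)."""
        keep = self.descendants(term)
        sub = {
            tid: Term(tid, self._terms[tid].name,
                      frozenset(p for p in self._parents[tid] if p in keep))
            for tid in keep
        }
        alt = {a: c for a, c in self._alt_ids.items() if c in keep}
        return Ontology(sub, alt)

    def to_obo(self, path) -> None:
        """Write a minimal OBO 1.2 rendering (id, name, is_a, alt_id, is_obsolete)."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: scn2a-pheno-export\n")
            alt_by_canonical: dict[str, list[str]] = {}
            for a, c in self._alt_ids.items():
                alt_by_canonical.setdefault(c, []).append(a)
            for tid in sorted(self._terms):
                term = self._terms[tid]
                fh.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
                for a in sorted(alt_by_canonical.get(tid, [])):
                    fh.write(f"alt_id: {a}\n")
                for p in sorted(term.parents):
                    fh.write(f"is_a: {p} ! {self._terms[p].name}\n")
                if term.obsolete:
                    fh.write("is_obsolete: true\n")

    @classmethod
    def from_parent_map(cls, parents: Mapping[str, Collection[str]],
                        names: Mapping[str, str] | None = None) -> "Ontology":
        names = names or {}
        terms = {
            tid: Term(tid, names.get(tid, tid), frozenset(ps))
            for tid, ps in parents.items()
        }
        return cls(terms)


def parse_obo(source, restrict_to: str | None = None) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Only ``id``, ``name``, ``alt_id``, ``is_a`` and ``is_obsolete`` are
    interpreted; other relations (``part_of`` etc.) are ignored.

    Parameters
    ----------
    source:
        Path or readable text stream in OBO format.
    restrict_to:
        Optional term id; the returned ontology is restricted to that term's
        descendant subtree (for HPO, pass the phenotypic-abnormality term to
        drop inheritance/modifier branches before propagation).
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    dangling = []
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            dangling.append(node)
            continue
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parent_ids = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        ) if not obsolete else frozenset()
        terms[node] = Term(node, data["name"], parent_ids, obsolete=obsolete)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    if dangling:
        raise OntologyError(f"dangling is_a target(s): {sorted(dangling)}")

    ontology = Ontology(terms, alt_ids)
    if restrict_to is not None:
        ontology = ontology.restrict(ontology.canonical(restrict_to))
    return ontology


def ancestor_closure(ontology: Ontology, terms: Iterable[str]) -> frozenset[str]:
    """Union over *terms* of each term plus all of its ancestors (idempotent)."""
    out: set[str] = set()
    for t in ontology.canonicalize(terms):
        out |= ontology.ancestors(t)
    return frozenset(out)


def descendant_closure(ontology: Ontology, term: str) -> frozenset[str]:
    """*term* plus all of its descendants."""
    return ontology.descendants(term)


def term_frequencies(
    annotations: Mapping[str, Collection[str]] | Iterable[Collection[str]],
    n: int | None = None,
) -> pd.DataFrame:
    """Per-term cohort counts, frequencies and information content.

    Parameters
    ----------
    annotations:
        Per-individual term sets (a mapping id -> set, or an iterable of sets).
        Set semantics guarantee each individual contributes at most once per term.
    n:
        Cohort size; defaults to the number of individuals supplied.  Must be >= 1.

    Returns
    -------
    DataFrame indexed by term with columns ``count`` (int), ``f`` = count / n,
    and ``ic`` = -log2(f) in bits.  Terms never observed are absent, so f is in
    (0, 1] and ic = 0 iff f = 1.
    """
    if isinstance(annotations, Mapping):
        sets = list(annotations.values())
    else:
        sets = list(annotations)
    if n is None:
        n = len(sets)
    if n < 1:
        raise ValueError("cohort size n must be >= 1")
    if len(sets) > n:
        raise ValueError(f"{len(sets)} individuals supplied but n={n}")
    counts = Counter()
    for s in sets:
        counts.update(set(s))
    index = sorted(counts)
    count = np.array([counts[t] for t in index], dtype=int)
    f = count / n
    table = pd.DataFrame({"count": count, "f": f, "ic": -np.log2(f) + 0.0},
                         index=pd.Index(index, name="term"))
    return table


def information_content(count: int, n: int) -> float:
    """IC in bits of a term carried by *count* of *n* individuals."""
    if not 0 < count <= n:
        raise ValueError("count must be in (0, n]")
    return -math.log2(count / n)


def mica(ontology: Ontology, freqs: pd.DataFrame, t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms under a frequency table.

    A term subsuming the other is its own MICA candidate, because closures
    include the query term.  Ties in IC are broken deterministically by the
    lexicographically smallest term id.  Every candidate ancestor must appear
    in *freqs* — callers must supply complete propagated frequencies; a missing
    query term is a hard error, never silently imputed.
    """
    t1, t2 = ontology.canonical(t1), ontology.canonical(t2)
    ic = freqs["ic"]
    for t in (t1, t2):
        if t not in ic.index:
            raise OntologyError(f"term {t!r} missing from the frequency table")
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    candidates = [t for t in common if t in ic.index]
    if not candidates:
        raise OntologyError(
            f"no common ancestor of {t1!r} and {t2!r} has a frequency; "
            "supply complete propagated frequencies"
        )
    best = min(candidates, key=lambda t: (-ic[t], t))
    return best, float(ic[best])
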