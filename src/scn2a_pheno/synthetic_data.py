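"""Synthetic ontologies and cohorts with planted, recoverable structure.

Every pipeline stage is exercised on generated data whose ground truth is
known exactly: a random rooted DAG stands in for the phenotype ontology, and a
cohort of individuals receives

* background base terms drawn depth-biased from the ontology (median ≈ 6 base
  terms per individual, the granularity typical of literature-derived deep
  phenotyping),
* *planted class effects*: a designated leaf term carried with class-dependent
  probability tuned to a target odds ratio between protein-truncating (PTV)
  and missense carriers,
* a *planted location effect*: an autism-like leaf enriched in carriers of
  pore-loop missense variants,
* *recurrent-variant groups* sharing a homogeneous core of phenotype terms
  (high within-group similarity),
* a latent two-class gain-/loss-of-function factor expressed through disjoint
  marker-term sets, with electrophysiology labels revealed for a subset, and
* negative (explicitly absent) phenotypes, only ever asserted for individuals
  whose positive closure does not contradict them.

The returned truth record documents every planted effect so tests can verify
recovery, and the same seed always reproduces identical tables.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import Ontology, Term
from .variants import ProteinTopology, load_bundled_topology

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "generate_ontology", "generate_cohort"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_ontology(
    n_terms: int,
    depth: int = 6,
    branching: float = 2.0,
    extra_parent_p: float = 0.08,
    seed: int = 0,
) -> Ontology:
    """Random rooted DAG with HPO-like ids, acyclic by construction.

    Terms are assigned to levels 1..depth with probability proportional to
    ``branching**level`` (larger branching pushes mass toward the leaves);
    each term takes one uniformly chosen parent from a strictly shallower
    level, plus, with probability *extra_parent_p*, a second such parent, so
    the graph is a DAG rather than a tree.  Identical seeds give identical
    edge sets.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if n_terms > 1 and (branching <= 0 or depth < 1):
        raise ValueError("need branching > 0 and depth >= 1 for more than one term")
    rng = np.random.default_rng(seed)
    ids = [f"HP:{i + 1:07d}" for i in range(n_terms)]
    names = {ids[0]: "All"}
    levels = {ids[0]: 0}
    parents: dict[str, set[str]] = {ids[0]: set()}
    if n_terms > 1:
        weights = np.array([float(branching) ** l for l in range(1, depth + 1)])
        weights /= weights.sum()
        by_level: dict[int, list[str]] = {0: [ids[0]]}
        for i, tid in enumerate(ids[1:], start=1):
            while True:
                level = int(rng.choice(np.arange(1, depth + 1), p=weights))
                shallower = [t for l in range(level) for t in by_level.get(l, [])]
                if shallower:
                    break
            p1 = shallower[int(rng.integers(len(shallower)))]
            ps = {p1}
            if len(shallower) > 1 and rng.random() < extra_parent_p:
                p2 = p1
                while p2 == p1:
                    p2 = shallower[int(rng.integers(len(shallower)))]
                ps.add(p2)
            parents[tid] = ps
            levels[tid] = level
            by_level.setdefault(level, []).append(tid)
            names[tid] = f"Synthetic phenotype {i}"
    terms = {tid: Term(tid, names[tid], frozenset(parents[tid])) for tid in ids}
    return Ontology(terms)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a generated cohort.

    Defaults mirror the structure of a literature-curated channelopathy
    cohort: 341 missense + 68 PTV + 4 other individuals, a median of 6 base
    terms each, planted class effects at odds ratio 8, three recurrent-variant
    groups with shared phenotype cores, a pore-loop location effect, and a
    latent GoF/LoF factor with 17 GoF and ~57 LoF labeled carriers (PTVs count
    as LoF).
    """

    n_missense: int = 341
    n_ptv: int = 68
    n_other: int = 4
    base_terms_median: int = 6
    # (class, target odds ratio, baseline frequency outside the class)
    planted_class_effects: tuple[tuple[str, float, float], ...] = (
        ("PTV", 8.0, 0.12),
        ("missense", 8.0, 0.12),
    )
    # (group size, number of core terms, core penetrance)
    recurrent_groups: tuple[tuple[int, int, float], ...] = (
        (18, 3, 0.85),
        (14, 3, 0.85),
        (5, 4, 0.9),
    )
    pore_fraction: float = 0.12
    pore_effect: tuple[float, float] | None = (5.0, 0.12)  # (OR, baseline f)
    n_gof_markers: int = 6
    n_lof_markers: int = 6
    marker_hi: float = 0.60
    marker_lo: float = 0.08
    gof_fraction: float = 0.30
    n_gof_labeled: int = 17
    n_lof_labeled_missense: int = 30
    negative_rate: float = 0.6
    max_negative_terms: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("pore_fraction", "marker_hi", "marker_lo", "gof_fraction",
                     "negative_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for _, or_, f0 in self.planted_class_effects:
            if or_ <= 0 or not 0 < f0 < 1:
                raise ValueError("planted odds ratios must be > 0 with baseline in (0,1)")
        if sum(size for size, _, _ in self.recurrent_groups) > self.n_missense:
            raise ValueError("recurrent groups exceed the missense cohort")

    @property
    def n_individuals(self) -> int:
        return self.n_missense + self.n_ptv + self.n_other

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A no-effect configuration: pure background, no planted structure."""
        base = dict(
            planted_class_effects=(),
            recurrent_groups=(),
            pore_effect=None,
            n_gof_markers=0,
            n_lof_markers=0,
            n_gof_labeled=0,
            n_lof_labeled_missense=0,
        )
        base.update(overrides)
        return cls(**base)


def _or_to_freq(odds_ratio: float, f0: float) -> float:
    odds = odds_ratio * f0 / (1 - f0)
    return odds / (1 + odds)


def generate_cohort(
    config: CohortConfig,
    ontology: Ontology,
    topology: ProteinTopology | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (annotation table, variant table, truth record).

    The annotation table is long-format (individual_id, term, polarity); the
    variant table has individual_id, variant, var_class, phenotype_group and
    functional_evidence columns — exactly the dialects the pipeline consumes.
    """
    rng = np.random.default_rng(config.seed)
    topology = topology or load_bundled_topology()

    leaves = sorted(ontology.leaves() - {ontology.root})
    n_special = (
        len(config.planted_class_effects)
        + (1 if config.pore_effect else 0)
        + config.n_gof_markers + config.n_lof_markers
        + sum(c for _, c, _ in config.recurrent_groups)
    )
    if n_special > len(leaves):
        raise ValueError(
            f"ontology has {len(leaves)} leaves but {n_special} planted terms are needed"
        )
    special = list(rng.choice(leaves, size=n_special, replace=False)) if n_special else []
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = special[cursor:cursor + k]
        cursor += k
        return [str(t) for t in out]

    planted_terms = {eff: take(1)[0] for eff in config.planted_class_effects}
    pore_term = take(1)[0] if config.pore_effect else None
    gof_markers = take(config.n_gof_markers)
    lof_markers = take(config.n_lof_markers)
    group_cores = [take(c) for _, c, _ in config.recurrent_groups]

    background = [t for t in ontology if t != ontology.root and t not in set(special)]
    bg_weights = np.array([ontology.depth(t) for t in background], dtype=float)
    bg_weights /= bg_weights.sum()

    ids = [f"IND-{i + 1:04d}" for i in range(config.n_individuals)]
    classes = (["missense"] * config.n_missense + ["PTV"] * config.n_ptv
               + ["other"] * config.n_other)

    # --- variants ----------------------------------------------------------
    pore_spans = list(topology.pore_loop_spans.values())
    tm_positions = [
        (f.start, f.end) for f in topology.features if f.region == "Transmembrane"
    ]

    def random_position(pore: bool) -> int:
        spans = pore_spans if pore else tm_positions
        lo, hi = spans[int(rng.integers(len(spans)))]
        return int(rng.integers(lo, hi + 1))

    def missense_label(pos: int) -> str:
        ref, alt = rng.choice(list(_AA), size=2, replace=False)
        return f"p.{ref}{pos}{alt}"

    missense_ids = [i for i, c in zip(ids, classes) if c == "missense"]
    order = rng.permutation(len(missense_ids))
    shuffled = [missense_ids[i] for i in order]
    group_members: list[list[str]] = []
    pos_in_group: set[str] = set()
    for size, _, _ in config.recurrent_groups:
        members, shuffled = shuffled[:size], shuffled[size:]
        group_members.append(members)
        pos_in_group.update(members)

    variant_of: dict[str, tuple[str, str, bool]] = {}  # id -> (label, class, pore)
    group_labels = []
    for members in group_members:
        pos = random_position(pore=False)
        label = missense_label(pos)
        group_labels.append(label)
        for m in members:
            variant_of[m] = (label, "missense", False)
    for ind in shuffled:  # singleton missense
        pore = bool(rng.random() < config.pore_fraction)
        variant_of[ind] = (missense_label(random_position(pore)), "missense", pore)
    ptv_classes = ["nonsense", "frameshift", "splice site", "deletion"]
    for k, ind in enumerate(i for i, c in zip(ids, classes) if c == "PTV"):
        vc = ptv_classes[k % len(ptv_classes)]
        if vc == "nonsense":
            label = f"p.{rng.choice(list(_AA))}{int(rng.integers(1, topology.length + 1))}*"
        elif vc == "frameshift":
            label = f"p.{rng.choice(list(_AA))}{int(rng.integers(1, topology.length + 1))}fs"
        elif vc == "splice site":
            label = f"splice_site_{k + 1}"
        else:
            label = f"gene_deletion_{k + 1}"
        variant_of[ind] = (label, vc, False)
    other_classes = ["in-frame deletion", "complex indel", "duplication"]
    for k, ind in enumerate(i for i, c in zip(ids, classes) if c == "other"):
        variant_of[ind] = (f"other_event_{k + 1}", other_classes[k % len(other_classes)], False)

    # --- latent GoF/LoF factor ---------------------------------------------
    latent: dict[str, str] = {}
    for ind, cls in zip(ids, classes):
        if cls == "missense":
            latent[ind] = "GoF" if rng.random() < config.gof_fraction else "LoF"
        else:
            latent[ind] = "LoF"

    # --- phenotype sampling -------------------------------------------------
    # the background draw budget discounts each individual's expected planted
    # additions, so the overall base-term median stays at the configured target
    def _expected_extras(cls: str, lat: str, pore: bool) -> float:
        extra = 0.0
        for (eff_cls, or_, f0), _term in planted_terms.items():
            extra += _or_to_freq(or_, f0) if cls == eff_cls else f0
        if pore_term is not None and cls == "missense":
            or_, f0 = config.pore_effect
            extra += _or_to_freq(or_, f0) if pore else f0
        n_match = config.n_gof_markers if lat == "GoF" else config.n_lof_markers
        n_other = config.n_gof_markers + config.n_lof_markers - n_match
        return extra + config.marker_hi * n_match + config.marker_lo * n_other

    pos_terms: dict[str, set[str]] = {}
    for ind, cls in zip(ids, classes):
        lam = max(0.5, config.base_terms_median
                  - _expected_extras(cls, latent[ind], variant_of[ind][2]))
        k = max(1, int(rng.poisson(lam)))
        k = min(k, len(background))
        base = set(rng.choice(background, size=k, replace=False, p=bg_weights))
        for (eff_cls, or_, f0), term in planted_terms.items():
            prob = _or_to_freq(or_, f0) if cls == eff_cls else f0
            if rng.random() < prob:
                base.add(term)
        if pore_term is not None and cls == "missense":
            or_, f0 = config.pore_effect
            prob = _or_to_freq(or_, f0) if variant_of[ind][2] else f0
            if rng.random() < prob:
                base.add(pore_term)
        hi, lo = config.marker_hi, config.marker_lo
        for t in gof_markers:
            if rng.random() < (hi if latent[ind] == "GoF" else lo):
                base.add(t)
        for t in lof_markers:
            if rng.random() < (hi if latent[ind] == "LoF" else lo):
                base.add(t)
        pos_terms[ind] = base
    for members, core, (_, _, pen) in zip(group_members, group_cores,
                                          config.recurrent_groups):
        for m in members:
            for t in core:
                if rng.random() < pen:
                    pos_terms[m].add(t)

    # --- negative assertions (never contradicting the positive closure) -----
    neg_terms: dict[str, list[str]] = {ind: [] for ind in ids}
    candidates = [t for t in ontology if t != ontology.root]
    for ind in ids:
        if rng.random() >= config.negative_rate:
            continue
        closure = set()
        for t in pos_terms[ind]:
            closure |= ontology.ancestors(t)
        k = int(rng.integers(1, config.max_negative_terms + 1))
        picked = []
        for t in rng.permutation(candidates):
            t = str(t)
            if ontology.descendants(t) & closure or t in closure:
                continue
            picked.append(t)
            if len(picked) == k:
                break
        neg_terms[ind] = picked

    # --- functional evidence labels -----------------------------------------
    singles = [i for i in missense_ids if i not in pos_in_group]
    gof_pool = [i for i in singles if latent[i] == "GoF"]
    lof_pool = [i for i in singles if latent[i] == "LoF"]
    labeled_gof = list(gof_pool[: config.n_gof_labeled])
    labeled_lof = list(lof_pool[: config.n_lof_labeled_missense])
    evidence_of = {variant_of[i][0]: "GoF" for i in labeled_gof}
    evidence_of.update({variant_of[i][0]: "LoF" for i in labeled_lof})

    # --- assemble tables -----------------------------------------------------
    ann_rows = []
    for ind in ids:
        for t in sorted(pos_terms[ind]):
            ann_rows.append((ind, t, "positive"))
        for t in sorted(neg_terms[ind]):
            ann_rows.append((ind, t, "negative"))
    annotations = pd.DataFrame(ann_rows, columns=["individual_id", "term", "polarity"])

    group_name = {"missense": ("DEE", "BFNIS", "ASD", "other"),
                  "PTV": ("ASD", "DEE", "other"), "other": ("atypical",)}
    group_probs = {"missense": (0.55, 0.2, 0.15, 0.1),
                   "PTV": (0.5, 0.4, 0.1), "other": (1.0,)}
    var_rows = []
    for ind, cls in zip(ids, classes):
        label, vc, _ = variant_of[ind]
        pg = str(rng.choice(group_name[cls], p=group_probs[cls]))
        var_rows.append((ind, label, vc, pg, evidence_of.get(label, "")))
    variants = pd.DataFrame(
        var_rows,
        columns=["individual_id", "variant", "var_class", "phenotype_group",
                 "functional_evidence"],
    )

    truth = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "planted_class_effects": [
            {
                "class": eff_cls, "term": term, "odds_ratio": or_,
                "f_in_class": _or_to_freq(or_, f0), "f_baseline": f0,
            }
            for (eff_cls, or_, f0), term in planted_terms.items()
        ],
        "pore_term": pore_term,
        "pore_effect": list(config.pore_effect) if config.pore_effect else None,
        "gof_markers": gof_markers,
        "lof_markers": lof_markers,
        "recurrent_groups": [
            {"variant": label, "members": members, "core_terms": core,
             "penetrance": pen}
            for label, members, core, (_, _, pen) in zip(
                group_labels, group_members, group_cores, config.recurrent_groups)
        ],
        "latent_function": latent,
        "labeled_gof": labeled_gof,
        "labeled_lof_missense": labeled_lof,
    }
    return annotations, variants, truth
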