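"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain-Python recursion, exhaustive
enumeration, double loops — and shares no code with the implementation it
checks.
"""
from __future__ import annotations

from math import comb


def parent_map(ontology) -> dict[str, set[str]]:
    return {t: set(ontology.parents(t)) for t in ontology}


def brute_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive transitive closure over parent edges, by recursion."""
    out = {term}
    for p in parents[term]:
        out |= brute_ancestors(parents, p)
    return out


def brute_descendants(parents: dict[str, set[str]], term: str) -> set[str]:
    children: dict[str, set[str]] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            children[p].add(t)
    out = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for c in children[t]:
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def has_cycle(parents: dict[str, set[str]]) -> bool:
    """Depth-first cycle search over parent edges."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {t: WHITE for t in parents}

    def visit(t: str) -> bool:
        color[t] = GRAY
        for p in parents[t]:
            if color[p] == GRAY:
                return True
            if color[p] == WHITE and visit(p):
                return True
        color[t] = BLACK
        return False

    return any(color[t] == WHITE and visit(t) for t in parents)


def brute_mica(parents: dict[str, set[str]], ic: dict[str, float],
               t1: str, t2: str) -> tuple[str, float]:
    """Exhaustive common-ancestor enumeration; ties to the smallest id."""
    common = brute_ancestors(parents, t1) & brute_ancestors(parents, t2)
    common = [t for t in common if t in ic]
    assert common, "no scored common ancestor"
    best = sorted(common, key=lambda t: (-ic[t], t))[0]
    return best, ic[best]


def brute_similarity(set_a, set_b, parents, ic, symmetrize="mean") -> float:
    """Double-loop best-match similarity over all term pairs."""
    if not set_a or not set_b:
        return 0.0

    def direction(src, dst):
        total = 0.0
        for a in src:
            total += max(brute_mica(parents, ic, a, b)[1] for b in dst)
        return total

    s = direction(set_a, set_b) + direction(set_b, set_a)
    return s / 2 if symmetrize == "mean" else s


def fisher_p_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive tail summation over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def bh_stepup(pvals: list[float], q: float) -> list[bool]:
    """Hand-rolled Benjamini–Hochberg step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            k_max = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            reject[i] = True
    return reject


def auc_concordance(scores, labels) -> float:
    """AUC as the exhaustive pairwise concordance fraction (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
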