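"""Exact genotype–phenotype association testing with FDR control.

Each phenotype term is tested with a two-sided Fisher exact test on the 2×2
table of carriers/non-carriers inside and outside a genotype group (e.g.
protein-truncating versus missense variants).  The odds ratio is reported as
the conditional maximum-likelihood estimate with an exact 95% confidence
interval, matching the convention of exact tests: a zero cell yields a point
estimate of 0 or +inf with one finite bound.  Multiple testing is controlled
per analysis with the Benjamini–Hochberg step-up at FDR q (default 10%).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FisherResult",
    "fisher_2x2",
    "bh_fdr",
    "associate",
    "location_associations",
]


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test result for one 2×2 table.

    ``odds_ratio`` is the conditional MLE; ``sample_or`` is the ordinary
    cross-product ratio ad/bc, reported for transparency.
    """

    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    sample_or: float


def fisher_2x2(a: int, b: int, c: int, d: int, *, alpha: float = 0.05,
               ci: bool = True) -> FisherResult:
    """Exact test on the table [[a, b], [c, d]].

    The two-sided p-value sums hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.  With
    ``ci=True`` the conditional-MLE odds ratio and its exact (1-alpha) CI are
    computed; otherwise they are NaN (the p-value alone is much cheaper).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d < 1:
        raise ValueError("empty table")
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        sample = np.float64(a) * d / (np.float64(b) * c)
    if np.isnan(sample):  # 0/0: degenerate margin
        sample = np.nan
    if not ci:
        return FisherResult(p, np.nan, np.nan, np.nan, float(sample))
    res = stats.contingency.odds_ratio(table, kind="conditional")
    interval = res.confidence_interval(confidence_level=1 - alpha)
    point = float(res.statistic)
    # zero-margin cells: conditional MLE degenerates to 0 or +inf
    if b == 0 or c == 0:
        if a > 0 and d > 0:
            point = np.inf
    elif a == 0 or d == 0:
        point = 0.0
    return FisherResult(p, point, float(interval.low), float(interval.high), float(sample))


def bh_fdr(pvals, q: float = 0.10) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at FDR level *q*.

    Flags are invariant to the input order; an empty input yields an empty
    flag array.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _group_mask(matrix: pd.DataFrame, group) -> np.ndarray:
    if isinstance(group, pd.Series):
        g = group.reindex(matrix.index)
        if g.isna().any():
            raise ValueError("group indicator missing for some individuals")
        return g.to_numpy(dtype=bool)
    if isinstance(group, (set, frozenset, list, tuple)) and not isinstance(group, np.ndarray):
        members = set(group)
        unknown = members - set(matrix.index)
        if unknown:
            raise ValueError(f"group members not in matrix: {sorted(unknown)[:5]}")
        return matrix.index.isin(members)
    g = np.asarray(group, dtype=bool)
    if g.shape != (len(matrix),):
        raise ValueError("group indicator length mismatch")
    return g


def associate(
    matrix: pd.DataFrame,
    group,
    q: float = 0.10,
    ci: bool = True,
    analysis: str = "",
) -> pd.DataFrame:
    """Term-wise Fisher association of a binary phenotype matrix with a group.

    Parameters
    ----------
    matrix:
        Individuals × terms boolean DataFrame (propagated positive terms plus
        pruned negative ``NP:`` columns, from
        :func:`scn2a_pheno.harmonize.build_phenotype_matrix`).
    group:
        Boolean indicator aligned with ``matrix.index``, or a collection of
        member ids.  Both the group and its complement must be non-empty.
    q:
        BH-FDR level applied across all terms of this analysis.
    ci:
        Compute exact conditional CIs per term (slower); the p-values and
        significance flags do not depend on this.

    Returns
    -------
    One row per term: counts, frequencies in/out of the group, p, odds ratio
    with CI, enrichment direction, and the BH significance flag.
    """
    g = _group_mask(matrix, group)
    n_in, n_out = int(g.sum()), int((~g).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError(f"both groups must be non-empty (got {n_in} vs {n_out})")
    X = matrix.to_numpy(dtype=bool)
    a_vec = X[g].sum(axis=0)
    c_vec = X[~g].sum(axis=0)
    rows = []
    for j, term in enumerate(matrix.columns):
        a, c = int(a_vec[j]), int(c_vec[j])
        res = fisher_2x2(a, n_in - a, c, n_out - c, ci=ci)
        rows.append(
            (term, "negative" if term.startswith("NP:") else "positive",
             a, n_in - a, c, n_out - c, a / n_in, c / n_out,
             res.p, res.odds_ratio, res.ci_low, res.ci_high, res.sample_or)
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "polarity", "a", "b", "c", "d",
                 "freq_in_group", "freq_out_group", "p",
                 "odds_ratio", "ci_low", "ci_high", "sample_or"],
    )
    out["direction"] = np.where(out["freq_in_group"] >= out["freq_out_group"],
                                "group_enriched", "group_depleted")
    out["significant"] = bh_fdr(out["p"].to_numpy(), q) if len(out) else []
    if analysis:
        out.insert(0, "analysis", analysis)
    return out


def location_associations(
    groups: Mapping[str, Collection[str]],
    matrix: pd.DataFrame,
    q: float = 0.10,
    ci: bool = False,
) -> pd.DataFrame:
    """Term associations for each variant location, FDR-pooled across locations.

    *matrix* must already be restricted to missense carriers (location analyses
    exclude other variant classes); *groups* maps a location label (domain,
    segment class, or the pore-loop flag) to the ids of missense carriers at
    that location, each tested against all other missense carriers.  BH runs
    once over the full location × term family.  Locations with no members (or
    no complement) are skipped with a log notice.
    """
    frames = []
    for label in sorted(groups):
        members = set(groups[label]) & set(matrix.index)
        if not members or len(members) == len(matrix):
            logger.info("location %r skipped (%d of %d members)",
                        label, len(members), len(matrix))
            continue
        res = associate(matrix, members, q=q, ci=ci, analysis=label)
        res = res.rename(columns={"analysis": "location"})
        frames.append(res)
    if not frames:
        raise ValueError("no testable locations")
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out
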