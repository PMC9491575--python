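"""Direction-stratified over-representation analysis of annotation categories.

Per category a 2×2 table (in-category × differential) is tested one-sided
(enrichment) with Fisher's exact test; q-values are BH-adjusted within a
category family and direction, mirroring how families of signaling,
metabolic and gene-class categories form separate panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnnotationCatalog
from .diffexpr import de_overlaps
from .stats_core import bh_adjust


@dataclass
class EnrichmentResult:
    category: str
    direction: str
    count: int          # category ∩ DE
    category_size: int  # category ∩ background
    de_size: int
    background_size: int
    odds_ratio: float
    p: float
    q: float | None = None


def _fisher_enrichment_p(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """One-sided (over-representation) Fisher p and odds ratio for a 2×2
    table with k of n DE genes in a category of size K over N genes."""
    # hypergeometric tail P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b = k, K - k
    c, d = n - k, N - K - (n - k)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return min(p, 1.0), odds


def enrich(de_set: set, direction: str, catalog: AnnotationCatalog,
           background: set, two_sided: bool = False) -> list[EnrichmentResult]:
    """Test every catalog category for over-representation of ``de_set``.

    Category members are intersected with the background first; a category
    with empty intersection is reported with p = 1.  q-values are assigned
    per family across its categories (same direction).
    """
    if not background:
        raise ValueError("background gene set is empty")
    de = set(de_set) & set(background)
    if de_set - set(background):
        raise ValueError("de_set must be a subset of the background")
    N, n = len(background), len(de)
    results: list[EnrichmentResult] = []
    for name, genes in catalog.sets.items():
        cat = set(genes) & set(background)
        K = len(cat)
        k = len(cat & de)
        if K == 0:
            p, odds = 1.0, np.nan
        elif two_sided:
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            _, odds = _fisher_enrichment_p(k, K, n, N)
        else:
            p, odds = _fisher_enrichment_p(k, K, n, N)
        results.append(EnrichmentResult(
            category=name, direction=direction, count=k, category_size=K,
            de_size=n, background_size=N, odds_ratio=odds, p=p,
        ))
    # BH within each family
    by_family: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        by_family.setdefault(catalog.family(r.category), []).append(i)
    for idxs in by_family.values():
        qs = bh_adjust([results[i].p for i in idxs])
        for i, q in zip(idxs, qs):
            results[i].q = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def pathway_overlap_report(de_sets_by_subgroup: dict[str, set],
                           catalog: AnnotationCatalog) -> pd.DataFrame:
    """Per category, the 7 disjoint Venn region counts of the three
    subgroups' differential members of that category."""
    names = list(de_sets_by_subgroup)
    if len(names) != 3:
        raise ValueError("expects exactly three subgroup DE sets")
    rows = []
    for cat, genes in catalog.sets.items():
        parts = [de_sets_by_subgroup[n] & genes for n in names]
        counts = de_overlaps(*parts, names=tuple(names))
        counts["category"] = cat
        rows.append(counts)
    return pd.DataFrame(rows).set_index("category")
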