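"""Gene-list overlap testing and generic category enrichment.

Overlaps between two gene lists drawn from a common population (by default
the 18,011 unique genes detected on the array) are tested with Fisher's
exact test; enrichment of annotation categories (up to three nesting
levels, nested Cat1/Cat2/Cat3 labels) uses one-sided hypergeometric tests
with Bonferroni correction within each level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["OverlapResult", "fisher_overlap", "category_enrichment"]


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_ab: int
    population: int
    p: float
    odds_ratio: float
    significant: bool
    alternative: str


def fisher_overlap(
    n_a: int,
    n_b: int,
    n_ab: int,
    population: int,
    alternative: str = "greater",
    alpha: float = 0.001,
) -> OverlapResult:
    """Fisher's exact test for the overlap of two gene lists.

    The 2x2 table is (in-A, not-in-A) x (in-B, not-in-B) over ``population``
    genes.  ``alternative='greater'`` gives the exact hypergeometric upper
    tail P(X >= n_ab); the odds ratio uses the sample (cross-product)
    convention.  ``significant`` is p < alpha.
    """
    if not (0 <= n_ab <= min(n_a, n_b)):
        raise DataError("need 0 <= n_ab <= min(n_a, n_b)")
    if max(n_a, n_b) > population:
        raise DataError("list sizes exceed the population size")
    if n_a + n_b - n_ab > population:
        raise DataError("union of the lists exceeds the population size")
    table = np.array(
        [
            [n_ab, n_a - n_ab],
            [n_b - n_ab, population - n_a - n_b + n_ab],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_ab=n_ab,
        population=population,
        p=float(p),
        odds_ratio=float(odds),
        significant=bool(p < alpha),
        alternative=alternative,
    )


def category_enrichment(
    genes: Iterable[str],
    annotation: pd.DataFrame,
    population: int | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Category enrichment of a gene list against a nested annotation table.

    ``annotation`` has one row per gene with columns ``gene``, ``cat1`` and
    optionally ``cat2``, ``cat3`` (deeper labels may be missing).  Categories
    at level k are identified by the joined path ``cat1: ...: catk``.  Per
    level, each category is tested with the one-sided hypergeometric upper
    tail and Bonferroni-corrected by the number of categories tested at that
    level (clamped to 1).  Returns the categories with corrected p <= alpha,
    Table-style: level, category, count, expected, p, bonferroni_fdr, genes.
    """
    if "gene" not in annotation.columns or "cat1" not in annotation.columns:
        raise DataError("annotation needs at least columns 'gene' and 'cat1'")
    ann = annotation.set_index("gene")
    gene_list = sorted(set(genes))
    known = [g for g in gene_list if g in ann.index]
    missing = set(gene_list) - set(known)
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from the annotation; counted in "
            "the population only",
            stacklevel=2,
        )
    if population is None:
        population = len(ann)
    n_list = len(gene_list)

    rows = []
    levels = [c for c in ("cat1", "cat2", "cat3") if c in ann.columns]
    for depth, _ in enumerate(levels, start=1):
        cols = levels[:depth]
        paths = ann[cols].apply(
            lambda r: ": ".join(str(v) for v in r if pd.notna(v)), axis=1
        )
        full = paths[ann[cols[-1]].notna()] if depth > 1 else paths
        pop_counts = full.groupby(full).size()
        hit_counts = full.loc[full.index.intersection(known)].groupby(
            full.loc[full.index.intersection(known)]
        ).size()
        n_tested = len(pop_counts)
        for cat, big_k in pop_counts.items():
            k = int(hit_counts.get(cat, 0))
            if k == 0:
                continue
            p = float(stats.hypergeom.sf(k - 1, population, int(big_k), n_list))
            corrected = min(1.0, p * max(n_tested, 1))
            if corrected <= alpha:
                members = sorted(
                    set(full.index[full == cat]) & set(known)
                )
                rows.append(
                    {
                        "level": depth,
                        "category": cat,
                        "count": k,
                        "category_size": int(big_k),
                        "expected": n_list * int(big_k) / population,
                        "p": p,
                        "bonferroni_fdr": corrected,
                        "genes": ", ".join(members),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "category",
            "count",
            "category_size",
            "expected",
            "p",
            "bonferroni_fdr",
            "genes",
        ],
    )
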