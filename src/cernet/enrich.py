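"""Hypergeometric gene-set enrichment with Bonferroni control.

Hub sub-network genes (protein-coding by default) are tested against GMT
collections: for each set, the overlap with the query follows a
hypergeometric distribution over the chosen gene universe, and the
upper-tail p is Bonferroni adjusted within each category (HALLMARK, GO_BP,
KEGG, CGP are corrected separately, mirroring how per-category result tables
are usually reported).
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .cerna import hypergeom_shared
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["enrich"]

ENRICH_COLUMNS = [
    "category",
    "set_name",
    "overlap",
    "query_size",
    "set_size",
    "universe_size",
    "p",
    "fdr",
    "significant",
]


def enrich(
    query_genes: Iterable,
    collection: GeneSetCollection,
    universe_genes: Iterable,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test ``query_genes`` against every set of ``collection``.

    ``p = P(X >= overlap)`` with ``X ~ Hypergeometric(|universe|,
    |set & universe|, |query|)``.  Sets are intersected with the universe
    first; sets with an empty intersection are skipped and logged.  The
    Bonferroni factor is the number of sets actually tested within the
    category.  Rows are sorted by adjusted p (ties by name).
    """
    universe = frozenset(universe_genes)
    query = frozenset(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    rows = []
    for category in collection.categories():
        tested = []
        for name in sorted(collection.sets[category]):
            members = collection.sets[category][name] & universe
            if not members:
                logger.info("set %s/%s has no gene in the universe; skipped", category, name)
                continue
            tested.append((name, members))
        m = len(tested)
        for name, members in tested:
            overlap = len(query & members)
            p = hypergeom_shared(len(universe), len(members), len(query), overlap)
            adj = min(1.0, p * m)
            rows.append(
                {
                    "category": category,
                    "set_name": name,
                    "overlap": overlap,
                    "query_size": len(query),
                    "set_size": len(members),
                    "universe_size": len(universe),
                    "p": p,
                    "fdr": adj,
                    "significant": adj < fdr,
                }
            )
    table = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    return table.sort_values(["fdr", "category", "set_name"], kind="mergesort").reset_index(drop=True)
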