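"""Hypergeometric over-representation analysis against any GMT catalog.

One engine serves GO/KEGG-style functional enrichment and regulon (TF
target) enrichment alike: the catalog is whatever the user supplies. The
universe should be the analyzed transcriptome (genes surviving the
low-expression filter), not the whole genome.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .data_io import GeneSetCatalog
from .stats import adjust_bh, hypergeom_tail

log = logging.getLogger(__name__)


def ora(
    query: Iterable[str],
    catalog: GeneSetCatalog,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each catalog set.

    Query genes outside the universe are dropped (count logged); catalog
    sets are intersected with the universe and skipped when empty. Returns
    a table sorted by p with BH-adjusted p across the tested sets.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    outside = query - universe
    if outside:
        log.info("ora: dropped %d query genes outside the universe", len(outside))
    query = query & universe
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in catalog.sets.items():
        in_univ = genes & universe
        if not in_univ:
            continue
        overlap = sorted(in_univ & query)
        k, K = len(overlap), len(in_univ)
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_tail(k, K, n, N), "genes": ",".join(overlap)}
        )
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "genes"])
    if len(table):
        table["padj"] = adjust_bh(table["p"].to_numpy())
        table["significant"] = table["padj"] < alpha
        table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        table["padj"] = np.array([], dtype=float)
        table["significant"] = np.array([], dtype=bool)
    return table
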