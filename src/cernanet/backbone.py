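"""miRNA target-site-share backbone network.

Two genes are connected in the backbone when they share significantly more
miRNAs (by target-site presence on their 3'-UTRs) than expected under a
hypergeometric null over the miRNA universe.  The backbone is built once from
the target-site table and is shared by every condition-specific ceRNA network;
co-expression thresholding happens downstream.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TargetSiteTable", "mirna_set", "overlap_pvalue", "build_backbone"]


class TargetSiteTable:
    """Gene x miRNA table of non-negative target-site counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per miRNA; integer
        site counts, no negatives, no duplicated gene or miRNA ids.
    universe
        Ordered miRNA universe for the hypergeometric test.  Defaults to the
        miRNAs present in ``counts``; may be a superset (e.g. all curated
        miRNAs rather than the expressed ones).
    """

    def __init__(self, counts: pd.DataFrame, universe: Optional[Iterable[str]] = None):
        if counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in target-site table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate miRNA ids in target-site table")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative site counts")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("site counts must be integers")
        self.counts = counts.astype(int)
        if universe is None:
            universe = list(counts.columns)
        else:
            universe = list(universe)
            missing = set(counts.columns) - set(universe)
            if missing:
                raise ValueError(f"universe is missing referenced miRNAs: {sorted(missing)[:5]}")
        if len(universe) != len(set(universe)):
            raise ValueError("duplicate miRNA ids in universe")
        self.universe = universe

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def total_sites(self) -> pd.Series:
        """Total site count per gene (the sponge-potential filter quantity)."""
        return self.counts.sum(axis=1)

    def mirna_set(self, gene: str) -> frozenset[str]:
        return mirna_set(self, gene)

    def restrict_genes(self, genes: Iterable[str]) -> "TargetSiteTable":
        keep = [g for g in self.counts.index if g in set(genes)]
        return TargetSiteTable(self.counts.loc[keep], universe=self.universe)


def mirna_set(table: TargetSiteTable, gene: str) -> frozenset[str]:
    """miRNAs with at least one site on ``gene``."""
    if gene not in table.counts.index:
        raise KeyError(f"unknown gene: {gene}")
    row = table.counts.loc[gene]
    return frozenset(row.index[row > 0])


def overlap_pvalue(set_a: frozenset, set_b: frozenset, universe_size: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= |A ∩ B|) where X counts how many of the |B| drawn miRNAs fall in A,
    drawing without replacement from a universe of ``universe_size``.
    Symmetric in the two sets.
    """
    a, b = len(set_a), len(set_b)
    if universe_size < max(a, b):
        raise ValueError("universe smaller than one of the sets")
    k = len(set_a & set_b)
    # sf(k-1) = P(X >= k); P(X >= 0) = 1 by construction
    return float(stats.hypergeom.sf(k - 1, universe_size, a, b))


def build_backbone(
    table: TargetSiteTable,
    min_sites: int = 6,
    q_threshold: float = 0.05,
) -> nx.Graph:
    """Build the target-site-share backbone.

    Restricts to genes with total site count >= ``min_sites`` (possible
    sponges), tests every unordered pair with the upper-tail hypergeometric
    overlap test, Benjamini-Hochberg adjusts across all tested pairs, and
    keeps pairs with q < ``q_threshold``.

    Returns a simple undirected :class:`networkx.Graph` whose nodes are the
    qualifying genes and whose edges carry ``p`` and ``q``.
    """
    if min_sites < 0:
        raise ValueError("min_sites must be >= 0")
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must be in (0, 1]")
    if table.counts.empty:
        raise ValueError("empty target-site table")

    totals = table.total_sites()
    genes = sorted(totals.index[totals >= min_sites])
    graph = nx.Graph(min_sites=min_sites, q_threshold=q_threshold, universe_size=table.universe_size)
    graph.add_nodes_from(genes)
    if len(genes) < 2:
        return graph

    presence = (table.counts.loc[genes].to_numpy() > 0)
    sizes = presence.sum(axis=1)
    overlap = presence.astype(np.int64) @ presence.T.astype(np.int64)
    iu, ju = np.triu_indices(len(genes), k=1)
    pvals = stats.hypergeom.sf(overlap[iu, ju] - 1, table.universe_size, sizes[iu], sizes[ju])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    keep = qvals < q_threshold
    for i, j, p, q in zip(iu[keep], ju[keep], pvals[keep], qvals[keep]):
        graph.add_edge(genes[i], genes[j], p=float(p), q=float(q))
    return graph
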