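"""Downstream subtype-comparison statistics.

Everything that sits on top of the calibrated ceRNA networks: recurrent APA
calls, 3'US ceRNA partners, housekeeping-sponge subnetwork similarity against
matched random null subnetworks, degree-retention and fold-change summaries,
gene-set overlap significance, generic over-representation, and the
subsampling experiment that demonstrates edge-count inflation at small sample
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .backbone import overlap_pvalue
from .cerna import ExpressionMatrix, build_cerna_network, edge_correlations
from .spectral import ks_similarity

__all__ = [
    "SubnetworkComparison",
    "SubsampleResult",
    "recurrent_apa",
    "cerna_partners",
    "edge_subnetwork",
    "matched_null_similarity",
    "degree_ratio",
    "log2_fold_change",
    "group_difference_test",
    "set_overlap_significance",
    "overrepresentation",
    "classify_network_genes",
    "subsample_experiment",
    "expression_variability",
]


@dataclass
class SubnetworkComparison:
    """Focal-subnetwork similarity against matched random subnetworks.

    ``empirical_p`` uses the add-one permutation estimator
    (1 + #{null p >= focal p}) / (reps + 1), so it is never zero.
    """

    focal_statistic: float
    focal_p: float
    null_ps: np.ndarray
    empirical_p: float


@dataclass
class SubsampleResult:
    """Edge counts and per-edge occurrence over repeated subsampling."""

    edge_counts: pd.DataFrame  # columns: size, rep, n_edges
    occurrence: dict[int, pd.Series]  # size -> edge ("a|b") -> count over reps


def recurrent_apa(
    calls: pd.DataFrame,
    samples: Sequence[str],
    kind: str,
    fraction: float = 0.2,
) -> set[str]:
    """Genes with an APA call of ``kind`` in strictly more than ``fraction``
    of ``samples``.

    ``calls`` is tidy with columns sample, gene, event (e.g. "3US"/"3UL").
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if len(samples) == 0:
        raise ValueError("no samples")
    sub = calls[(calls["event"] == kind) & calls["sample"].isin(set(samples))]
    if sub.empty:
        return set()
    freq = sub.groupby("gene")["sample"].nunique() / len(samples)
    return set(freq.index[freq > fraction])


def cerna_partners(network: nx.Graph, seed_genes: Iterable[str]) -> set[str]:
    """Union of the neighbors of ``seed_genes``, minus the seeds."""
    seeds = set(seed_genes)
    out: set[str] = set()
    for g in seeds:
        if g in network:
            out.update(network.neighbors(g))
    return out - seeds


def edge_subnetwork(network: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph of edges with at least one endpoint in ``genes``."""
    focal = set(genes)
    sub = nx.Graph(**network.graph)
    for u, v, data in network.edges(data=True):
        if u in focal or v in focal:
            sub.add_edge(u, v, **data)
    return sub


def _edges_sorted(network: nx.Graph) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in network.edges)


def matched_null_similarity(
    net_a: nx.Graph,
    net_b: nx.Graph,
    focal_genes: Iterable[str],
    reps: int = 200,
    seed: int = 0,
) -> SubnetworkComparison:
    """Compare focal-gene edge subnetworks across conditions against a
    matched random-edge null.

    The focal subnetworks (edges touching ``focal_genes``) of the two
    networks are compared with the KS spectral similarity.  For each of
    ``reps`` repetitions, the same number of edges is drawn (without
    replacement, per network) from the edges touching no focal gene, and the
    two random subnetworks are compared the same way; ``empirical_p``
    summarizes how exceptional the focal similarity is among the nulls.
    """
    focal = set(focal_genes)
    if not focal:
        raise ValueError("focal_genes must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    focal_subs, null_pools, n_focal = [], [], []
    for net in (net_a, net_b):
        fsub = edge_subnetwork(net, focal)
        if fsub.number_of_edges() == 0:
            raise ValueError("a focal subnetwork has no edges")
        pool = [e for e in _edges_sorted(net) if e[0] not in focal and e[1] not in focal]
        if len(pool) < fsub.number_of_edges():
            raise ValueError("insufficient non-focal edges for matched nulls")
        focal_subs.append(fsub)
        null_pools.append(pool)
        n_focal.append(fsub.number_of_edges())

    focal_sim = ks_similarity(*focal_subs)
    rng = np.random.default_rng(seed)
    null_ps = np.empty(reps)
    for r in range(reps):
        subs = []
        for pool, k, net in zip(null_pools, n_focal, (net_a, net_b)):
            take = rng.choice(len(pool), size=k, replace=False)
            g = nx.Graph()
            for i in sorted(take):
                u, v = pool[i]
                g.add_edge(u, v, **net.edges[u, v])
            subs.append(g)
        null_ps[r] = ks_similarity(*subs).p_value
    empirical_p = (1.0 + float(np.sum(null_ps >= focal_sim.p_value))) / (reps + 1.0)
    return SubnetworkComparison(
        focal_statistic=focal_sim.ks_statistic,
        focal_p=focal_sim.p_value,
        null_ps=null_ps,
        empirical_p=empirical_p,
    )


def degree_ratio(normal_net: nx.Graph, tumor_net: nx.Graph, gene: str) -> float:
    """Fraction of a gene's normal-network neighbors retained in the tumor
    network.  Tumor-only gains are ignored."""
    if gene not in normal_net or normal_net.degree(gene) == 0:
        raise ValueError(f"{gene} has no neighbors in the normal network")
    normal_nb = set(normal_net.neighbors(gene))
    tumor_nb = set(tumor_net.neighbors(gene)) if gene in tumor_net else set()
    return len(normal_nb & tumor_nb) / len(normal_nb)


def log2_fold_change(
    tumor_vals: np.ndarray, normal_vals: np.ndarray, pseudocount: float = 1.0
) -> float:
    """log2((mean tumor + pc) / (mean normal + pc))."""
    tumor_vals = np.asarray(tumor_vals, dtype=float)
    normal_vals = np.asarray(normal_vals, dtype=float)
    if tumor_vals.size == 0 or normal_vals.size == 0:
        raise ValueError("empty input vector")
    if (tumor_vals < 0).any() or (normal_vals < 0).any():
        raise ValueError("negative expression values")
    return float(
        np.log2((tumor_vals.mean() + pseudocount) / (normal_vals.mean() + pseudocount))
    )


def group_difference_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Uses the exact null distribution when both samples are small and
    tie-free, the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied: rank-sum test degenerate")
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and min(a.size, b.size) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def set_overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p of the overlap of two gene sets."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be contained in the universe")
    return overlap_pvalue(frozenset(a), frozenset(b), len(u))


def overrepresentation(
    genes: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Generic hypergeometric over-representation of a gene set in a
    collection (e.g. GMT pathway sets), BH-adjusted across the collection."""
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    if not collection:
        raise ValueError("empty collection")
    query = set(genes) & u
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & u
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, len(u), len(members), len(query)))
        rows.append((name, len(members), k, p))
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def classify_network_genes(
    backbone: nx.Graph,
    apa_genes: Iterable[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Label every network gene as a 3'US gene, a 3'US ceRNA partner, or
    unconnected to 3'US, carrying the HK/TA/TF flags along.

    Intended for backbone-only ceRNA mode (target-share significance alone,
    no correlation filter), as when replicates are too few for co-expression.
    """
    apa = set(apa_genes)
    partners = cerna_partners(backbone, apa)
    rows = []
    for g in sorted(backbone.nodes):
        if g in apa:
            cat = "3US"
        elif g in partners:
            cat = "3US_partner"
        else:
            cat = "unconnected"
        flags = annotation.loc[g] if g in annotation.index else None
        rows.append(
            (
                g,
                cat,
                bool(flags["HK"]) if flags is not None else False,
                bool(flags["TA"]) if flags is not None else False,
                bool(flags["TF"]) if flags is not None else False,
            )
        )
    return pd.DataFrame(rows, columns=["gene", "category", "HK", "TA", "TF"]).set_index("gene")


def subsample_experiment(
    matrix: ExpressionMatrix,
    backbone: nx.Graph,
    sizes: Sequence[int],
    cutoff: float,
    reps: int = 100,
    seed: int = 0,
    log_transform: bool = True,
) -> SubsampleResult:
    """Edge-count inflation under repeated subsampling.

    For each subsample size, draws ``reps`` sample subsets (without
    replacement), builds the ceRNA network at the fixed ``cutoff``, and
    records the edge count plus, per edge, how many of the ``reps`` networks
    contain it.
    """
    n = matrix.n_samples
    if any(s < 3 for s in sizes):
        raise ValueError("subsample sizes must be >= 3")
    if max(sizes) > n:
        raise ValueError("subsample size exceeds sample count")
    rng = np.random.default_rng(seed)
    counts_rows = []
    occurrence: dict[int, pd.Series] = {}
    samples = matrix.samples
    for size in sizes:
        occ: dict[str, int] = {}
        for rep in range(reps):
            take = rng.choice(n, size=size, replace=False)
            sub = matrix.subset_samples([samples[i] for i in sorted(take)])
            corr = edge_correlations(sub, backbone, log_transform=log_transform)
            net = build_cerna_network(sub, backbone, cutoff, correlations=corr)
            counts_rows.append((size, rep, net.number_of_edges()))
            for a, b in _edges_sorted(net):
                key = f"{a}|{b}"
                occ[key] = occ.get(key, 0) + 1
        occurrence[size] = pd.Series(occ, dtype=int).sort_index()
    edge_counts = pd.DataFrame(counts_rows, columns=["size", "rep", "n_edges"])
    return SubsampleResult(edge_counts=edge_counts, occurrence=occurrence)


def expression_variability(
    matrix: ExpressionMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> tuple[pd.Series, pd.Series, float]:
    """Per-gene SD across samples for two gene groups, plus the rank-sum p
    comparing the two SD vectors."""
    ga, gb = sorted(set(group_a)), sorted(set(group_b))
    if not ga or not gb:
        raise ValueError("gene groups must be non-empty")
    missing = [g for g in ga + gb if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sd_a = matrix.values.loc[ga].std(axis=1, ddof=1)
    sd_b = matrix.values.loc[gb].std(axis=1, ddof=1)
    return sd_a, sd_b, group_difference_test(sd_a.to_numpy(), sd_b.to_numpy())
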