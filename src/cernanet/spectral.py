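"""Spectral comparison of networks and correlation-cutoff calibration.

Networks built from different numbers of samples are not directly comparable:
the smaller group's network is inflated at any fixed correlation cutoff.  The
calibration here compares the small group's network, across a grid of cutoffs,
to a reference network via the eigenvalue distribution of the normalized
Laplacian, scored with a two-sample Kolmogorov-Smirnov test: the cutoff whose
network is most similar to the reference (highest KS p-value) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cerna import ExpressionMatrix, build_cerna_network, edge_correlations

__all__ = [
    "SpectralSimilarity",
    "CalibrationResult",
    "normalized_laplacian",
    "eigenvalue_distribution",
    "network_spectrum",
    "ks_similarity",
    "average_clustering",
    "calibrate_cutoff",
]

_SYM_TOL = 1e-8


@dataclass
class SpectralSimilarity:
    """KS comparison of two normalized-Laplacian spectra.

    ``ks_statistic`` is the sup-distance of the two empirical eigenvalue
    CDFs; higher ``p_value`` means more similar topology.
    """

    ks_statistic: float
    p_value: float
    eigenvalues_a: np.ndarray
    eigenvalues_b: np.ndarray


@dataclass
class CalibrationResult:
    """Cutoff grid with per-cutoff similarity and the selected cutoff.

    ``grid`` columns: cutoff, ks_statistic, p_value, n_edges, n_nodes,
    avg_clustering.  The selection rule (max p, ties by clustering
    coefficient closest to the reference's, then the smaller cutoff) is
    reproducible from the stored grid plus ``reference_clustering``.
    """

    grid: pd.DataFrame
    selected_cutoff: float
    reference_clustering: float


def normalized_laplacian(network: nx.Graph) -> np.ndarray:
    """Normalized Laplacian N = D^{-1/2} L D^{-1/2} over non-isolated nodes.

    Entries: 1 on the diagonal, -1/sqrt(deg_i * deg_j) for adjacent pairs,
    0 otherwise.  Isolated nodes are dropped (their all-zero rows would pad
    the spectrum with bookkeeping-dependent zeros).  Node order is
    lexicographic.
    """
    nodes = sorted(n for n in network.nodes if network.degree(n) > 0)
    if not nodes:
        raise ValueError("network has no edges")
    idx = {n: i for i, n in enumerate(nodes)}
    deg = np.array([network.degree(n) for n in nodes], dtype=float)
    mat = np.eye(len(nodes))
    for u, v in network.edges:
        if u == v:
            continue
        i, j = idx[u], idx[v]
        val = -1.0 / np.sqrt(deg[i] * deg[j])
        mat[i, j] = val
        mat[j, i] = val
    return mat


def eigenvalue_distribution(matrix: np.ndarray) -> np.ndarray:
    """All eigenvalues of a symmetric matrix, ascending, clipped to [0, 2]."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=_SYM_TOL):
        raise ValueError("matrix is not symmetric within tolerance")
    ev = np.linalg.eigvalsh(matrix)
    if ev.size and (ev.min() < -_SYM_TOL * ev.size or ev.max() > 2 + _SYM_TOL * ev.size):
        raise ValueError("eigenvalues outside [0, 2] beyond tolerance")
    return np.sort(np.clip(ev, 0.0, 2.0))


def network_spectrum(network: nx.Graph) -> np.ndarray:
    """Normalized-Laplacian eigenvalue distribution of a network."""
    return eigenvalue_distribution(normalized_laplacian(network))


def _ks(ev_a: np.ndarray, ev_b: np.ndarray) -> tuple[float, float]:
    res = stats.ks_2samp(ev_a, ev_b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_similarity(net_a: nx.Graph, net_b: nx.Graph) -> SpectralSimilarity:
    """Two-sample two-sided KS test between two networks' spectra.

    Identical networks give statistic 0 and p = 1; the higher the p-value,
    the more similar the topologies.  Uses the asymptotic p approximation.
    """
    ev_a = network_spectrum(net_a)
    ev_b = network_spectrum(net_b)
    stat, p = _ks(ev_a, ev_b)
    return SpectralSimilarity(stat, p, ev_a, ev_b)


def average_clustering(network: nx.Graph) -> float:
    """Mean local clustering coefficient (0 for degree < 2 nodes)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(network))


def calibrate_cutoff(
    reference: nx.Graph,
    target_expr: ExpressionMatrix,
    backbone: nx.Graph,
    step: float = 0.01,
    log_transform: bool = True,
    condition: Optional[str] = None,
) -> CalibrationResult:
    """Select the target group's cutoff by spectral similarity to a reference.

    Builds the target-condition network at every cutoff in {0, step, ..., 1},
    compares each to ``reference`` with :func:`ks_similarity`, and selects
    the cutoff with maximal p-value.  Ties are broken by average clustering
    coefficient closest to the reference's, then by the smaller cutoff.
    Cutoffs yielding an empty network get NaN similarity.
    """
    if step <= 0 or step > 1:
        raise ValueError("step must be in (0, 1]")
    ref_ev = network_spectrum(reference)
    ref_clust = average_clustering(reference)
    corr = edge_correlations(target_expr, backbone, log_transform=log_transform)

    rows = []
    n_steps = int(round(1.0 / step))
    for i in range(n_steps + 1):
        c = min(round(i * step, 10), 1.0)
        net = build_cerna_network(
            target_expr, backbone, c, condition=condition, correlations=corr
        )
        if net.number_of_edges() == 0:
            rows.append((c, np.nan, np.nan, 0, 0, np.nan))
            continue
        stat, p = _ks(ref_ev, network_spectrum(net))
        rows.append(
            (c, stat, p, net.number_of_edges(), net.number_of_nodes(), average_clustering(net))
        )
    grid = pd.DataFrame(
        rows,
        columns=["cutoff", "ks_statistic", "p_value", "n_edges", "n_nodes", "avg_clustering"],
    )
    if grid["p_value"].isna().all():
        raise ValueError("every grid cutoff yields an empty network")
    best_p = grid["p_value"].max()
    cand = grid[grid["p_value"] == best_p].copy()
    cand["clust_gap"] = (cand["avg_clustering"] - ref_clust).abs()
    cand = cand.sort_values(["clust_gap", "cutoff"], kind="mergesort")
    selected = float(cand.iloc[0]["cutoff"])
    return CalibrationResult(grid=grid, selected_cutoff=selected, reference_clustering=ref_clust)
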