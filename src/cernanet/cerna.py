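"""Condition-specific ceRNA networks.

A ceRNA edge is a backbone (target-share) edge whose two genes are also
positively co-expressed above a Pearson cutoff in the condition of interest.
This module holds the expression container, the FPM expression filter, the
t-based correlation significance machinery, the equal-significance cutoff
mapping between unequal sample sizes, and the network constructor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ConstantExpressionWarning",
    "filter_expressed",
    "pearson_with_pvalue",
    "correlation_pvalue",
    "equivalent_cutoff",
    "edge_correlations",
    "build_cerna_network",
]


class ConstantExpressionWarning(UserWarning):
    """A constant-expression gene was excluded before correlation."""


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression values (FPM scale).

    ``labels`` is indexed by sample id with columns ``group`` (subtype) and
    ``state`` (normal/tumor); it must cover exactly the sample columns.
    """

    values: pd.DataFrame
    labels: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.labels is None:
            self.labels = pd.DataFrame(
                {"group": "all", "state": "all"}, index=self.values.columns
            )
        if list(self.labels.index) != list(self.values.columns):
            raise ValueError("labels index must equal the sample columns")
        arr = self.values.to_numpy()
        if arr.size and np.isnan(arr).any():
            raise ValueError("missing expression values")
        if arr.size and (arr < 0).any():
            raise ValueError("negative expression values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.labels)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.labels.loc[list(samples)])

    def log2(self) -> pd.DataFrame:
        """log2(value + 1), the default scale for co-expression."""
        return np.log2(self.values + 1.0)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.labels.equals(other.labels)


def filter_expressed(
    matrix: ExpressionMatrix, min_value: float = 1.0, min_fraction: float = 0.8
) -> ExpressionMatrix:
    """Keep genes expressed >= ``min_value`` in strictly more than
    ``min_fraction`` of all samples (the FPM >= 1 in > 80% rule)."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    frac = (matrix.values >= min_value).mean(axis=1)
    return matrix.subset_genes(matrix.values.index[frac > min_fraction])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a sample Pearson r at sample size ``n``.

    Student's t with df = n - 2 and t = r * sqrt(df / (1 - r^2)); |r| = 1
    maps to p = 0.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not -1 <= r <= 1:
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_, ny_ = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx_ == 0 or ny_ == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.clip(np.dot(xc, yc) / (nx_ * ny_), -1.0, 1.0))
    return r, correlation_pvalue(r, n)


def equivalent_cutoff(
    r_ref: float, n_ref: int, n_target: int, step: float = 0.01
) -> float:
    """Smallest grid cutoff at ``n_target`` at least as significant as
    ``r_ref`` at ``n_ref``.

    Scans c in {0, step, ..., 1} and returns the smallest c whose two-tailed
    p at ``n_target`` is <= the two-tailed p of ``r_ref`` at ``n_ref``.  This
    is the sample-size mapping that sends the traditional 0.6 cutoff of a
    large group onto the inflated cutoff an equally-significant small group
    would need.
    """
    if not 0 < r_ref < 1:
        raise ValueError("r_ref must be in (0, 1)")
    if n_ref < 3 or n_target < 3:
        raise ValueError("sample sizes must be >= 3")
    if step <= 0:
        raise ValueError("step must be positive")
    p_ref = correlation_pvalue(r_ref, n_ref)
    n_steps = int(round(1.0 / step))
    for i in range(n_steps + 1):
        c = round(i * step, 10)
        c = min(c, 1.0)
        if correlation_pvalue(c, n_target) <= p_ref:
            if c == 1.0:
                warnings.warn("only the degenerate cutoff 1.0 qualifies")
            return c
    warnings.warn("no grid cutoff qualifies; returning 1.0")
    return 1.0


def edge_correlations(
    matrix: ExpressionMatrix, backbone: nx.Graph, log_transform: bool = True
) -> pd.DataFrame:
    """Pearson r for every backbone edge, computed in this condition.

    Correlations are computed on log2(value + 1) by default.  Edges touching
    a constant-expression gene are dropped with a warning.  Returns a
    DataFrame with columns gene_a, gene_b (lexicographic within pair), r, q.
    """
    missing = [g for g in backbone.nodes if g not in matrix.values.index]
    if any(backbone.degree(g) > 0 for g in missing):
        raise ValueError("backbone genes missing from the expression matrix")
    data = matrix.log2() if log_transform else matrix.values.astype(float)
    genes = [g for g in data.index]
    pos = {g: i for i, g in enumerate(genes)}
    arr = data.to_numpy()
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        bad = {genes[i] for i in np.flatnonzero(constant)}
        if any(g in bad for e in backbone.edges for g in e):
            warnings.warn(
                f"excluding {len(bad)} constant-expression gene(s) from correlation",
                ConstantExpressionWarning,
            )
    safe = np.where(constant, 1.0, norms)
    z = centered / safe[:, None]

    edges = sorted(tuple(sorted(e)) for e in backbone.edges)
    rows = []
    for a, b in edges:
        ia, ib = pos[a], pos[b]
        if constant[ia] or constant[ib]:
            continue
        r = float(np.clip(np.dot(z[ia], z[ib]), -1.0, 1.0))
        rows.append((a, b, r, backbone.edges[a, b].get("q", np.nan)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "q"])


def build_cerna_network(
    matrix: ExpressionMatrix,
    backbone: nx.Graph,
    cutoff: float,
    condition: Optional[str] = None,
    log_transform: bool = True,
    correlations: Optional[pd.DataFrame] = None,
) -> nx.Graph:
    """Threshold co-expression on the backbone to get a ceRNA network.

    Keeps backbone edges with Pearson r >= ``cutoff`` (positive co-expression
    only), and only nodes with at least one retained edge.  ``correlations``
    may carry a precomputed :func:`edge_correlations` table to avoid
    recomputation across a cutoff grid.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    if correlations is None:
        correlations = edge_correlations(matrix, backbone, log_transform=log_transform)
    net = nx.Graph(condition=condition, cutoff=float(cutoff))
    kept = correlations[correlations["r"] >= cutoff]
    for a, b, r, q in kept.itertuples(index=False):
        net.add_edge(a, b, r=float(r), q=float(q))
    return net
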