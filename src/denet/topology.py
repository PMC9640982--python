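"""Degree statistics, hubs, ECDF contrasts and degree-bias permutation tests.

The central question: do DE genes occupy different positions in the merged
pathway network than other genes?  Two permutation statistics address it —
the ECDF difference at a reference connectivity (default k = 25) and the
mean-degree difference — both against a null that re-draws the DE label
set uniformly among all network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pathways import BioNetwork
from .permutation import PermutationResult

__all__ = [
    "degrees",
    "hubs",
    "ecdf_at",
    "degree_bias_test",
    "mean_degree_test",
    "powerlaw_diagnostic",
    "PowerLawFit",
]

#: Hub definition: nodes with degree k >= 20.
DEFAULT_HUB_DEGREE = 20

#: Reference connectivity for the ECDF contrast.
DEFAULT_K_REF = 25


def degrees(net: BioNetwork) -> pd.Series:
    """Degree of every node, indexed by node name (sorted)."""
    deg = dict(net.graph.degree())
    return pd.Series(deg, name="degree").sort_index().astype(int)


def hubs(dt: pd.Series | BioNetwork, k_min: int = DEFAULT_HUB_DEGREE) -> set[str]:
    """Nodes with degree >= k_min (inclusive)."""
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    if isinstance(dt, BioNetwork):
        dt = degrees(dt)
    return set(dt.index[dt >= k_min])


def ecdf_at(values: Sequence[float], x: float) -> float:
    """Empirical CDF at x: the fraction of values <= x (weak inequality)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    return float((values <= x).mean())


def _node_arrays(net: BioNetwork, de_set: Iterable[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    nodes = sorted(net.graph.nodes)
    deg = np.array([net.graph.degree[n] for n in nodes], dtype=float)
    de = set(de_set)
    extra = de - set(nodes)
    if extra:
        raise ValueError(f"DE set contains node(s) absent from the network: {sorted(extra)[:5]}")
    mask = np.array([n in de for n in nodes], dtype=bool)
    return nodes, deg, mask


def _check_proper(mask: np.ndarray) -> None:
    n_de = int(mask.sum())
    if n_de == 0:
        raise ValueError("DE set is empty")
    if n_de == mask.size:
        raise ValueError("DE set equals the whole node set; the contrast is undefined")


def _uniform_subsets(rng: np.random.Generator, n: int, k: int, n_iter: int) -> np.ndarray:
    """n_iter uniform k-subsets of range(n), as an (n_iter, k) index array."""
    keys = rng.random((n_iter, n))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def degree_bias_test(
    net: BioNetwork,
    de_set: Iterable[str],
    k_ref: int = DEFAULT_K_REF,
    n_iter: int = 1000,
    seed: int | None = None,
    side: str = "greater",
) -> PermutationResult:
    """ECDF_DE(k_ref) - ECDF_nonDE(k_ref) against a uniform relabeling null.

    A positive statistic means DE genes are enriched at or below the
    reference connectivity, i.e. biased toward low-degree nodes.  One-sided
    "greater" by default.
    """
    _, deg, mask = _node_arrays(net, de_set)
    _check_proper(mask)
    n, n_de = deg.size, int(mask.sum())
    le = (deg <= k_ref).astype(float)
    total_le = le.sum()

    def stat(sum_le_de: np.ndarray) -> np.ndarray:
        return sum_le_de / n_de - (total_le - sum_le_de) / (n - n_de)

    observed = float(stat(np.array(le[mask].sum())))
    rng = np.random.default_rng(seed)
    idx = _uniform_subsets(rng, n, n_de, n_iter)
    null = stat(le[idx].sum(axis=1))
    return PermutationResult(f"ecdf_diff_at_k{k_ref}", observed, null, side, seed,
                             tie_u=float(rng.uniform()))


def mean_degree_test(
    net: BioNetwork,
    de_set: Iterable[str],
    n_iter: int = 1000,
    seed: int | None = None,
    side: str = "two-sided",
) -> PermutationResult:
    """Mean degree(DE) - mean degree(non-DE) against a uniform relabeling null."""
    _, deg, mask = _node_arrays(net, de_set)
    _check_proper(mask)
    n, n_de = deg.size, int(mask.sum())
    total = deg.sum()

    def stat(sum_de: np.ndarray) -> np.ndarray:
        return sum_de / n_de - (total - sum_de) / (n - n_de)

    observed = float(stat(np.array(deg[mask].sum())))
    rng = np.random.default_rng(seed)
    idx = _uniform_subsets(rng, n, n_de, n_iter)
    null = stat(deg[idx].sum(axis=1))
    return PermutationResult("mean_degree_diff", observed, null, side, seed,
                             tie_u=float(rng.uniform()))


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log10 frequency vs log10 degree (diagnostic only)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def powerlaw_diagnostic(dt: pd.Series, n_bins: int = 12) -> PowerLawFit:
    """Log-log slope of the logarithmically binned degree histogram.

    Scale-free networks show an approximately linear decay (negative
    slope).  This is a qualitative diagnostic, not a maximum-likelihood
    power-law fit.
    """
    deg = np.asarray(dt, dtype=float)
    deg = deg[deg > 0]
    if np.unique(deg).size < 3:
        raise ValueError("need at least 3 distinct positive degrees for the diagnostic")
    lo, hi = deg.min(), deg.max()
    bins = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    bins[-1] *= 1 + 1e-9  # include the max degree in the last bin
    counts, edges = np.histogram(deg, bins=bins)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / widths
    keep = density > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 populated bins; degree range too narrow")
    x = np.log10(centers[keep])
    y = np.log10(density[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(float(slope), float(intercept), r2, int(keep.sum()))
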