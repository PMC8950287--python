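"""Network-level structural metrics for quantitative bipartite networks.

Implements the standard descriptors of mutualistic network structure:

* connectance ``C = L / (R * A)`` — realized fraction of possible links;
* links per species ``L / S``;
* unweighted degree per species;
* NODF — nestedness based on overlap and decreasing fill, over all row
  pairs and all column pairs (0-1 scale by default, 0-100 on request);
* weighted NODF — the quantitative variant keyed on strictly decreasing
  binary fill with strict cell-wise dominance;
* H2' — complementary network specialization, the observed interaction
  (Shannon) entropy rescaled between the most-even (H2max) and most-
  concentrated (H2min) integer tables sharing the observed marginal totals,
  so that 0 means complete generalization and 1 complete specialization.

NODF is computed pair-by-pair without pre-sorting the matrix: the
decreasing-fill condition is evaluated per pair, which makes the index
invariant to row/column permutation (the classical presentation sorts the
matrix first, but sorting only fixes which member of a pair is "upper").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .network import BipartiteNetwork

__all__ = [
    "NetworkMetrics",
    "H2Result",
    "connectance",
    "links_per_species",
    "unweighted_degree",
    "nodf",
    "wnodf",
    "h2prime",
    "network_metrics",
]


def _as_matrix(net_or_matrix) -> np.ndarray:
    if isinstance(net_or_matrix, BipartiteNetwork):
        return np.asarray(net_or_matrix.weights)
    return np.asarray(net_or_matrix)


def connectance(net: BipartiteNetwork) -> float:
    """C = L / (R * A), the realized fraction of possible links."""
    return net.links / (net.n_plants * net.n_pollinators)


def links_per_species(net: BipartiteNetwork, include_isolated: bool = True) -> float:
    """Mean number of links per species, L / S.

    ``include_isolated`` counts zero-degree species in S, matching the
    convention of reporting every observed species in the community.
    """
    s = net.n_species_total if include_isolated else net.n_species
    return net.links / s


def unweighted_degree(net: BipartiteNetwork) -> dict[str, dict[str, int]]:
    """Number of interaction partners per species, isolated species at 0."""
    b = net.weights > 0
    plants = {p: int(b[i].sum()) for i, p in enumerate(net.plant_labels)}
    pols = {a: int(b[:, j].sum()) for j, a in enumerate(net.pollinator_labels)}
    plants.update({p: 0 for p in net.isolated_plants})
    pols.update({a: 0 for a in net.isolated_pollinators})
    return {"plants": plants, "pollinators": pols}


def _check_no_empty_lines(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ValueError("matrix must be 2-D and non-empty")
    if np.any(m.sum(axis=1) == 0) or np.any(m.sum(axis=0) == 0):
        raise ValueError("matrix has an empty row or column")


def _nodf_pairs_binary(b: np.ndarray) -> float:
    """Sum of paired nestedness over all row pairs of a binary matrix."""
    fills = b.sum(axis=1)
    overlap = b @ b.T
    n = b.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    fi, fj = fills[iu], fills[ju]
    smaller = np.minimum(fi, fj)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(fi == fj, 0.0, overlap[iu, ju] / smaller)
    return float(contrib.sum())


def nodf(matrix, scale: str = "unit") -> float:
    """NODF nestedness of a binary matrix.

    For each unordered pair of rows (and of columns) with unequal fills the
    paired nestedness is the overlap count divided by the smaller fill;
    equal-fill pairs contribute zero. NODF is the mean over all
    ``R(R-1)/2 + A(A-1)/2`` pairs.

    Parameters
    ----------
    matrix : array-like
        Binary (or quantitative; positive cells are taken as presences)
        matrix with no empty rows or columns.
    scale : {"unit", "percent"}
        0-1 or the conventional 0-100 presentation scale.
    """
    m = _as_matrix(matrix)
    _check_no_empty_lines(m)
    b = (m > 0).astype(int)
    r, a = b.shape
    n_pairs = r * (r - 1) // 2 + a * (a - 1) // 2
    if n_pairs == 0:
        value = 0.0
    else:
        value = (_nodf_pairs_binary(b) + _nodf_pairs_binary(b.T)) / n_pairs
    if scale == "percent":
        return value * 100.0
    if scale != "unit":
        raise ValueError(f"unknown scale {scale!r}")
    return value


def _wnodf_pairs(m: np.ndarray) -> float:
    """Sum of weighted paired nestedness over all row pairs."""
    b = m > 0
    fills = b.sum(axis=1)
    total = 0.0
    n = m.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            if fills[i] == fills[j]:
                continue
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            mask = b[lo]
            total += float(np.count_nonzero(m[hi, mask] > m[lo, mask])) / fills[lo]
    return total


def wnodf(matrix, scale: str = "unit") -> float:
    """Weighted NODF of a quantitative matrix.

    A pair of rows (columns) contributes zero unless its binary fills
    differ; otherwise the larger-fill line is the reference and the
    contribution is the fraction of the smaller-fill line's positive cells
    whose paired cell in the reference line is strictly greater. On binary
    input no cell can be strictly greater than a positive cell, so
    wnodf <= nodf always holds there.
    """
    m = _as_matrix(matrix)
    _check_no_empty_lines(m)
    r, a = m.shape
    n_pairs = r * (r - 1) // 2 + a * (a - 1) // 2
    if n_pairs == 0:
        value = 0.0
    else:
        value = (_wnodf_pairs(m) + _wnodf_pairs(m.T)) / n_pairs
    return value * 100.0 if scale == "percent" else value


# ---------------------------------------------------------------------------
# H2' complementary specialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class H2Result:
    """Observed interaction entropy and its marginal-constrained extremes (nats)."""

    h2: float
    h2_max: float
    h2_min: float
    h2prime: float
    extremes_method: str  # "exhaustive" or "heuristic"


def _entropy(table: np.ndarray) -> float:
    f = table.sum()
    p = table[table > 0] / f
    return float(-(p * np.log(p)).sum())


def _h2max_table_greedy(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most-even integer table: place units where the independence
    expectation is least satisfied, honoring both marginals exactly."""
    f = int(r.sum())
    expect = np.outer(r, c) / f
    a = np.zeros((len(r), len(c)), dtype=int)
    rrem = r.astype(int).copy()
    crem = c.astype(int).copy()
    for _ in range(f):
        gap = expect - a
        gap[rrem == 0, :] = -np.inf
        gap[:, crem == 0] = -np.inf
        i, j = np.unravel_index(int(np.argmax(gap)), a.shape)
        a[i, j] += 1
        rrem[i] -= 1
        crem[j] -= 1
    return a


def _h2min_table_greedy(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most-concentrated table: repeatedly pour min(remaining row, remaining
    column) into the cell pairing the two largest remaining marginals."""
    a = np.zeros((len(r), len(c)), dtype=int)
    rrem = r.astype(int).copy()
    crem = c.astype(int).copy()
    while rrem.sum() > 0:
        i = int(np.argmax(rrem))  # argmax takes the lowest index on ties
        j = int(np.argmax(crem))
        amount = min(rrem[i], crem[j])
        a[i, j] += amount
        rrem[i] -= amount
        crem[j] -= amount
    return a


def _iter_tables(rrem: tuple[int, ...], c: tuple[int, ...], cap: list[int]):
    """Yield all non-negative integer tables with the given marginals."""
    if len(rrem) == 1:
        yield (c,)
        return
    target = rrem[0]

    def fill_row(j: int, left: int, row: tuple[int, ...], crem: tuple[int, ...]):
        if j == len(crem):
            if left == 0:
                for sub in _iter_tables(rrem[1:], crem, cap):
                    cap[0] -= 1
                    if cap[0] < 0:
                        raise _EnumerationCap
                    yield (row,) + sub
            return
        lo = max(0, left - sum(crem[j + 1:]))
        hi = min(left, crem[j])
        for v in range(lo, hi + 1):
            yield from fill_row(
                j + 1, left - v, row + (v,), crem[:j] + (crem[j] - v,) + crem[j + 1:]
            )

    yield from fill_row(0, target, (), c)


class _EnumerationCap(Exception):
    pass


@lru_cache(maxsize=512)
def _entropy_extremes(r: tuple[int, ...], c: tuple[int, ...], max_cells: int = 12,
                      max_tables: int = 200_000) -> tuple[float, float, str]:
    """(H2max, H2min, method) over integer tables with marginals r, c.

    Exhaustive enumeration when the table has <= ``max_cells`` cells and
    fewer than ``max_tables`` candidate tables; greedy heuristics otherwise.
    Cached because null-model resampling holds the marginals fixed.
    """
    ra = np.asarray(r)
    ca = np.asarray(c)
    if len(r) * len(c) <= max_cells:
        hmax, hmin = -np.inf, np.inf
        cap = [max_tables]
        try:
            for table in _iter_tables(r, c, cap):
                h = _entropy(np.asarray(table, dtype=float))
                hmax = max(hmax, h)
                hmin = min(hmin, h)
            return float(hmax), float(hmin), "exhaustive"
        except _EnumerationCap:
            pass
    hmax = _entropy(_h2max_table_greedy(ra, ca))
    hmin = _entropy(_h2min_table_greedy(ra, ca))
    return float(hmax), float(hmin), "heuristic"


def h2prime(net_or_matrix) -> H2Result:
    """Complementary specialization H2' of a quantitative matrix.

    H2 is the Shannon entropy of the interaction proportions
    ``p_ij = a_ij / F``; H2max and H2min are the entropies of the most-even
    and most-concentrated integer tables with the observed marginal totals;
    ``H2' = (H2max - H2) / (H2max - H2min)``, clamped to [0, 1].

    Degenerate marginals with ``H2max == H2min`` yield H2' = 0 with a warning.
    """
    m = _as_matrix(net_or_matrix).astype(int)
    f = int(m.sum())
    if f == 0:
        raise ValueError("cannot compute H2' on an all-zero matrix")
    h2 = _entropy(m)
    r = tuple(int(x) for x in m.sum(axis=1))
    c = tuple(int(x) for x in m.sum(axis=0))
    h2max, h2min, method = _entropy_extremes(r, c)
    if h2max - h2min < 1e-12:
        warnings.warn("degenerate marginals: H2max == H2min; H2' defined as 0")
        value = 0.0
    else:
        value = (h2max - h2) / (h2max - h2min)
    return H2Result(h2, h2max, h2min, float(min(1.0, max(0.0, value))), method)


@dataclass(frozen=True)
class NetworkMetrics:
    """Bundle of network-level metrics on the 0-1 NODF scale."""

    connectance: float
    links: int
    links_per_species: float
    nodf: float
    wnodf: float
    h2: H2Result

    @property
    def nodf_percent(self) -> float:
        return self.nodf * 100.0


def network_metrics(net: BipartiteNetwork) -> NetworkMetrics:
    """Compute the full network-level metric bundle for a network."""
    return NetworkMetrics(
        connectance=connectance(net),
        links=net.links,
        links_per_species=links_per_species(net),
        nodf=nodf(net.weights),
        wnodf=wnodf(net.weights),
        h2=h2prime(net.weights),
    )
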