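"""Maximum attainable NODF and size-corrected nestedness (combined NODF).

Raw NODF values of networks with different dimensions and connectance are
not directly comparable. The correction used here first normalizes raw
NODF by the maximum NODF attainable by *any* binary matrix with the same
shape and link count, then divides by a size/connectance term:

    NODF_c = (NODF / max NODF) / (C * log10(sqrt(R * A)))

with ``C = L / (R * A)`` computed from the ORIGINAL link count. Max NODF
is defined only when every species can hold a link, i.e. when
``R + A <= L``; sparser networks are handled by augmenting the link count
(a conservative, slightly inflated maximum). Because the optimal witness
depends only on (R, A, L), augmentation is a pure link-count adjustment.

Max NODF is found exhaustively (all placements of L ones with no empty
line) when the candidate count is small, and otherwise by a greedy nested
fill followed by steepest-ascent 1-swap hill climbing with random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log10, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import nodf
from .network import BipartiteNetwork

__all__ = [
    "MaxNodfResult",
    "NodfcResult",
    "augment_links",
    "max_nodf",
    "nodf_c",
    "compare_daily",
    "nodfc_table",
]

EXHAUSTIVE_LIMIT = 10**6  # max candidate placements enumerated by method="auto"


@dataclass(frozen=True)
class MaxNodfResult:
    rows: int
    cols: int
    links: int
    max_nodf: float
    witness: np.ndarray
    method: str

    def __post_init__(self):
        assert int(self.witness.sum()) == self.links


@dataclass(frozen=True)
class NodfcResult:
    raw_nodf: float
    max_nodf: float
    connectance: float
    nodf_c: float


def augment_links(R: int, A: int, L: int, links_added: int | None = None) -> int:
    """Effective link count for the max-NODF analysis.

    By default the count is raised to ``R + A`` when needed (so every
    species can carry a link); an explicit ``links_added`` override
    reproduces published augmentations exactly.
    """
    if L < max(R, A):
        raise ValueError(
            f"no valid {R}x{A} binary matrix with {L} links covers every species"
        )
    if links_added is not None:
        if links_added < 0 or L + links_added > R * A:
            raise ValueError("links_added out of range")
        return L + links_added
    return max(L, R + A)


# -- fast NODF on bitmask rows ----------------------------------------------


def _nodf_bits(row_masks: list[int], A: int) -> float:
    R = len(row_masks)
    fills = [m.bit_count() for m in row_masks]
    total = 0.0
    for i in range(R - 1):
        for j in range(i + 1, R):
            if fills[i] != fills[j]:
                total += (row_masks[i] & row_masks[j]).bit_count() / min(fills[i], fills[j])
    col_masks = [0] * A
    for i, m in enumerate(row_masks):
        for j in range(A):
            if m >> j & 1:
                col_masks[j] |= 1 << i
    cfills = [m.bit_count() for m in col_masks]
    for i in range(A - 1):
        for j in range(i + 1, A):
            if cfills[i] != cfills[j]:
                total += (col_masks[i] & col_masks[j]).bit_count() / min(cfills[i], cfills[j])
    return total / (R * (R - 1) // 2 + A * (A - 1) // 2)


def _cells_to_matrix(cells, R: int, A: int) -> np.ndarray:
    m = np.zeros((R, A), dtype=int)
    for c in cells:
        m[divmod(c, A)] = 1
    return m


def _max_nodf_exhaustive(R: int, A: int, L: int) -> tuple[float, np.ndarray]:
    best = -1.0
    best_cells = None
    full_row = (1 << A) - 1
    for cells in combinations(range(R * A), L):
        masks = [0] * R
        for c in cells:
            i, j = divmod(c, A)
            masks[i] |= 1 << j
        if 0 in masks:
            continue
        cover = 0
        for m in masks:
            cover |= m
        if cover != full_row:
            continue
        val = _nodf_bits(masks, A)
        if val > best:
            best = val
            best_cells = cells
    return best, _cells_to_matrix(best_cells, R, A)


def _greedy_nested(R: int, A: int, L: int) -> np.ndarray:
    """Valid starting matrix: staircase skeleton covering every line, then
    fill remaining links in nested (top-left packed) order."""
    m = np.zeros((R, A), dtype=int)
    for i in range(R):
        m[i, 0] = 1
    for j in range(A):
        m[0, j] = 1
    placed = int(m.sum())
    if placed > L:
        # L < R + A - 1: shrink the first row, fanning rows across columns
        m[:] = 0
        for i in range(R):
            m[i, min(i, A - 1)] = 1
        for j in range(A):
            if m[:, j].sum() == 0:
                m[min(j, R - 1), j] = 1
        placed = int(m.sum())
    order = sorted(
        ((i, j) for i in range(R) for j in range(A)),
        key=lambda ij: (ij[0] + ij[1], ij[0], ij[1]),
    )
    for i, j in order:
        if placed >= L:
            break
        if m[i, j] == 0:
            m[i, j] = 1
            placed += 1
    return m


def _random_valid(R: int, A: int, L: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        cells = rng.choice(R * A, size=L, replace=False)
        m = np.zeros(R * A, dtype=int)
        m[cells] = 1
        m = m.reshape(R, A)
        if m.sum(axis=1).all() and m.sum(axis=0).all():
            return m


def _hill_climb(m: np.ndarray) -> tuple[float, np.ndarray]:
    """Steepest-ascent 1-swaps (move a link to an empty cell) keeping validity."""
    cur = m.copy()
    cur_val = _matrix_nodf(cur)
    while True:
        best_delta = 0.0
        best_move = None
        ones = np.argwhere(cur == 1)
        zeros = np.argwhere(cur == 0)
        for oi, oj in ones:
            row_ok = cur[oi].sum() > 1
            col_ok = cur[:, oj].sum() > 1
            for zi, zj in zeros:
                if (zi == oi or row_ok) and (zj == oj or col_ok):
                    cur[oi, oj] = 0
                    cur[zi, zj] = 1
                    val = _matrix_nodf(cur)
                    cur[oi, oj] = 1
                    cur[zi, zj] = 0
                    if val - cur_val > best_delta + 1e-12:
                        best_delta = val - cur_val
                        best_move = (oi, oj, zi, zj)
        if best_move is None:
            return cur_val, cur
        oi, oj, zi, zj = best_move
        cur[oi, oj] = 0
        cur[zi, zj] = 1
        cur_val += best_delta


def _matrix_nodf(m: np.ndarray) -> float:
    masks = [int(sum(1 << j for j in range(m.shape[1]) if m[i, j])) for i in range(m.shape[0])]
    return _nodf_bits(masks, m.shape[1])


def _greedy_add(R: int, A: int, L: int) -> np.ndarray:
    """Start from a minimal valid staircase, then add links one at a time
    wherever NODF increases most."""
    m = np.zeros((R, A), dtype=int)
    for i in range(R):
        m[i, min(i, A - 1)] = 1
    for j in range(A):
        if m[:, j].sum() == 0:
            m[min(j, R - 1), j] = 1
    while int(m.sum()) < L:
        best_val, best_ij = -1.0, None
        for i in range(R):
            for j in range(A):
                if m[i, j] == 0:
                    m[i, j] = 1
                    val = _matrix_nodf(m)
                    m[i, j] = 0
                    if val > best_val:
                        best_val, best_ij = val, (i, j)
        m[best_ij] = 1
    return m


def _max_nodf_heuristic(
    R: int, A: int, L: int, restarts: int, seed: int | None
) -> tuple[float, np.ndarray]:
    rng = np.random.default_rng(seed)
    best_val, best_m = _hill_climb(_greedy_add(R, A, L))
    val, m = _hill_climb(_greedy_nested(R, A, L))
    if val > best_val + 1e-12:
        best_val, best_m = val, m
    for _ in range(max(restarts - 2, 0)):
        val, m = _hill_climb(_random_valid(R, A, L, rng))
        if val > best_val + 1e-12:
            best_val, best_m = val, m
    return best_val, best_m


def max_nodf(
    R: int,
    A: int,
    L_eff: int,
    method: str = "auto",
    seed: int | None = None,
    restarts: int = 50,
) -> MaxNodfResult:
    """Maximum NODF over all R x A binary matrices with ``L_eff`` links.

    ``method="exhaustive"`` enumerates every placement with no empty line;
    ``"heuristic"`` runs greedy nested fill + steepest-ascent 1-swap hill
    climbing with ``restarts`` seeded random restarts; ``"auto"`` picks
    exhaustive when ``C(R*A, L_eff) <= EXHAUSTIVE_LIMIT``.
    """
    if not (max(R, A) <= L_eff <= R * A):
        raise ValueError(f"infeasible link count {L_eff} for a {R}x{A} matrix")
    if method == "auto":
        method = "exhaustive" if comb(R * A, L_eff) <= EXHAUSTIVE_LIMIT else "heuristic"
    if method == "exhaustive":
        val, witness = _max_nodf_exhaustive(R, A, L_eff)
    elif method == "heuristic":
        val, witness = _max_nodf_heuristic(R, A, L_eff, restarts, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MaxNodfResult(R, A, L_eff, float(val), witness, method)


def nodf_c(
    raw_nodf: float, max_nodf_value: float, R: int, A: int, L_original: int
) -> NodfcResult:
    """Combined (size-corrected) nestedness NODF_c.

    ``NODF_c = (raw / max) / (C * log10(sqrt(R * A)))`` with connectance C
    computed from the original (pre-augmentation) link count. Scale-
    invariant: raw and max may both be on the 0-1 or both on the 0-100
    scale.
    """
    if max_nodf_value <= 0:
        raise ValueError("max NODF must be positive")
    if L_original < 1:
        raise ValueError("original link count must be >= 1")
    c = L_original / (R * A)
    value = (raw_nodf / max_nodf_value) / (c * log10(sqrt(R * A)))
    return NodfcResult(raw_nodf, max_nodf_value, c, float(value))


def compare_daily(
    networks: Mapping[int, BipartiteNetwork],
    links_added: Mapping[int, int] | None = None,
    method: str = "auto",
    seed: int | None = None,
    restarts: int = 50,
) -> pd.DataFrame:
    """Per-day nestedness comparison table for a dated network series.

    Computes, for each day: network size, original links L, effective
    links after augmentation, raw NODF, max NODF and NODF_c. The returned
    frame carries the day with maximal NODF_c in ``df.attrs["argmax_day"]``.
    """
    links_added = links_added or {}
    rows = []
    for day in sorted(networks):
        net = networks[day]
        R, A, L = net.n_plants, net.n_pollinators, net.links
        l_eff = augment_links(R, A, L, links_added.get(day))
        raw = nodf(net.weights)
        mx = max_nodf(R, A, l_eff, method=method, seed=seed, restarts=restarts)
        res = nodf_c(raw, mx.max_nodf, R, A, L)
        rows.append({"day": day, "plants": R, "pollinators": A, "links": L,
                     "links_eff": l_eff, "raw_nodf": raw, "max_nodf": mx.max_nodf,
                     "nodf_c": res.nodf_c})
    df = pd.DataFrame(rows).set_index("day")
    df.attrs["argmax_day"] = int(df["nodf_c"].idxmax())
    return df


def nodfc_table(
    daily_params: Sequence[tuple[int, int, int, int, int, float, float]],
) -> pd.DataFrame:
    """NODF_c table from printed per-day parameters.

    Each entry is ``(day, R, A, L, links_added, raw_nodf, max_nodf)`` with
    raw/max NODF already known (e.g. from a published table); only the
    size-correction is recomputed.
    """
    rows = []
    for day, R, A, L, added, raw, mx in daily_params:
        res = nodf_c(raw, mx, R, A, L)
        rows.append({"day": day, "plants": R, "pollinators": A, "links": L,
                     "links_eff": L + added, "raw_nodf": raw, "max_nodf": mx,
                     "nodf_c": res.nodf_c})
    df = pd.DataFrame(rows).set_index("day")
    df.attrs["argmax_day"] = int(df["nodf_c"].idxmax())
    return df
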