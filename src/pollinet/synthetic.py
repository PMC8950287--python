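"""Synthetic visitation networks with controllable structure.

Generators for the statistical features the analysis pipeline assumes:
nestedness (subset-structured binary matrices), planted module structure
(block-concentrated quantitative matrices), and exact degree-sequence
realizations (Gale-Ryser). All generators are seed-deterministic and emit
matrices without empty rows or columns.

Visit weights, where generated, default to overdispersed negative-binomial
counts — the typical mean-variance behaviour of field visitation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import network_from_matrix

__all__ = [
    "generate_nested",
    "generate_modular",
    "realize_degree_sequence",
    "DegreeRealization",
    "attach_weights",
]


def generate_nested(
    R: int, A: int, fill_exponent: float, L: int, seed: int | None = None
) -> np.ndarray:
    """Binary matrix with tunable nestedness and exactly ``L`` links.

    A minimal skeleton covering every row and column is laid down first
    (a maximally nested cross when the budget allows, a staircase fan
    otherwise); the remaining cells are ranked by the superellipse score
    ``((i+1/2)/R)^p + ((j+1/2)/A)^p`` plus a small seeded jitter of the
    boundary, and the best-ranked free cells fill the budget. Small ``p`` orders cells by the product of
    their coordinates (hyperbolic, strongly nested fill: row fills decay
    steeply and are mutually distinct); ``p = 1`` gives a triangular
    staircase; large ``p`` approaches an evenly filled block with many
    tied fills, i.e. weak nestedness.

    ``L`` must allow a matrix with no empty line: ``max(R, A) <= L <= R*A``.
    """
    if not (max(R, A) <= L <= R * A):
        raise ValueError(f"infeasible link count {L} for {R}x{A}")
    if fill_exponent <= 0:
        raise ValueError("fill_exponent must be positive")
    rng = np.random.default_rng(seed)
    p = fill_exponent
    i = (np.arange(R)[:, None] + 0.5) / R
    j = (np.arange(A)[None, :] + 0.5) / A
    score = i**p + j**p
    score = score + rng.uniform(0, 0.02 * (score.max() - score.min()), size=score.shape)
    m = np.zeros((R, A), dtype=int)
    # skeleton guaranteeing no empty line: maximally nested cross when the
    # budget allows, a staircase fan otherwise
    if L >= R + A - 1:
        m[0, :] = 1
        m[:, 0] = 1
    else:
        for r in range(R):
            m[r, r % A] = 1
        for c in range(A):
            if m[:, c].sum() == 0:
                m[c % R, c] = 1
    # fill the remaining budget with the best-scored free cells
    order = np.argsort(score, axis=None, kind="stable")
    placed = int(m.sum())
    for flat in order:
        if placed >= L:
            break
        ij = np.unravel_index(flat, m.shape)
        if m[ij] == 0:
            m[ij] = 1
            placed += 1
    assert int(m.sum()) == L
    return m


def attach_weights(
    binary: np.ndarray,
    rng: np.random.Generator | int | None = None,
    nb_mean: float = 3.0,
    nb_dispersion: float = 1.0,
) -> np.ndarray:
    """Positive negative-binomial visit counts on the links of a binary matrix.

    Counts are ``1 + NB(r, p)`` with mean ``1 + nb_mean`` per link; the
    dispersion parameter ``r`` (smaller = more overdispersed) defaults to 1,
    i.e. geometric-tailed counts.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = nb_dispersion
    p = r / (r + nb_mean)
    w = binary.astype(int).copy()
    links = np.argwhere(binary > 0)
    w[links[:, 0], links[:, 1]] = 1 + rng.negative_binomial(r, p, size=len(links))
    return w


def generate_modular(
    R: int,
    A: int,
    k: int,
    within_share: float,
    F: int,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Quantitative matrix with ``k`` planted modules.

    Species of each level are split as evenly as possible into ``k``
    modules; ``F`` total visits are assigned multinomially with a fraction
    ``within_share`` of the probability mass on within-module cells. Every
    species is guaranteed at least one within-module visit so the matrix
    has no empty lines.

    Returns the matrix and the planted species -> module labels (keys
    ``p1..pR`` and ``a1..aA``, matching ``network_from_matrix`` naming).
    """
    if not (1 <= k <= min(R, A)):
        raise ValueError(f"cannot plant {k} modules in a {R}x{A} network")
    if not (0.0 < within_share <= 1.0):
        raise ValueError("within_share must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pmod = np.arange(R) % k
    amod = np.arange(A) % k
    within = pmod[:, None] == amod[None, :]
    prob = np.where(within, within_share / within.sum(),
                    (1 - within_share) / max((~within).sum(), 1))
    if within_share == 1.0:
        prob = np.where(within, 1.0 / within.sum(), 0.0)
    prob = prob / prob.sum()
    # seed every species with one within-module visit, then fill multinomially
    m = np.zeros((R, A), dtype=int)
    for i in range(R):
        cols = np.flatnonzero(amod == pmod[i])
        m[i, rng.choice(cols)] += 1
    for j in range(A):
        if m[:, j].sum() == 0:
            rows = np.flatnonzero(pmod == amod[j])
            m[rng.choice(rows), j] += 1
    remaining = F - int(m.sum())
    if remaining < 0:
        raise ValueError(f"F={F} too small to cover all {R + A} species")
    m += rng.multinomial(remaining, prob.ravel()).reshape(R, A)
    labels = {f"p{i + 1}": int(pmod[i]) for i in range(R)}
    labels.update({f"a{j + 1}": int(amod[j]) for j in range(A)})
    return m, labels


@dataclass(frozen=True)
class DegreeRealization:
    """Outcome of a bipartite degree-sequence realization attempt."""

    feasible: bool
    matrix: np.ndarray | None
    reason: str = ""


def _gale_ryser_feasible(plant_degrees: np.ndarray, pollinator_degrees: np.ndarray) -> bool:
    d = np.sort(plant_degrees)[::-1]
    e = pollinator_degrees
    for kk in range(1, len(d) + 1):
        if d[:kk].sum() > np.minimum(e, kk).sum():
            return False
    return True


def realize_degree_sequence(
    plant_degrees, pollinator_degrees, seed: int | None = None
) -> DegreeRealization:
    """One binary matrix with exactly the given bipartite degree sequences.

    Feasibility is checked with the Gale-Ryser condition; construction is
    maximal-first (largest remaining plant degree connects to the
    pollinators of largest remaining degree) with seeded random
    tie-breaking, so different seeds yield different consistent matrices.
    Infeasible input returns a verdict, not an exception.
    """
    d = np.asarray(plant_degrees, dtype=int)
    e = np.asarray(pollinator_degrees, dtype=int)
    if np.any(d < 0) or np.any(e < 0):
        return DegreeRealization(False, None, "negative degree")
    if d.sum() != e.sum():
        return DegreeRealization(False, None, "degree sums differ")
    if np.any(d > len(e)) or np.any(e > len(d)):
        return DegreeRealization(False, None, "degree exceeds partner count")
    if not _gale_ryser_feasible(d, e):
        return DegreeRealization(False, None, "Gale-Ryser condition violated")
    rng = np.random.default_rng(seed)
    m = np.zeros((len(d), len(e)), dtype=int)
    drem = d.copy().astype(float)
    erem = e.copy().astype(float)
    order = np.argsort(-(d + rng.random(len(d))))
    for i in order:
        need = int(drem[i])
        if need == 0:
            continue
        # connect to the `need` pollinators with largest remaining degree
        keys = erem + rng.random(len(erem)) * 0.5  # randomized tie-breaking
        keys[erem <= 0] = -np.inf
        targets = np.argsort(-keys)[:need]
        if np.any(erem[targets] <= 0):
            return DegreeRealization(False, None, "construction failed")
        m[i, targets] = 1
        erem[targets] -= 1
        drem[i] = 0
    if np.any(erem != 0):
        return DegreeRealization(False, None, "construction failed")
    return DegreeRealization(True, m)
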