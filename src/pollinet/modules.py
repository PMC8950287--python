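"""Quantitative bipartite modularity (Barber-type) with stochastic search.

The objective is the weighted bipartite modularity

    Q = (1/F) * sum_ij [ A_ij - k_i * d_j / F ] * delta(m_i, m_j)

where ``A`` is the quantitative visit matrix, ``k_i`` / ``d_j`` the row and
column totals, ``F`` the grand total, and ``delta`` indicates that plant i
and pollinator j share a module. Modules mix plants and pollinators in one
id space; the module count is emergent, not fixed.

Optimization is simulated annealing with three move types (single-species
reassignment including to a fresh module, module merge, module split) and
geometric cooling, followed by a steepest single-move refinement pass; the
best partition over independent repetitions is returned — the standard
best-of-restarts treatment for a stochastic modularity search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import BipartiteNetwork

__all__ = ["ModulePartition", "modularity_Q", "find_modules", "exhaustive_best_partition"]


@dataclass(frozen=True)
class ModulePartition:
    """Species -> module assignment with its modularity score."""

    assignment: dict[str, int]
    Q: float
    n_modules: int
    repetition_scores: tuple[float, ...]
    seed: int | None

    def members(self) -> dict[int, list[str]]:
        """Module id -> sorted member labels."""
        out: dict[int, list[str]] = {}
        for sp, m in self.assignment.items():
            out.setdefault(m, []).append(sp)
        return {m: sorted(v) for m, v in sorted(out.items())}


def _excess_matrix(net: BipartiteNetwork) -> np.ndarray:
    """B_ij = (A_ij - k_i d_j / F) / F; Q = sum of B over within-module cells."""
    a = net.weights.astype(float)
    f = a.sum()
    return (a - np.outer(a.sum(axis=1), a.sum(axis=0)) / f) / f


def modularity_Q(net: BipartiteNetwork, assignment: Mapping[str, int]) -> float:
    """Evaluate Q for an explicit species -> module assignment."""
    for label in list(net.plant_labels) + list(net.pollinator_labels):
        if label not in assignment:
            raise ValueError(f"assignment missing species {label!r}")
    unknown = set(assignment) - set(net.plant_labels) - set(net.pollinator_labels) - set(
        net.isolated_plants
    ) - set(net.isolated_pollinators)
    if unknown:
        raise ValueError(f"assignment contains unknown species: {sorted(unknown)}")
    b = _excess_matrix(net)
    pm = np.array([assignment[p] for p in net.plant_labels])
    am = np.array([assignment[a] for a in net.pollinator_labels])
    return float(b[pm[:, None] == am[None, :]].sum())


def _q_of(b: np.ndarray, pm: np.ndarray, am: np.ndarray) -> float:
    return float(b[pm[:, None] == am[None, :]].sum())


def _refine(b: np.ndarray, pm: np.ndarray, am: np.ndarray, max_sweeps: int = 50) -> float:
    """Steepest single-species reassignment until no move improves Q."""
    q = _q_of(b, pm, am)
    r, a = b.shape
    for _ in range(max_sweeps):
        improved = False
        labels = np.unique(np.concatenate([pm, am]))
        fresh = labels.max() + 1
        candidates = np.append(labels, fresh)
        for i in range(r):
            gains = np.array([
                b[i, am == m].sum() - b[i, am == pm[i]].sum() for m in candidates
            ])
            best = int(np.argmax(gains))
            if gains[best] > 1e-14:
                pm[i] = candidates[best]
                q += gains[best]
                improved = True
        for j in range(a):
            gains = np.array([
                b[pm == m, j].sum() - b[pm == am[j], j].sum() for m in candidates
            ])
            best = int(np.argmax(gains))
            if gains[best] > 1e-14:
                am[j] = candidates[best]
                q += gains[best]
                improved = True
        if not improved:
            break
    return _q_of(b, pm, am)


def _anneal_once(
    b: np.ndarray,
    rng: np.random.Generator,
    steps: int,
    t0: float,
    cooling: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    r, a = b.shape
    pm = rng.integers(0, max(2, min(r + a, 8)), size=r)
    am = rng.integers(0, max(2, min(r + a, 8)), size=a)
    q = _q_of(b, pm, am)
    t = t0
    for _ in range(steps):
        u = rng.random()
        if u < 0.85:
            # single-species reassignment, possibly to a fresh module
            modules = np.unique(np.concatenate([pm, am]))
            target = rng.integers(0, len(modules) + 1)
            new_m = modules[target] if target < len(modules) else modules.max() + 1
            if rng.random() < r / (r + a):
                i = rng.integers(0, r)
                dq = float(b[i, am == new_m].sum() - b[i, am == pm[i]].sum())
                if dq > 0 or rng.random() < np.exp(min(dq / t, 0.0)):
                    pm[i] = new_m
                    q += dq
            else:
                j = rng.integers(0, a)
                dq = float(b[pm == new_m, j].sum() - b[pm == am[j], j].sum())
                if dq > 0 or rng.random() < np.exp(min(dq / t, 0.0)):
                    am[j] = new_m
                    q += dq
        elif u < 0.95:
            # merge two modules
            modules = np.unique(np.concatenate([pm, am]))
            if len(modules) >= 2:
                m1, m2 = rng.choice(modules, size=2, replace=False)
                dq = float(b[np.ix_(pm == m1, am == m2)].sum()
                           + b[np.ix_(pm == m2, am == m1)].sum())
                if dq > 0 or rng.random() < np.exp(min(dq / t, 0.0)):
                    pm[pm == m2] = m1
                    am[am == m2] = m1
                    q += dq
        else:
            # split a module by a random bipartition
            modules = np.unique(np.concatenate([pm, am]))
            m = rng.choice(modules)
            rows = np.flatnonzero(pm == m)
            cols = np.flatnonzero(am == m)
            if len(rows) + len(cols) >= 2:
                fresh = modules.max() + 1
                move_r = rows[rng.random(len(rows)) < 0.5]
                move_c = cols[rng.random(len(cols)) < 0.5]
                keep_r = np.setdiff1d(rows, move_r)
                keep_c = np.setdiff1d(cols, move_c)
                dq = -float(b[np.ix_(move_r, keep_c)].sum()
                            + b[np.ix_(keep_r, move_c)].sum())
                if dq > 0 or rng.random() < np.exp(min(dq / t, 0.0)):
                    pm[move_r] = fresh
                    am[move_c] = fresh
                    q += dq
        t = max(t * cooling, 1e-6)
    _refine(b, pm, am)
    return pm, am, _q_of(b, pm, am)


def _canonical(pm: np.ndarray, am: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel modules 0..k-1 in order of first appearance (plants first)."""
    mapping: dict[int, int] = {}
    for m in np.concatenate([pm, am]):
        if int(m) not in mapping:
            mapping[int(m)] = len(mapping)
    return (np.array([mapping[int(m)] for m in pm]),
            np.array([mapping[int(m)] for m in am]))


def find_modules(
    net: BipartiteNetwork,
    n_repetitions: int = 100,
    steps: int = 10_000,
    t0: float = 0.02,
    cooling: float = 0.995,
    seed: int | None = None,
) -> ModulePartition:
    """Best-of-repetitions annealing maximization of quantitative modularity.

    Parameters
    ----------
    n_repetitions : int
        Independent annealing restarts; the partition with maximum Q wins
        (ties broken by earlier repetition).
    steps : int
        Annealing moves per repetition.
    t0, cooling : float
        Initial temperature and geometric cooling factor (T <- cooling * T
        after every move).
    seed : int, optional
        Seeds the whole search; identical seeds reproduce the partition.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if steps < 1 or not (0 < cooling <= 1) or t0 <= 0:
        raise ValueError("invalid annealing parameters")
    b = _excess_matrix(net)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    scores: list[float] = []
    for _ in range(n_repetitions):
        pm, am, q = _anneal_once(b, rng, steps, t0, cooling)
        scores.append(q)
        if best is None or q > best[0] + 1e-14:
            best = (q, pm.copy(), am.copy())
    q, pm, am = best
    pm, am = _canonical(pm, am)
    assignment = {p: int(m) for p, m in zip(net.plant_labels, pm)}
    assignment.update({a: int(m) for a, m in zip(net.pollinator_labels, am)})
    return ModulePartition(
        assignment=assignment,
        Q=float(q),
        n_modules=len(set(assignment.values())),
        repetition_scores=tuple(scores),
        seed=seed,
    )


def _set_partitions(items: list):
    """All set partitions of a list (Bell-number many; small inputs only)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_partition(net: BipartiteNetwork) -> ModulePartition:
    """Exact Q maximization by enumerating all set partitions of the species.

    Exponential; intended as an oracle for networks with at most ~10
    interacting species.
    """
    species = list(net.plant_labels) + list(net.pollinator_labels)
    if len(species) > 12:
        raise ValueError("exhaustive partition search limited to 12 species")
    best_q = -np.inf
    best_assignment: dict[str, int] = {}
    for part in _set_partitions(species):
        assignment = {sp: m for m, block in enumerate(part) for sp in block}
        q = modularity_Q(net, assignment)
        if q > best_q + 1e-14:
            best_q = q
            best_assignment = assignment
    return ModulePartition(
        assignment=best_assignment,
        Q=float(best_q),
        n_modules=len(set(best_assignment.values())),
        repetition_scores=(float(best_q),),
        seed=None,
    )
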