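"""Core data model for quantitative plant-pollinator visitation networks.

A network is a bipartite, integer-weighted interaction matrix: rows are
plants, columns are flower visitors (pollinators), and each cell holds the
number of visits recorded between that pair. Species that were present in
the community but never observed interacting (zero total visits) are kept on
an *isolated-species register* rather than as empty matrix lines, so that
every row and column of the matrix proper has at least one positive entry —
the convention under which connectance and the other matrix metrics are
defined here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InteractionRecord",
    "BipartiteNetwork",
    "EmptyNetworkError",
    "InteractionParseError",
    "build_network",
    "read_interactions_csv",
    "write_interactions_csv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class EmptyNetworkError(ValueError):
    """Raised when no interactions remain after filtering."""


class InteractionParseError(ValueError):
    """Raised on malformed interaction CSV input; carries the row number."""


@dataclass(frozen=True)
class InteractionRecord:
    """One aggregated field observation: visits of a pollinator to a plant.

    Parameters
    ----------
    day : int
        Julian day of year of the observation, in [1, 366].
    plant, pollinator : str
        Non-empty species labels.
    visits : int
        Non-negative visit count.
    """

    day: int
    plant: str
    pollinator: str
    visits: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.day) <= 366):
            raise ValueError(f"day of year out of range [1, 366]: {self.day}")
        if not self.plant or not self.pollinator:
            raise ValueError("species labels must be non-empty")
        if int(self.visits) < 0:
            raise ValueError(f"negative visit count: {self.visits}")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Quantitative bipartite network (plants x pollinators).

    ``weights`` is an R x A matrix of non-negative integer visit counts in
    which every row and every column has at least one positive entry.
    Species observed in the community but with zero interactions live in
    ``isolated_plants`` / ``isolated_pollinators``.
    """

    plant_labels: tuple[str, ...]
    pollinator_labels: tuple[str, ...]
    weights: np.ndarray
    isolated_plants: tuple[str, ...] = ()
    isolated_pollinators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        object.__setattr__(self, "weights", w)
        r, a = w.shape
        if r != len(self.plant_labels) or a != len(self.pollinator_labels):
            raise ValueError("label counts do not match matrix shape")
        if r < 1 or a < 1:
            raise EmptyNetworkError("network has no interacting species")
        if len(set(self.plant_labels)) != r or len(set(self.pollinator_labels)) != a:
            raise ValueError("species labels must be unique within a level")
        if np.any(w < 0):
            raise ValueError("visit counts must be non-negative")
        if np.any(w.sum(axis=1) == 0) or np.any(w.sum(axis=0) == 0):
            raise ValueError(
                "matrix has an empty row/column; zero-degree species belong "
                "on the isolated-species register"
            )

    # -- basic symbols ----------------------------------------------------
    @property
    def n_plants(self) -> int:
        """R, number of interacting plant species (matrix rows)."""
        return self.weights.shape[0]

    @property
    def n_pollinators(self) -> int:
        """A, number of interacting pollinator species (matrix columns)."""
        return self.weights.shape[1]

    @property
    def n_species(self) -> int:
        """Interacting species count R + A (isolated species excluded)."""
        return self.n_plants + self.n_pollinators

    @property
    def n_species_total(self) -> int:
        """All observed species, including the isolated register."""
        return self.n_species + len(self.isolated_plants) + len(self.isolated_pollinators)

    @property
    def links(self) -> int:
        """L, number of realized links (positive cells)."""
        return int(np.count_nonzero(self.weights))

    @property
    def total_visits(self) -> int:
        """F, grand total of the visit matrix."""
        return int(self.weights.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """k_i, per-plant visit totals."""
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """d_j, per-pollinator visit totals."""
        return self.weights.sum(axis=0)

    def to_binary(self) -> "BipartiteNetwork":
        """Presence/absence version: positive cells become 1."""
        return BipartiteNetwork(
            self.plant_labels,
            self.pollinator_labels,
            (self.weights > 0).astype(int),
            self.isolated_plants,
            self.isolated_pollinators,
        )


def build_network(
    records: Iterable[InteractionRecord],
    day_filter: set[int] | None = None,
    sort_labels: bool = False,
) -> BipartiteNetwork:
    """Aggregate interaction records into a quantitative network.

    Visit counts are summed per (plant, pollinator) pair. Species whose
    total is zero after aggregation (recorded only with ``visits == 0``)
    are moved to the isolated-species register. Label order is order of
    first appearance in the record stream unless ``sort_labels`` is set.

    Raises
    ------
    EmptyNetworkError
        If no records survive ``day_filter`` or all totals are zero.
    """
    recs = [r for r in records if day_filter is None or r.day in day_filter]
    if not recs:
        raise EmptyNetworkError("no interaction records after day filtering")

    plants: list[str] = []
    pols: list[str] = []
    agg: dict[tuple[str, str], int] = {}
    for r in recs:
        if r.plant not in plants:
            plants.append(r.plant)
        if r.pollinator not in pols:
            pols.append(r.pollinator)
        agg[(r.plant, r.pollinator)] = agg.get((r.plant, r.pollinator), 0) + int(r.visits)

    if sort_labels:
        plants = sorted(plants)
        pols = sorted(pols)

    w = np.zeros((len(plants), len(pols)), dtype=int)
    p_idx = {p: i for i, p in enumerate(plants)}
    a_idx = {a: j for j, a in enumerate(pols)}
    for (p, a), v in agg.items():
        w[p_idx[p], a_idx[a]] += v

    keep_r = w.sum(axis=1) > 0
    keep_c = w.sum(axis=0) > 0
    if not keep_r.any() or not keep_c.any():
        raise EmptyNetworkError("all aggregated visit totals are zero")
    iso_p = tuple(p for p, k in zip(plants, keep_r) if not k)
    iso_a = tuple(a for a, k in zip(pols, keep_c) if not k)
    return BipartiteNetwork(
        tuple(p for p, k in zip(plants, keep_r) if k),
        tuple(a for a, k in zip(pols, keep_c) if k),
        w[np.ix_(keep_r, keep_c)],
        iso_p,
        iso_a,
    )


_CSV_HEADER = ["day", "plant", "pollinator", "visits"]


def read_interactions_csv(path) -> list[InteractionRecord]:
    """Read long-format interaction records (``day,plant,pollinator,visits``)."""
    records: list[InteractionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _CSV_HEADER:
            raise InteractionParseError(
                f"expected header {','.join(_CSV_HEADER)!r}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                day = int(row["day"])
                visits = int(row["visits"])
                rec = InteractionRecord(day, row["plant"], row["pollinator"], visits)
            except (TypeError, ValueError, KeyError) as exc:
                raise InteractionParseError(f"row {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_interactions_csv(path, records: Iterable[InteractionRecord]) -> None:
    """Write records in the same long CSV format read_interactions_csv reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            writer.writerow([r.day, r.plant, r.pollinator, r.visits])


def read_matrix_tsv(path) -> BipartiteNetwork:
    """Read a quantitative matrix TSV (first row pollinators, first column plants)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EmptyNetworkError("empty matrix file")
    header = lines[0].split("\t")
    pols = [h for h in header[1:]]
    plants: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(pols) + 1:
            raise InteractionParseError(f"row {lineno}: expected {len(pols) + 1} fields")
        plants.append(parts[0])
        try:
            rows.append([int(x) for x in parts[1:]])
        except ValueError as exc:
            raise InteractionParseError(f"row {lineno}: {exc}") from exc
    w = np.array(rows, dtype=int)
    keep_r = w.sum(axis=1) > 0
    keep_c = w.sum(axis=0) > 0
    return BipartiteNetwork(
        tuple(p for p, k in zip(plants, keep_r) if k),
        tuple(a for a, k in zip(pols, keep_c) if k),
        w[np.ix_(keep_r, keep_c)],
        tuple(p for p, k in zip(plants, keep_r) if not k),
        tuple(a for a, k in zip(pols, keep_c) if not k),
    )


def write_matrix_tsv(path, net: BipartiteNetwork, include_isolated: bool = False) -> None:
    """Write the visit matrix as TSV; optionally append isolated species as zero lines."""
    pols = list(net.pollinator_labels)
    plants = list(net.plant_labels)
    w = net.weights
    if include_isolated:
        pols += list(net.isolated_pollinators)
        plants += list(net.isolated_plants)
        w = np.zeros((len(plants), len(pols)), dtype=int)
        w[: net.n_plants, : net.n_pollinators] = net.weights
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + pols) + "\n")
        for p, row in zip(plants, w):
            fh.write("\t".join([p] + [str(int(x)) for x in row]) + "\n")


def network_from_matrix(
    weights: np.ndarray,
    plant_labels: Sequence[str] | None = None,
    pollinator_labels: Sequence[str] | None = None,
) -> BipartiteNetwork:
    """Wrap a raw matrix, auto-labelling species and shelving empty lines."""
    w = np.asarray(weights, dtype=int)
    r, a = w.shape
    plants = list(plant_labels) if plant_labels is not None else [f"p{i + 1}" for i in range(r)]
    pols = (
        list(pollinator_labels)
        if pollinator_labels is not None
        else [f"a{j + 1}" for j in range(a)]
    )
    keep_r = w.sum(axis=1) > 0
    keep_c = w.sum(axis=0) > 0
    if not keep_r.any() or not keep_c.any():
        raise EmptyNetworkError("matrix has no positive cells")
    return BipartiteNetwork(
        tuple(p for p, k in zip(plants, keep_r) if k),
        tuple(x for x, k in zip(pols, keep_c) if k),
        w[np.ix_(keep_r, keep_c)],
        tuple(p for p, k in zip(plants, keep_r) if not k),
        tuple(x for x, k in zip(pols, keep_c) if not k),
    )
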