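"""Packaged study fixture: the printed summary data of a one-season
plant-pollinator survey around the food-deceptive slipper orchid
*Cypripedium guttatum* (12 plant species, 19 flower-visitor species,
42 links, four dated sub-networks).

The quantitative cell values of the observed visit matrix were never
published; what this fixture carries are the *printed* summaries — species
lists, per-species unweighted degrees, visitation-bout durations, hourly
visit counts, and per-day network parameters. A binary interaction matrix
consistent with the printed degree sequences is shipped alongside as a
clearly flagged synthetic reconstruction ("one of many consistent
matrices"), generated by :func:`pollinet.synthetic.realize_degree_sequence`;
matrix-dependent quantities computed from it (weighted nestedness, exact
module membership, centrality values) are illustrative, not observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .network import BipartiteNetwork, build_network, read_interactions_csv
from .synthetic import realize_degree_sequence

__all__ = ["PaperFixture", "load_fixture", "fixture_network", "fixture_interactions_path"]

# Seed used to generate the shipped reconstruction CSV (data/ directory).
RECONSTRUCTION_SEED = 20220317
RECONSTRUCTION_DAY = 149  # placeholder: per-day splits are not recoverable

_PLANTS = (
    "Polygonatum odoratum var. pluriflorum",
    "Ranunculus japonicus",
    "Viola mandshurica",
    "Rhododendron schlippenbachii",
    "Cypripedium guttatum",
    "Aruncus dioicus var. kamtschaticus",
    "Weigela florida",
    "Arabis gemmifera",
    "Taraxacum officinale",
    "Barbarea vulgaris",
    "Valeriana fauriei",
    "Cerastium holosteoides var. hallaisanensis",
)

_POLLINATORS = (
    "Andrena sp. 1",
    "Apis mellifera",
    "Bombylius major",
    "Carterocephalus silvicola",
    "Ceratina flavipes",
    "Curculionidae sp. 1",
    "Elateridae sp. 1",
    "Eristalomyia tenax",
    "Eucera sp. 1",
    "Lasioglossum exiliceps",
    "Lasioglossum duplex",
    "Lasioglossum virideglaucum",
    "Lasioglossum miyabei",
    "Metasyrphus luniger",
    "Oedemeridae sp. 1",
    "Parnassius stubbendorfii",
    "Philopota nigroaenea",
    "Pristomyrmex pungens",
    "Vespidae sp. 1",
)

# Unweighted degrees, same order as the species tuples above.
_PLANT_DEGREES = (2, 10, 0, 5, 1, 2, 4, 5, 1, 1, 7, 4)
_POLLINATOR_DEGREES = (2, 3, 2, 1, 1, 2, 1, 1, 1, 2, 3, 8, 2, 5, 3, 2, 1, 1, 1)

# Timed visitation bouts of the effective pollinator (seconds).
_VISIT_DURATIONS_S = (55.0, 68.0, 60.0, 78.0, 67.0, 71.0, 57.0, 45.0)

_HOURLY_WINDOWS = (
    "0900-1000", "1000-1100", "1100-1200", "1200-1300",
    "1300-1400", "1400-1500", "1500-1600",
)
_HOURLY_DATES = ("2018-05-28", "2018-05-31", "2018-06-04")
_HOURLY_VISITS = (
    (0, 2, 2, 2, 1, 3, 0),
    (0, 0, 2, 1, 2, 3, 0),
    (0, 0, 0, 0, 0, 0, 0),
)

# Per-day network parameters: day -> (R, A, L, links_added, raw_nodf, max_nodf)
_DAILY_PARAMS = {
    146: (8, 14, 25, 0, 0.239, 0.598),
    147: (4, 3, 5, 3, 0.333, 0.889),
    149: (10, 9, 17, 3, 0.216, 0.469),
    154: (4, 8, 12, 1, 0.353, 0.647),
}

FLOWERING_START_DAY = 147
FLOWERING_END_DAY = 157


@dataclass(frozen=True)
class PaperFixture:
    """The printed summary data of the survey, as packaged constants."""

    plant_species: tuple[str, ...]
    pollinator_species: tuple[str, ...]
    plant_degrees: tuple[int, ...]
    pollinator_degrees: tuple[int, ...]
    visit_durations_s: tuple[float, ...]
    hourly_visits: pd.DataFrame  # dates x hourly windows
    daily_params: dict[int, tuple[int, int, int, int, float, float]]

    def daily_param_rows(self) -> list[tuple]:
        """(day, R, A, L, links_added, raw_nodf, max_nodf) rows, day-sorted."""
        return [(day, *p) for day, p in sorted(self.daily_params.items())]


def load_fixture() -> PaperFixture:
    """The packaged survey constants (species lists, degrees, durations,
    hourly visits, per-day network parameters)."""
    hourly = pd.DataFrame(
        np.array(_HOURLY_VISITS, dtype=int),
        index=list(_HOURLY_DATES),
        columns=list(_HOURLY_WINDOWS),
    )
    return PaperFixture(
        plant_species=_PLANTS,
        pollinator_species=_POLLINATORS,
        plant_degrees=_PLANT_DEGREES,
        pollinator_degrees=_POLLINATOR_DEGREES,
        visit_durations_s=_VISIT_DURATIONS_S,
        hourly_visits=hourly,
        daily_params=dict(_DAILY_PARAMS),
    )


def fixture_interactions_path():
    """Path to the shipped synthetic reconstruction CSV.

    The file is one binary realization of the printed degree sequences
    (seed ``RECONSTRUCTION_SEED``), not the observed visit matrix.
    """
    return resources.files("pollinet").joinpath("data/fixture_interactions_synthetic.csv")


def fixture_network(from_csv: bool = True, seed: int = RECONSTRUCTION_SEED) -> BipartiteNetwork:
    """Reconstructed fixture network with the printed degree sequences.

    With ``from_csv=True`` (default) the shipped CSV is loaded; otherwise
    the realization is regenerated from the degree sequences with ``seed``.
    The zero-degree plant is carried on the isolated-species register.
    """
    if from_csv:
        with resources.as_file(fixture_interactions_path()) as path:
            records = read_interactions_csv(path)
        net = build_network(records)
        # canonical order: plants as listed in the survey, pollinators
        # alphabetical (the CSV stores cells row-major, so rebuild order);
        # the zero-degree plant arrives via its zero-visit CSV row
        rows = [net.plant_labels.index(p) for p in _PLANTS if p in net.plant_labels]
        cols = [net.pollinator_labels.index(a) for a in _POLLINATORS]
        return BipartiteNetwork(
            tuple(net.plant_labels[i] for i in rows),
            tuple(net.pollinator_labels[j] for j in cols),
            net.weights[np.ix_(rows, cols)],
            net.isolated_plants, net.isolated_pollinators,
        )
    connected = [(p, k) for p, k in zip(_PLANTS, _PLANT_DEGREES) if k > 0]
    result = realize_degree_sequence(
        [k for _, k in connected], list(_POLLINATOR_DEGREES), seed=seed
    )
    if not result.feasible:
        raise RuntimeError(f"printed degree sequences infeasible: {result.reason}")
    iso = tuple(p for p, k in zip(_PLANTS, _PLANT_DEGREES) if k == 0)
    return BipartiteNetwork(
        tuple(p for p, _ in connected),
        _POLLINATORS,
        result.matrix,
        isolated_plants=iso,
    )
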