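"""Metric unit tests with independent brute-force oracles."""

import itertools
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinet import connectance, h2prime, links_per_species, nodf, unweighted_degree, wnodf
from pollinet.metrics import (
    _entropy,
    _h2max_table_greedy,
    _h2min_table_greedy,
    _iter_tables,
)
from pollinet.network import network_from_matrix

# ---------------------------------------------------------------------------
# oracles (independent, naive implementations)
# ---------------------------------------------------------------------------


def nodf_oracle(b):
    """Explicit pair enumeration with python sets."""
    b = np.asarray(b) > 0
    rows = [frozenset(np.flatnonzero(r)) for r in b]
    cols = [frozenset(np.flatnonzero(c)) for c in b.T]
    total, pairs = 0.0, 0
    for lines in (rows, cols):
        for x, y in itertools.combinations(lines, 2):
            pairs += 1
            if len(x) != len(y):
                small, big = sorted((x, y), key=len)
                total += len(small & big) / len(small)
    return total / pairs


def wnodf_oracle(m):
    m = np.asarray(m)

    def line_pairs(lines):
        total = 0.0
        for x, y in itertools.combinations(lines, 2):
            fx, fy = (x > 0).sum(), (y > 0).sum()
            if fx == fy:
                continue
            hi, lo = (x, y) if fx > fy else (y, x)
            total += sum(1 for v_hi, v_lo in zip(hi, lo) if v_lo > 0 and v_hi > v_lo) / (
                lo > 0
            ).sum()
        return total

    r, a = m.shape
    return (line_pairs(list(m)) + line_pairs(list(m.T))) / (
        r * (r - 1) / 2 + a * (a - 1) / 2
    )


# ---------------------------------------------------------------------------
# simple metrics
# ---------------------------------------------------------------------------


class TestConnectanceAndDegrees:
    def test_connectance_examples(self):
        assert connectance(network_from_matrix(np.ones((3, 4), dtype=int))) == 1.0
        assert connectance(network_from_matrix(np.eye(2, dtype=int))) == 0.5

    def test_links_per_species_examples(self):
        assert links_per_species(network_from_matrix([[1]])) == 0.5
        assert links_per_species(network_from_matrix(np.eye(2, dtype=int))) == 0.5

    def test_degree_counts_partners(self):
        net = network_from_matrix([[1, 1], [0, 1]])
        deg = unweighted_degree(net)
        assert [deg["plants"][p] for p in net.plant_labels] == [2, 1]
        assert [deg["pollinators"][a] for a in net.pollinator_labels] == [1, 2]


# ---------------------------------------------------------------------------
# NODF / WNODF
# ---------------------------------------------------------------------------


class TestNodf:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            ([[1, 1, 1], [1, 1, 0], [1, 0, 0]], 1.0),  # perfect subset chain
            (np.eye(3, dtype=int), 0.0),  # no overlap
            ([[1, 1, 1], [1, 1, 0], [1, 0, 0], [1, 0, 0]], 8 / 9),
        ],
    )
    def test_hand_computed_values(self, matrix, expected):
        assert nodf(matrix) == pytest.approx(expected)

    def test_percent_scale_is_x100(self):
        m = [[1, 1, 1], [1, 1, 0], [1, 0, 0], [1, 0, 0]]
        assert nodf(m, scale="percent") == pytest.approx(100 * nodf(m))

    def test_empty_line_rejected(self):
        with pytest.raises(ValueError):
            nodf([[1, 0], [0, 0]])

    def test_against_oracle_on_random_matrices(self, rng):
        checked = 0
        while checked < 200:
            r, a = rng.integers(2, 7, size=2)
            m = (rng.random((r, a)) < rng.uniform(0.2, 0.9)).astype(int)
            if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            assert nodf(m) == pytest.approx(nodf_oracle(m))
            checked += 1

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**30), st.integers(0, 2**30))
    def test_permutation_invariance(self, seed, perm_seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((5, 6)) < 0.6).astype(int)
        if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
            return
        prng = np.random.default_rng(perm_seed)
        pm = m[prng.permutation(5)][:, prng.permutation(6)]
        assert nodf(pm) == pytest.approx(nodf(m))
        assert wnodf(pm * 3) == pytest.approx(wnodf(m * 3))


class TestWnodf:
    def test_hand_computed_dominant_pair(self):
        assert wnodf([[5, 2], [1, 0]]) == 1.0

    def test_identical_rows_give_zero(self):
        assert wnodf([[1, 2], [1, 2], [1, 2]]) == 0.0

    def test_binary_wnodf_below_nodf(self, rng):
        for _ in range(50):
            m = (rng.random((4, 4)) < 0.6).astype(int)
            if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            assert wnodf(m) <= nodf(m) + 1e-12

    def test_against_oracle_on_random_weighted(self, rng):
        checked = 0
        while checked < 100:
            r, a = rng.integers(2, 7, size=2)
            m = (rng.random((r, a)) < 0.6) * rng.integers(1, 9, size=(r, a))
            if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            assert wnodf(m) == pytest.approx(wnodf_oracle(m))
            checked += 1


def test_nodf_and_wnodf_match_vegan(tmp_path, rng):
    """Cross-check against the reference R implementation (vegan)."""
    mats = []
    while len(mats) < 5:
        m = (rng.random((4, 5)) < 0.6) * rng.integers(1, 9, size=(4, 5))
        if m.sum(axis=1).all() and m.sum(axis=0).all():
            mats.append(m)
    script = ["library(vegan)"]
    for k, m in enumerate(mats):
        np.savetxt(tmp_path / f"m{k}.txt", m, fmt="%d")
        script.append(
            f'm <- as.matrix(read.table("{tmp_path}/m{k}.txt"));'
            "cat(sprintf('%.12f %.12f\\n', nestednodf(m>0, order=TRUE)$statistic['NODF'],"
            "nestednodf(m, order=TRUE, weighted=TRUE)$statistic['NODF']))"
        )
    out = subprocess.run(
        ["Rscript", "-e", "\n".join(script)], capture_output=True, text=True, check=True
    )
    for m, line in zip(mats, out.stdout.strip().splitlines()):
        ref_nodf, ref_wnodf = map(float, line.split())
        assert nodf(m, scale="percent") == pytest.approx(ref_nodf, abs=1e-6)
        assert wnodf(m, scale="percent") == pytest.approx(ref_wnodf, abs=1e-6)


# ---------------------------------------------------------------------------
# H2'
# ---------------------------------------------------------------------------


def enumerate_tables_oracle(row_totals, col_totals):
    """All integer tables with the given marginals, by direct recursion."""
    rows = list(row_totals)
    cols = list(col_totals)

    def rec(remaining_rows, crem):
        if not remaining_rows:
            yield ()
            return
        target = remaining_rows[0]
        ncol = len(crem)

        def row_fill(j, left, row):
            if j == ncol:
                if left == 0:
                    new_crem = tuple(c - v for c, v in zip(crem, row))
                    for rest in rec(remaining_rows[1:], new_crem):
                        yield (row,) + rest
                return
            for v in range(min(left, crem[j]) + 1):
                yield from row_fill(j + 1, left - v, row + (v,))

        yield from row_fill(0, target, ())

    yield from rec(rows, tuple(cols))


class TestH2prime:
    def test_diagonal_is_fully_specialized(self):
        assert h2prime([[5, 0], [0, 5]]).h2prime == 1.0

    def test_even_table_is_fully_generalized(self):
        assert h2prime([[5, 5], [5, 5]]).h2prime == 0.0

    def test_2x2_extremes_match_exhaustive_oracle(self):
        # marginals rows (6,4) x cols (5,5)
        entropies = [
            _entropy(np.array(t, dtype=float))
            for t in enumerate_tables_oracle([6, 4], [5, 5])
        ]
        res = h2prime([[4, 2], [1, 3]])
        assert res.extremes_method == "exhaustive"
        assert res.h2_max == pytest.approx(max(entropies))
        assert res.h2_min == pytest.approx(min(entropies))
        # extreme witnesses: [[3,3],[2,2]] most even, [[5,1],[0,4]] most concentrated
        assert res.h2_max == pytest.approx(_entropy(np.array([[3, 3], [2, 2.0]])))
        assert res.h2_min == pytest.approx(_entropy(np.array([[5, 1], [0, 4.0]])))
        assert res.h2prime == pytest.approx(0.2041, abs=1e-3)

    def test_internal_enumerator_agrees_with_oracle(self):
        got = sorted(tuple(map(tuple, t)) for t in _iter_tables((3, 2), (2, 2, 1), [10**6]))
        want = sorted(tuple(map(tuple, t)) for t in enumerate_tables_oracle([3, 2], [2, 2, 1]))
        assert got == want

    def test_greedy_heuristics_close_to_exhaustive(self, rng):
        """Greedy extremes are feasible tables bracketed by the true
        extremes, with a bounded quality gap (the even fill is near-exact;
        the concentration fill is the looser of the two)."""
        for _ in range(30):
            m = rng.integers(0, 6, size=(2, rng.integers(2, 4)))
            if m.sum() < 2 or not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            r, c = m.sum(axis=1), m.sum(axis=0)
            entropies = [
                _entropy(np.array(t, dtype=float)) for t in enumerate_tables_oracle(r, c)
            ]
            gmax = _entropy(_h2max_table_greedy(r, c))
            gmin = _entropy(_h2min_table_greedy(r, c))
            assert min(entropies) - 1e-9 <= gmin <= min(entropies) + 0.25
            assert max(entropies) - 0.05 <= gmax <= max(entropies) + 1e-9
            # greedy tables honor the marginals exactly
            t = _h2max_table_greedy(r, c)
            assert (t.sum(axis=1) == r).all() and (t.sum(axis=0) == c).all()

    def test_value_in_unit_interval_and_entropy_bracketed(self, rng):
        for _ in range(30):
            m = rng.integers(0, 7, size=(3, 3))
            if m.sum() < 2 or not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            res = h2prime(m)
            assert 0.0 <= res.h2prime <= 1.0
            assert res.h2_min - 1e-9 <= res.h2 <= res.h2_max + 0.05

    def test_large_independence_table_near_zero(self, rng):
        p_r = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        p_c = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        m = rng.multinomial(4000, np.outer(p_r, p_c).ravel()).reshape(5, 5)
        assert h2prime(m).h2prime < 0.05

    def test_zero_matrix_rejected_and_degenerate_warns(self):
        with pytest.raises(ValueError):
            h2prime(np.zeros((2, 2), dtype=int))
        with pytest.warns(UserWarning):
            assert h2prime([[7]]).h2prime == 0.0
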