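"""Completeness formulas, weighted richness, priority, and Jenks breaks."""

import itertools

import numpy as np
import pandas as pd
import pytest

import surveygap as sg
from surveygap.completeness import (assign_classes, cell_counts, collection_priority,
                                    incompleteness, jenks_breaks, summarize_cells,
                                    weighted_richness)
from surveygap.grids import GridSystem


def brute_force_jenks(values, k):
    """Exhaustive contiguous-partition oracle: min within-class SSD."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        total = sum(ssd(v[bounds[i]:bounds[i + 1]]) for i in range(k))
        if total < best[0] - 1e-12:
            best = (total, cuts)
    return best[0]


def jenks_cost(values, k):
    v = np.sort(np.asarray(values, dtype=float))
    breaks = jenks_breaks(values, k)
    cls = assign_classes(v, breaks)
    return sum(((v[cls == i] - v[cls == i].mean()) ** 2).sum()
               for i in np.unique(cls))


class TestIncompleteness:
    def test_ratio_formula(self):
        v_c, v_inc = incompleteness(91, 100)
        assert v_c == pytest.approx(0.91, abs=1e-12)
        assert v_inc == pytest.approx(0.09, abs=1e-12)

    def test_unsurveyed_and_complete_extremes(self):
        assert incompleteness(0, 10)[1] == pytest.approx(1.0)
        assert incompleteness(10, 10)[1] == pytest.approx(0.0)

    def test_empty_cell_is_missing_not_zero(self):
        v_c, v_inc = incompleteness(0, 0)
        assert np.isnan(v_c) and np.isnan(v_inc)

    def test_invariant_violation_raises(self):
        with pytest.raises(ValueError):
            incompleteness(5, 3)

    def test_adding_recorded_species_never_increases_v_inc(self):
        for s_o in range(0, 10):
            for s_r in range(max(s_o, 1), 12):
                base = incompleteness(s_o, s_r)[1]
                same_pool = incompleteness(s_o + 1, max(s_r, s_o + 1))[1]
                new_species = incompleteness(s_o + 1, s_r + 1)[1]
                assert same_pool <= base + 1e-12
                assert new_species <= base + 1e-12


class TestCellCounts:
    def test_union_counting(self):
        grid = GridSystem(1, 1, cell_size=10)
        counts = cell_counts({"a": {(0, 0)}, "b": {(0, 0)}},
                             {"b": {(0, 0)}, "c": {(0, 0)}}, grid)
        row = counts.iloc[0]
        assert (row.S_original, row.S_potential, row.S_r) == (2, 2, 3)

    def test_prediction_only_cell(self):
        grid = GridSystem(1, 1, cell_size=10)
        row = cell_counts({}, {"a": {(0, 0)}}, grid).iloc[0]
        assert (row.S_original, row.S_potential, row.S_r) == (0, 1, 1)

    def test_matches_brute_force_union_recount(self, landscape, species):
        rng = np.random.default_rng(0)
        grid = landscape.grid
        recorded = {
            sp.species_id: {c for c in sp.presence_cells() if rng.random() < 0.4}
            for sp in species}
        predicted = {sp.species_id: sp.presence_cells() for sp in species}
        counts = cell_counts(recorded, predicted, grid)
        for cell in [(0, 0), (5, 5), (10, 3), (19, 19)]:
            sr = sum(1 for sp in species
                     if cell in recorded[sp.species_id] | predicted[sp.species_id])
            assert counts.loc[cell[0] * grid.n_cols + cell[1], "S_r"] == sr


class TestWeightedRichness:
    def test_reciprocal_occupancy_sum(self):
        # species with occupancy 1, 2, 4 meeting in one cell
        cells = {"a": {(0, 0)}, "b": {(0, 0), (0, 1)},
                 "c": {(0, 0), (0, 1), (1, 0), (1, 1)}}
        wr = weighted_richness(cells)
        assert wr[(0, 0)] == pytest.approx(1.75, abs=1e-12)

    def test_single_cell_endemic(self):
        assert weighted_richness({"e": {(2, 3)}})[(2, 3)] == pytest.approx(1.0)

    def test_cosmopolitan_symmetry(self):
        all_cells = {(r, c) for r in range(3) for c in range(3)}
        wr = weighted_richness({f"s{i}": all_cells for i in range(6)})
        for cell in all_cells:
            assert wr[cell] == pytest.approx(6 / 9, abs=1e-12)

    def test_global_conservation(self, species):
        cells = {sp.species_id: sp.presence_cells() for sp in species}
        n_occupying = sum(1 for v in cells.values() if v)
        wr = weighted_richness(cells)
        assert sum(wr.values()) == pytest.approx(n_occupying, abs=1e-9)


class TestPriority:
    @pytest.mark.parametrize("wr,v_inc,expected", [
        (1.75, 0.2, 0.35), (3.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
    def test_product_formula(self, wr, v_inc, expected):
        assert collection_priority(wr, v_inc) == pytest.approx(expected, abs=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            collection_priority(-1.0, 0.5)
        with pytest.raises(ValueError):
            collection_priority(1.0, 1.5)


class TestJenks:
    def test_well_separated_clusters(self):
        breaks = jenks_breaks([1, 2, 3, 10, 11, 12], 2)
        cls = assign_classes([1, 2, 3, 10, 11, 12], breaks)
        assert list(cls) == [0, 0, 0, 1, 1, 1]

    def test_constant_vector_earliest_split(self):
        breaks = jenks_breaks([4.0] * 6, 2)
        assert breaks == [4.0]
        cls = assign_classes([4.0] * 6, breaks)
        assert set(cls) == {0}  # all at or below the break

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 2.0], 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        values = rng.uniform(0, 100, n)
        for k in (2, 3, 4):
            assert jenks_cost(values, k) == pytest.approx(
                brute_force_jenks(values, k), abs=1e-9)


class TestSummary:
    def test_hand_built_summary(self):
        grid = GridSystem(1, 2, cell_size=10)
        recorded = {"a": {(0, 0)}, "b": {(0, 0)}}
        predicted = {"b": {(0, 0), (0, 1)}, "c": {(0, 0)}}
        out = summarize_cells(recorded, predicted, grid, n_priority_classes=2)
        c0 = out.loc[0]
        assert (c0.S_original, c0.S_potential, c0.S_r) == (2, 2, 3)
        assert c0.V_inc == pytest.approx(1 / 3)
        # occupancies on the union: a->1, b->2, c->1
        assert c0.WR == pytest.approx(1 + 0.5 + 1)
        assert c0.P == pytest.approx(c0.WR * c0.V_inc)
        c1 = out.loc[1]
        assert c1.S_original == 0 and c1.V_inc == pytest.approx(1.0)

    def test_recorded_only_occupancy_mode(self):
        grid = GridSystem(1, 2, cell_size=10)
        recorded = {"a": {(0, 0)}}
        predicted = {"a": {(0, 0), (0, 1)}}
        union = summarize_cells(recorded, predicted, grid, occupancy_basis="union",
                                n_priority_classes=2)
        rec = summarize_cells(recorded, predicted, grid, occupancy_basis="recorded",
                              n_priority_classes=2)
        assert union.loc[0, "WR"] == pytest.approx(0.5)
        assert rec.loc[0, "WR"] == pytest.approx(1.0)
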