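import numpy as np
import pandas as pd
import pytest

import lymphomap as lm
from lymphomap.spots import (
    call_sample_spots,
    cooccurrence,
    segment_spots,
    spot_statistics,
)


def flood_fill(mask):
    """Brute-force 8-connectivity components of a boolean grid."""
    comps, seen = [], set()
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and (r, c) not in seen:
                stack, comp = [(r, c)], set()
                seen.add((r, c))
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < rows and 0 <= nc < cols
                                    and mask[nr, nc] and (nr, nc) not in seen):
                                seen.add((nr, nc))
                                stack.append((nr, nc))
                comps.append(comp)
    return comps


def grid_portrait(grid, pid="p"):
    grid = np.asarray(grid, dtype=float)
    return lm.Portrait(pid, grid.ravel(), grid.shape[0], grid.shape[1])


class TestSegmentSpots:
    def test_single_plateau(self):
        grid = np.zeros((5, 5)) - 0.1
        grid[1:3, 1:4] = 2.0
        spots = segment_spots(grid_portrait(grid), min_size=5)
        assert spots == [{(1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3)}]

    def test_no_overexpression_empty(self):
        spots = segment_spots(grid_portrait(-np.ones((4, 4))))
        assert spots == []

    def test_matches_bruteforce_flood_fill(self, rng):
        for _ in range(20):
            grid = rng.normal(size=(10, 10))
            p = grid_portrait(grid)
            got = segment_spots(p, threshold_frac=0.5, min_size=1)
            mask = grid > 0.5 * grid.max()
            expected = flood_fill(mask)
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_monotone_in_threshold(self, rng):
        grid = rng.normal(size=(12, 12))
        p = grid_portrait(grid)
        lo = segment_spots(p, threshold_frac=0.6, min_size=1)
        hi = segment_spots(p, threshold_frac=0.9, min_size=1)
        lo_units = set().union(*lo) if lo else set()
        hi_units = set().union(*hi) if hi else set()
        assert hi_units <= lo_units

    def test_min_size_discards_small(self):
        grid = np.zeros((6, 6))
        grid[0, 0] = 3.0  # singleton peak above threshold
        grid[3:5, 3:5] = 2.5  # plateau below 0.9 * 3.0 -> not segmented
        spots = segment_spots(grid_portrait(grid), min_size=2)
        assert spots == []

    def test_interpolated_units_excluded(self):
        grid = np.zeros((3, 5))
        grid[1, 0:2] = 2.0
        grid[1, 3:5] = 2.0
        bridge = np.zeros(15, dtype=bool)
        bridge[7] = True  # (1,2) would connect the two plateaus
        p = lm.Portrait("b", grid.ravel(), 3, 5, interpolated=bridge)
        p.values[7] = 2.0
        spots = segment_spots(p, min_size=2)
        assert len(spots) == 2


class TestSummaryMapAndCalls:
    def test_union_idempotent_single_spot(self, small_model):
        pre, model, portraits, groups = small_model
        g = list(groups.values())[0]
        once = lm.build_summary_map([g], model, pre, min_size=2)
        twice = lm.build_summary_map([g, g], model, pre, min_size=2)
        assert [m.units for m in once] == [m.units for m in twice]

    def test_labels_ordered_by_peak(self, small_model):
        pre, model, portraits, groups = small_model
        mods = lm.build_summary_map(list(groups.values()), model, pre,
                                    min_size=2)
        labels = [m.label for m in mods]
        assert labels == sorted(labels)[: len(labels)]
        peaks = [m.peak_value for m in mods]
        assert peaks == sorted(peaks, reverse=True)

    def test_modules_disjoint_and_connected(self, small_model):
        pre, model, portraits, groups = small_model
        mods = lm.build_summary_map(list(groups.values()), model, pre,
                                    min_size=2)
        seen = set()
        for m in mods:
            assert not (seen & m.units)
            seen |= m.units
            comps = flood_fill(_mask_of(m.units, model))
            assert len(comps) == 1

    def test_planted_modules_recovered(self, small_model, small_cohort):
        _, matrix, truth = small_cohort
        pre, model, portraits, groups = small_model
        mods = lm.build_summary_map(list(groups.values()), model, pre,
                                    min_size=2)
        for genes in truth.module_gene_map.values():
            best = max(
                len(set(m.genes) & set(genes)) / len(set(m.genes) | set(genes))
                for m in mods
            )
            assert best >= 0.7

    def test_flat_portrait_no_calls(self, small_model):
        pre, model, portraits, groups = small_model
        mods = lm.build_summary_map(list(groups.values()), model, pre,
                                    min_size=2)
        flat = lm.Portrait("flat", np.zeros(model.n_units), model.grid_rows,
                           model.grid_cols)
        assert call_sample_spots(mods, flat) == set()

    def test_sample_calls_match_planted_activation(self, small_model,
                                                   small_cohort):
        _, matrix, truth = small_cohort
        pre, model, portraits, groups = small_model
        mods = lm.build_summary_map(list(groups.values()), model, pre,
                                    min_size=2)
        # map detected labels to planted labels by gene overlap
        detected_to_planted = {}
        for m in mods:
            best = max(truth.module_gene_map,
                       key=lambda pl: len(set(m.genes)
                                          & set(truth.module_gene_map[pl])))
            detected_to_planted[m.label] = best
        hits = 0
        for s in matrix.sample_ids:
            called = call_sample_spots(mods, portraits[s], min_size=2)
            planted = {detected_to_planted[c] for c in called}
            hits += planted == set(truth.sample_active_modules[s])
        assert hits / matrix.n_samples >= 0.95


def _mask_of(units, model):
    mask = np.zeros((model.grid_rows, model.grid_cols), dtype=bool)
    for r, c in units:
        mask[r, c] = True
    return mask


class TestIncidenceStatistics:
    def make_incidence(self, rng, n=40, mods=("A", "B", "C")):
        return pd.DataFrame(
            rng.random((n, len(mods))) < 0.4,
            index=[f"s{i}" for i in range(n)],
            columns=list(mods),
        )

    def test_spot_statistics_bruteforce(self, rng):
        inc = self.make_incidence(rng)
        classes = pd.Series(
            ["u" if i < 20 else "v" for i in range(40)], index=inc.index
        )
        assoc, counts = spot_statistics(inc, classes)
        for cls in ("u", "v"):
            members = classes.index[classes == cls]
            for m in inc.columns:
                assert assoc.loc[cls, m] == pytest.approx(
                    inc.loc[members, m].mean()
                )
            np.testing.assert_allclose(counts.loc[cls].sum(), 1.0)
            spot_n = inc.loc[members].sum(axis=1)
            for k in counts.columns:
                assert counts.loc[cls, k] == pytest.approx(
                    (spot_n == k).mean()
                )

    def test_unknown_sample_errors(self, rng):
        inc = self.make_incidence(rng, n=4)
        with pytest.raises(KeyError):
            spot_statistics(inc, pd.Series({"s0": "u"}))

    def test_cooccurrence_bruteforce(self, rng):
        inc = self.make_incidence(rng)
        table = cooccurrence(inc).set_index(["module_i", "module_j"])
        n = len(inc)
        for mi in inc.columns:
            for mj in inc.columns:
                joint = (inc[mi] & inc[mj]).sum() / n
                row = table.loc[(mi, mj)]
                assert row["joint"] == pytest.approx(joint)
                pi, pj = inc[mi].mean(), inc[mj].mean()
                if pi > 0:
                    assert row["confidence"] == pytest.approx(joint / pi)
                if pi > 0 and pj > 0:
                    assert row["lift"] == pytest.approx(joint / (pi * pj))

    def test_cooccurrence_boundaries(self):
        inc = pd.DataFrame(
            {"A": [True] * 4, "B": [False] * 4},
            index=[f"s{i}" for i in range(4)],
        )
        table = cooccurrence(inc).set_index(["module_i", "module_j"])
        assert table.loc[("A", "A"), "joint"] == 1.0
        assert table.loc[("A", "A"), "lift"] == 1.0
        assert table.loc[("A", "B"), "joint"] == 0.0
        assert np.isnan(table.loc[("B", "B"), "lift"])
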