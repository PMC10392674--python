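"""Orientation grids, pair scans, exact mean-field ranking and the staged
sampling protocol."""
import numpy as np
import pytest

from gpcrforge.core import HelixBundle, build_ideal_helix
from gpcrforge.forcefield import interhelical_energy
from gpcrforge.sampling import (OrientationGrid, PairEnergyTable,
                                contact_pairs, default_bihelix_grid,
                                default_superbihelix_grid, diversity_select,
                                grid_combinations, mean_field_rank,
                                pair_energy_scan, rebuild_and_rescore,
                                superbihelix_protocol, RankedCombo)


class TestGrids:
    def test_coarse_grid_has_12_axial_rotations_per_helix(self):
        grid = default_bihelix_grid()
        assert all(grid.size(h) == 12 for h in grid.helix_ids)
        assert len(grid.helix_ids) == 7

    def test_fine_grid_has_75_orientations_per_helix(self):
        grid = default_superbihelix_grid()
        assert all(grid.size(h) == 75 for h in grid.helix_ids)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            OrientationGrid.uniform([1, 2], [0.0], [0.0], [])

    def test_combination_counts(self):
        # the coarse stage enumerates 12^7, the fine stage (3*5*5)^7
        assert grid_combinations(default_bihelix_grid()) == 12 ** 7
        assert grid_combinations(default_bihelix_grid()) == 35_831_808
        assert grid_combinations(default_superbihelix_grid()) == 75 ** 7
        assert grid_combinations(default_superbihelix_grid()) == \
            13_348_388_671_875

    def test_single_helix_count(self):
        grid = OrientationGrid.uniform([1], [0.0], [0.0],
                                       [0, 72, 144, 216, 288])
        assert grid_combinations(grid) == 5

    def test_count_matches_brute_force_enumeration(self):
        import itertools
        grid = OrientationGrid.uniform([1, 2, 3], [0.0, 10.0], [0.0],
                                       [0.0, 120.0, 240.0])
        n = sum(1 for _ in itertools.product(
            *[grid.orientations(h) for h in grid.helix_ids]))
        assert grid_combinations(grid) == n


class TestContactPairs:
    def _linear_bundle(self, spacing):
        helices = []
        for k in range(3):
            h = build_ideal_helix("A" * 10, helix_id=k + 1,
                                  start_index=1 + 100 * k)
            for a in h.atoms:
                a.coord = a.coord + np.array([k * spacing, 0.0, 0.0])
            helices.append(h)
        return HelixBundle(helices=helices)

    def test_linear_arrangement_nearest_neighbours_only(self):
        b = self._linear_bundle(10.0)
        assert contact_pairs(b, cutoff=14.0) == [(1, 2), (2, 3)]

    def test_all_pairs_at_large_cutoff(self):
        b = self._linear_bundle(10.0)
        assert contact_pairs(b, cutoff=50.0) == [(1, 2), (1, 3), (2, 3)]


class TestPairEnergyScan:
    def test_small_scan_matches_direct_calls(self, ff):
        h1 = build_ideal_helix("AKSAA", helix_id=1)
        h2 = build_ideal_helix("ADSAA", helix_id=2, start_index=101)
        for a in h2.atoms:
            a.coord = a.coord + np.array([9.0, 0.0, 0.0])
        b = HelixBundle(helices=[h1, h2])
        grid = OrientationGrid.uniform([1, 2], [0.0], [0.0], [0.0, 180.0])
        table = pair_energy_scan(b, (1, 2), grid, ff)
        from gpcrforge.core import apply_orientation
        for i, oi in enumerate(grid.orientations(1)):
            for j, oj in enumerate(grid.orientations(2)):
                two = HelixBundle(helices=[apply_orientation(h1, oi),
                                           apply_orientation(h2, oj)])
                direct = interhelical_energy(two, 1, 2, ff).total
                assert table.energies[i, j] == pytest.approx(direct, abs=1e-9)

    def test_far_pair_all_zero(self, ff):
        h1 = build_ideal_helix("AKSAA", helix_id=1)
        h2 = build_ideal_helix("ADSAA", helix_id=2, start_index=101)
        for a in h2.atoms:
            a.coord = a.coord + np.array([60.0, 0.0, 0.0])
        b = HelixBundle(helices=[h1, h2])
        grid = OrientationGrid.uniform([1, 2], [0.0], [0.0],
                                       [0.0, 90.0, 180.0])
        assert np.all(pair_energy_scan(b, (1, 2), grid, ff).energies == 0.0)


def _random_tables(rng, ids, size, pairs):
    grid = OrientationGrid.uniform(ids, [0.0], [0.0],
                                   list(np.arange(size) * 360.0 / size))
    tables = [PairEnergyTable(pair=pr, energies=rng.normal(size=(size, size)))
              for pr in pairs]
    return grid, tables


def _brute_force_rank(tables, ids, size, top_n):
    pos = {h: k for k, h in enumerate(ids)}
    E = np.zeros([size] * len(ids))
    for t in tables:
        i, j = t.pair
        shape = [1] * len(ids)
        shape[pos[i]] = size
        shape[pos[j]] = size
        E = E + t.energies.reshape(shape)
    flat = E.ravel()
    order = np.argsort(flat, kind="stable")[:top_n]
    return [tuple(np.unravel_index(k, E.shape)) for k in order], flat[order]


class TestMeanFieldRank:
    def test_two_helices_equals_sorted_table(self, rng):
        grid, tables = _random_tables(rng, [1, 2], 6, [(1, 2)])
        ranked = mean_field_rank(tables, grid, top_n=10)
        flat = np.sort(tables[0].energies.ravel())
        got = [r.estimated_energy for r in ranked]
        assert np.allclose(got, flat[:10], atol=1e-12)

    def test_exact_against_brute_force_chain(self, rng):
        # 4 helices x 4 orientations, chain contacts: 256 combinations
        ids = [1, 2, 3, 4]
        grid, tables = _random_tables(rng, ids, 4, [(1, 2), (2, 3), (3, 4)])
        ranked = mean_field_rank(tables, grid, top_n=10)
        combos, energies = _brute_force_rank(tables, ids, 4, 10)
        for r, combo, e in zip(ranked, combos, energies):
            assert tuple(r.indices[h] for h in ids) == combo
            assert r.estimated_energy == pytest.approx(e, abs=1e-9)

    def test_exact_against_brute_force_with_cycle(self, rng):
        ids = [1, 2, 3]
        grid, tables = _random_tables(rng, ids, 5,
                                      [(1, 2), (2, 3), (1, 3)])
        ranked = mean_field_rank(tables, grid, top_n=8)
        combos, energies = _brute_force_rank(tables, ids, 5, 8)
        got = [r.estimated_energy for r in ranked]
        assert np.allclose(got, energies, atol=1e-9)

    def test_best_first_search_matches_dense_path(self, rng):
        # large enough space (40^4 = 2.56e6) to engage best-first search
        ids = [1, 2, 3, 4]
        grid, tables = _random_tables(rng, ids, 40,
                                      [(1, 2), (2, 3), (3, 4), (1, 4)])
        ranked = mean_field_rank(tables, grid, top_n=25)
        combos, energies = _brute_force_rank(tables, ids, 40, 25)
        got = [r.estimated_energy for r in ranked]
        assert np.allclose(got, energies, atol=1e-9)
        assert tuple(ranked[0].indices[h] for h in ids) == combos[0]

    def test_separable_tables_argmin_componentwise(self, rng):
        ids = [1, 2, 3]
        size = 6
        f = {h: rng.normal(size=size) for h in ids}
        tables = [PairEnergyTable(pair=(i, j),
                                  energies=f[i][:, None] + f[j][None, :])
                  for i, j in [(1, 2), (2, 3)]]
        grid = OrientationGrid.uniform(ids, [0.0], [0.0],
                                       list(np.arange(size) * 60.0))
        best = mean_field_rank(tables, grid, top_n=1)[0]
        for h in ids:
            assert best.indices[h] == int(np.argmin(f[h]))

    def test_top_n_larger_than_space_returns_full_ranking(self, rng):
        grid, tables = _random_tables(rng, [1, 2], 3, [(1, 2)])
        ranked = mean_field_rank(tables, grid, top_n=1000)
        assert len(ranked) == 9

    def test_disconnected_graph_rejected(self, rng):
        grid, tables = _random_tables(rng, [1, 2, 3], 3, [(1, 2)])
        with pytest.raises(ValueError, match="connected"):
            mean_field_rank(tables, grid, top_n=5)


class TestDiversitySelect:
    def _fake(self, bundle, energy):
        return (bundle, RankedCombo(indices={}, estimated_energy=energy,
                                    rebuilt_energy=energy))

    def test_identical_structures_collapse_to_one(self, planted_bundle):
        bundle, _ = planted_bundle
        items = [self._fake(bundle, e) for e in (-5.0, -4.0, -3.0)]
        assert len(diversity_select(items, n=3)) == 1

    def test_two_separated_clusters_yield_one_each(self, planted_bundle):
        import copy
        bundle, _ = planted_bundle
        moved = copy.deepcopy(bundle)
        for a in (x for h in moved.helices for x in h.atoms):
            a.coord = a.coord + np.array([30.0, 0.0, 0.0])
        items = [self._fake(bundle, -5.0), self._fake(bundle, -4.9),
                 self._fake(moved, -4.8), self._fake(moved, -4.7)]
        chosen = diversity_select(items, n=2, energy_window=50.0,
                                  rmsd_threshold=2.0)
        assert len(chosen) == 2
        assert chosen[0][1].rebuilt_energy == -5.0
        assert chosen[1][1].rebuilt_energy == -4.8

    def test_output_never_exceeds_n(self, planted_bundle):
        bundle, _ = planted_bundle
        items = [self._fake(bundle, -5.0 + 0.1 * k) for k in range(6)]
        assert len(diversity_select(items, n=2)) <= 2


class TestProtocol:
    def test_planted_combo_recovered(self, ff, planted_bundle):
        bundle, truth = planted_bundle
        grid = default_bihelix_grid(range(1, 4))
        ensemble, log = superbihelix_protocol(
            bundle, grid=grid, p=ff, top_combos=20, ensemble_size=5,
            contact_cutoff=truth["contact_cutoff"], rebuild_top=10)
        top = {int(h): int(i) for h, i in ensemble[0][1].indices.items()}
        assert top == truth["planted_combo"]

    def test_stage_counts_logged(self, ff, planted_bundle):
        bundle, truth = planted_bundle
        grid = default_bihelix_grid(range(1, 4))
        ensemble, log = superbihelix_protocol(
            bundle, grid=grid, p=ff, top_combos=15, ensemble_size=4,
            contact_cutoff=truth["contact_cutoff"], rebuild_top=6)
        stages = dict(log.stages)
        assert stages["mean_field_rank"] == 15
        assert stages["rebuild"] == 6
        assert stages["diversity_select"] == len(ensemble) <= 4
        assert log.n_combinations == 12 ** 3

    def test_rebuild_deterministic(self, ff, planted_bundle):
        bundle, truth = planted_bundle
        grid = default_bihelix_grid(range(1, 4))
        from gpcrforge.sampling import contact_pairs, pair_energy_scan
        pairs = contact_pairs(bundle, cutoff=truth["contact_cutoff"])
        tables = [pair_energy_scan(bundle, pr, grid, ff) for pr in pairs]
        ranked = mean_field_rank(tables, grid, top_n=4)
        r1 = rebuild_and_rescore(bundle, ranked, ff, grid=grid)
        r2 = rebuild_and_rescore(bundle, ranked, ff, grid=grid)
        assert [c.rebuilt_energy for _, c in r1] == \
            [c.rebuilt_energy for _, c in r2]
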