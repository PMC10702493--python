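"""Patch extraction, effective distances and equivalent connected area."""

import numpy as np
import pytest

from fragcf.landscape import (
    DispersalSpec,
    Legend,
    LegendError,
    class_connectivity_summary,
    dispersal_matrix,
    dispersal_probability,
    equivalent_connected_area,
    extract_patches,
    pairwise_effective_distances,
    patch_distance,
    resistance_map_for_class,
)


def flood_fill_partition(mask, connectivity):
    """Brute-force connected components by BFS (independent of scipy.ndimage)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    comps = []
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        comp, stack = set(), [(int(r0), int(c0))]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            comp.add((r, c))
            for dr, dc in steps:
                nr, nc = r + dr, c + dc
                if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc] and not seen[nr, nc]):
                    seen[nr, nc] = True
                    stack.append((nr, nc))
        comps.append(frozenset(comp))
    return set(comps)


class TestExtractPatches:
    def test_single_block(self, make_grid, mini_legend):
        g = make_grid(np.full((3, 3), 1))
        patches = extract_patches(g, 1, mini_legend, connectivity=8)
        assert len(patches) == 1
        assert patches[0].area == pytest.approx(9 * g.cell_area)
        # all but the centre cell of a 3x3 block touch the outside
        assert len(patches[0].boundary_cells) == 8

    @pytest.mark.parametrize("conn,expected", [(4, 2), (8, 1)])
    def test_diagonal_cells(self, make_grid, mini_legend, conn, expected):
        codes = np.zeros((3, 3), int)
        codes[0, 0] = codes[1, 1] = 1
        g = make_grid(codes)
        assert len(extract_patches(g, 1, mini_legend, connectivity=conn)) == expected

    @pytest.mark.parametrize("conn", [4, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, make_grid, mini_legend, conn, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice([0, 1], size=(20, 20), p=[0.6, 0.4])
        g = make_grid(codes)
        patches = extract_patches(g, 1, mini_legend, connectivity=conn)
        got = {frozenset(map(tuple, p.cells)) for p in patches}
        assert got == flood_fill_partition(codes == 1, conn)

    def test_unknown_code_and_empty_class(self, make_grid, mini_legend):
        g = make_grid(np.zeros((3, 3), int))
        with pytest.raises(LegendError):
            extract_patches(g, 99, mini_legend)
        assert extract_patches(g, 1, mini_legend) == []


class TestPatchDistance:
    def test_adjacent_patches_one_cell_step(self, make_grid, mini_legend):
        codes = np.zeros((1, 4), int)
        codes[0, :2] = 1
        codes[0, 2:] = 2
        g = make_grid(codes, cell_size=10.0)
        a = extract_patches(g, 1, mini_legend)[0]
        b = extract_patches(g, 2, mini_legend)[0]
        assert patch_distance(a, b, g) == pytest.approx(10.0)

    def test_zero_resistance_equals_grid_euclidean(self, make_grid, mini_legend):
        codes = np.zeros((1, 7), int)
        codes[0, 0] = 1
        codes[0, 6] = 2
        g = make_grid(codes, cell_size=5.0)
        a = extract_patches(g, 1, mini_legend)[0]
        b = extract_patches(g, 2, mini_legend)[0]
        d_euclid = patch_distance(a, b, g)
        d_cost = patch_distance(a, b, g, resistance=np.zeros(g.shape))
        assert d_cost == pytest.approx(d_euclid)
        assert d_euclid == pytest.approx(6 * 5.0)

    def test_barrier_row_vs_dijkstra_oracle(self, make_grid, mini_legend):
        networkx = pytest.importorskip("networkx")
        codes = np.zeros((5, 5), int)
        codes[0, :] = 1
        codes[4, :] = 2
        g = make_grid(codes, cell_size=1.0)
        r = np.zeros((5, 5))
        r[2, :] = 1.0  # high-resistance barrier
        a = extract_patches(g, 1, mini_legend)[0]
        b = extract_patches(g, 2, mini_legend)[0]
        d_cost = patch_distance(a, b, g, resistance=r)
        assert d_cost >= patch_distance(a, b, g)

        # independent oracle: Dijkstra over the full cell graph via networkx
        G = networkx.Graph()
        cost = 1.0 + r
        for row in range(5):
            for col in range(5):
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    nr, nc = row + dr, col + dc
                    if 0 <= nr < 5 and 0 <= nc < 5:
                        w = (np.sqrt(2) if dr and dc else 1.0)
                        w *= 0.5 * (cost[row, col] + cost[nr, nc])
                        G.add_edge((row, col), (nr, nc), weight=w)
        best = min(
            networkx.dijkstra_path_length(G, tuple(u), tuple(v))
            for u in a.cells for v in b.cells
        )
        assert d_cost == pytest.approx(best, rel=1e-12)

    def test_overlapping_patches_error(self, make_grid, mini_legend):
        g = make_grid(np.full((2, 2), 1))
        p = extract_patches(g, 1, mini_legend)[0]
        with pytest.raises(ValueError):
            patch_distance(p, p, g)


class TestDispersalProbability:
    def test_kernel_contract(self):
        spec = DispersalSpec("plants", d_med=100.0)
        assert dispersal_probability(0.0, spec) == pytest.approx(1.0)
        assert dispersal_probability(100.0, spec) == pytest.approx(0.5)
        assert dispersal_probability(200.0, spec) == pytest.approx(0.25)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dispersal_probability(-1.0, DispersalSpec("plants", 100.0))

    def test_strictly_decreasing(self):
        spec = DispersalSpec("birds", d_med=5000.0)
        d = np.linspace(0, 50000, 100)
        p = dispersal_probability(d, spec)
        assert np.all(np.diff(p) < 0)


def random_patch_set(rng, n, cell_area=100.0):
    """Disjoint single-cell dummy patches with random areas for ECA tests."""
    from fragcf.landscape import Patch

    patches = []
    for i in range(n):
        cells = np.array([[i, 0]])
        patches.append(Patch(i + 1, "cropland", "minimal", cells,
                             float(rng.uniform(1, 50)) * cell_area, cells))
    return patches


class TestECA:
    def test_single_patch(self):
        rng = np.random.default_rng(0)
        (p,) = random_patch_set(rng, 1)
        assert equivalent_connected_area([p], np.ones((1, 1))) == pytest.approx(p.area)

    def test_two_patch_closed_forms(self):
        rng = np.random.default_rng(0)
        patches = random_patch_set(rng, 2)
        for p in patches:
            p.area = 40.0
        full = np.ones((2, 2))
        none = np.eye(2)
        assert equivalent_connected_area(patches, full) == pytest.approx(80.0)
        assert equivalent_connected_area(patches, none) == pytest.approx(40.0 * np.sqrt(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        patches = random_patch_set(rng, n)
        p = rng.uniform(0, 1, (n, n))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        areas = np.array([q.area for q in patches])
        oracle = np.sqrt(sum(
            areas[x] * areas[y] * p[x, y] for x in range(n) for y in range(n)
        ))
        got = equivalent_connected_area(patches, p)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(3)
        patches = random_patch_set(rng, 6)
        areas = np.array([q.area for q in patches])
        p = rng.uniform(0, 1, (6, 6))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        eca = equivalent_connected_area(patches, p)
        assert max(areas) <= eca <= areas.sum() + 1e-9
        # raising one off-diagonal probability cannot lower the ECA
        p2 = p.copy()
        p2[0, 1] = p2[1, 0] = min(1.0, p[0, 1] + 0.3)
        assert equivalent_connected_area(patches, p2) >= eca

    def test_splitting_a_patch_decreases_eca(self):
        from fragcf.landscape import Patch

        whole = [Patch(1, "c", "m", np.array([[0, 0]]), 100.0, np.array([[0, 0]]))]
        halves = [
            Patch(1, "c", "m", np.array([[0, 0]]), 50.0, np.array([[0, 0]])),
            Patch(2, "c", "m", np.array([[5, 0]]), 50.0, np.array([[5, 0]])),
        ]
        p = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert equivalent_connected_area(halves, p) < equivalent_connected_area(
            whole, np.ones((1, 1))
        )

    def test_dimension_mismatch_error(self):
        rng = np.random.default_rng(0)
        patches = random_patch_set(rng, 3)
        with pytest.raises(ValueError):
            equivalent_connected_area(patches, np.ones((2, 2)))


class TestClassConnectivitySummary:
    def test_fully_natural_grid(self, make_grid, mini_legend):
        g = make_grid(np.zeros((6, 6), int), cell_size=10.0)
        spec = DispersalSpec("plants", 100.0)
        out = class_connectivity_summary(g, mini_legend, spec)
        assert len(out) == 1
        assert out["eca"].iloc[0] == pytest.approx(g.area())
        assert out["total_area"].iloc[0] == pytest.approx(g.area())

    def test_single_block_class_fully_connected(self, make_grid, mini_legend):
        codes = np.zeros((6, 6), int)
        codes[:3, :3] = 1
        g = make_grid(codes, cell_size=10.0)
        out = class_connectivity_summary(g, mini_legend, DispersalSpec("plants", 50.0))
        row = out[out["land_use"] == "cropland"].iloc[0]
        assert row["eca"] == pytest.approx(row["total_area"])

    def test_eca_never_exceeds_area(self, small_world):
        from fragcf.landscape import DispersalSpec

        g = small_world.grids["eco00"]
        out = class_connectivity_summary(
            g, small_world.legend, DispersalSpec("plants", 800.0)
        )
        assert (out["eca"] <= out["total_area"] * (1 + 1e-12)).all()

    def test_resistance_never_increases_eca(self, make_grid, mini_legend):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2], size=(15, 15), p=[0.6, 0.2, 0.2])
        g = make_grid(codes, cell_size=10.0)
        spec = DispersalSpec("plants", 30.0)
        free = class_connectivity_summary(g, mini_legend, spec)
        rmaps = {
            c: resistance_map_for_class(g, mini_legend, c, {1: 0.9, 2: 0.9})
            for c in (0, 1, 2)
        }
        resisted = class_connectivity_summary(g, mini_legend, spec, rmaps)
        merged = free.merge(resisted, on=["land_use", "intensity"],
                            suffixes=("_free", "_res"))
        assert (merged["eca_res"] <= merged["eca_free"] * (1 + 1e-9)).all()
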