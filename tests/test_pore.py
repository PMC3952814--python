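"""Clearance lattice and widest-bottleneck path search, checked against a
brute-force threshold-percolation oracle."""

import numpy as np
import pytest

from fgbrush.models import AssemblyFrame, BathGeometry, ChainRecord, Trajectory, ValidationError
from fgbrush.pore import (
    ClearanceGrid,
    axial_pore_size,
    build_clearance_grid,
    export_pore_map,
    pore_size_stats,
    radial_pore_size,
    widest_bottleneck_path,
)
from fgbrush.synth import make_channel_phantom

from conftest import straight_chain


# ---------------------------------------------------------------------------
# independent oracle: for each candidate threshold t (the distinct clearance
# values), keep nodes with r >= t and test source->sink connectivity by BFS;
# the answer is the largest t that still percolates.

def oracle_bottleneck(clearance, source, sink, connectivity=6):
    from collections import deque

    dims = clearance.shape
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
            (0, 0, -1)]
    if connectivity == 26:
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    best = 0.0
    for t in sorted(np.unique(clearance), reverse=True):
        seen = set()
        queue = deque(s for s in source if clearance[s] >= t)
        seen.update(queue)
        ok = False
        while queue:
            node = queue.popleft()
            if node in sink:
                ok = True
                break
            for o in offs:
                nb = tuple(np.add(node, o))
                if all(0 <= nb[a] < dims[a] for a in range(3)) \
                        and nb not in seen and clearance[nb] >= t:
                    seen.add(nb)
                    queue.append(nb)
        if ok:
            best = float(t)
            break
    return best


def grid_from_field(field):
    field = np.asarray(field, dtype=float)
    return ClearanceGrid(origin=np.zeros(3), spacing=1.0, dims=field.shape,
                         clearance=field, margin_layers=0)


def faces(dims, axis=2):
    idx = np.indices(dims).reshape(3, -1).T
    source = [tuple(n) for n in idx if n[axis] == 0]
    sink = [tuple(n) for n in idx if n[axis] == dims[axis] - 1]
    return source, sink


class TestClearanceGrid:
    def test_point_mode_distance(self):
        bead = ChainRecord("A", "A", np.array([[0.0, 0.0, 0.0]]))
        frame = AssemblyFrame(chains=[bead])
        grid = build_clearance_grid(frame, spacing=1.0,
                                    bounds=(np.zeros(3), np.full(3, 4.0)),
                                    margin_layers=0)
        node = (3, 4, 0)
        assert np.isclose(grid.clearance[node], 5.0)

    def test_subtract_radii_mode(self):
        bead = ChainRecord("A", "A", np.array([[0.0, 0.0, 0.0]]))
        frame = AssemblyFrame(chains=[bead])
        grid = build_clearance_grid(frame, spacing=1.0,
                                    bead_radius_mode="subtract_radii",
                                    default_radius=2.0,
                                    bounds=(np.zeros(3), np.full(3, 4.0)),
                                    margin_layers=0)
        assert np.isclose(grid.clearance[(3, 4, 0)], 3.0)

    def test_matches_bruteforce_scan(self, rng):
        coords = rng.uniform(0, 20, size=(50, 3))
        frame = AssemblyFrame(chains=[ChainRecord("A", "A" * 50, coords)])
        grid = build_clearance_grid(frame, spacing=2.0)
        idx = np.indices(grid.dims).reshape(3, -1).T
        nodes = grid.origin[None, :] + idx * grid.spacing
        brute = np.linalg.norm(nodes[:, None, :] - coords[None, :, :],
                               axis=-1).min(axis=1)
        assert np.allclose(grid.clearance.ravel(), brute)

    def test_empty_frame_capped_at_diagonal(self):
        frame = AssemblyFrame(chains=[],
                              geometry=BathGeometry((100.0,) * 3, False))
        grid = build_clearance_grid(frame, spacing=10.0)
        assert np.all(grid.clearance >= 100.0)

    def test_bad_spacing(self):
        frame = AssemblyFrame(chains=[straight_chain("A", 3)])
        with pytest.raises(ValidationError):
            build_clearance_grid(frame, spacing=0.0)


class TestWidestPath:
    def test_single_corridor_min_rules(self):
        grid = grid_from_field(np.array([5.0, 9.0, 4.0, 7.0])
                               .reshape(1, 1, 4))
        res = widest_bottleneck_path(grid, [(0, 0, 0)], [(0, 0, 3)])
        assert res.bottleneck_radius == 4.0
        assert [n[2] for n in res.witness_path] == [0, 1, 2, 3]

    def test_max_over_two_corridors(self):
        field = np.zeros((3, 1, 3))
        field[0, 0] = [10.0, 3.0, 10.0]   # corridor with bottleneck 3
        field[2, 0] = [10.0, 6.0, 10.0]   # corridor with bottleneck 6
        grid = grid_from_field(field)
        res = widest_bottleneck_path(
            grid, [(0, 0, 0), (2, 0, 0)], [(0, 0, 2), (2, 0, 2)])
        assert res.bottleneck_radius == 6.0
        assert res.witness_path[0][0] == 2

    def test_disconnected_returns_zero(self):
        field = np.ones((1, 1, 5))
        field[0, 0, 2] = 0.0
        grid = grid_from_field(field)
        mask = field > 0
        res = widest_bottleneck_path(grid, [(0, 0, 0)], [(0, 0, 4)],
                                     allowed_mask=mask)
        assert res.bottleneck_radius == 0.0 and res.witness_path == []

    def test_witness_path_attains_bottleneck(self, rng):
        field = rng.uniform(0, 10, size=(9, 9, 9))
        grid = grid_from_field(field)
        source, sink = faces((9, 9, 9))
        res = widest_bottleneck_path(grid, source, sink)
        path_min = min(field[n] for n in res.witness_path)
        assert np.isclose(path_min, res.bottleneck_radius)
        # path is 6-connected and runs source -> sink
        assert res.witness_path[0][2] == 0 and res.witness_path[-1][2] == 8
        steps = np.abs(np.diff(np.asarray(res.witness_path), axis=0))
        assert np.all(steps.sum(axis=1) == 1)

    def test_equals_percolation_oracle(self, rng):
        for trial in range(25):
            dims = tuple(rng.integers(8, 13, size=3))
            field = rng.uniform(0, 1, size=dims)
            grid = grid_from_field(field)
            source, sink = faces(dims)
            got = widest_bottleneck_path(grid, source, sink).bottleneck_radius
            want = oracle_bottleneck(field, set(source), set(sink))
            assert got == want, f"trial {trial}: {got} != {want}"

    def test_26_connectivity_at_least_6(self, rng):
        field = rng.uniform(0, 1, size=(8, 8, 8))
        grid = grid_from_field(field)
        source, sink = faces((8, 8, 8))
        b6 = widest_bottleneck_path(grid, source, sink, 6).bottleneck_radius
        b26 = widest_bottleneck_path(grid, source, sink, 26).bottleneck_radius
        assert b26 >= b6
        assert b26 == oracle_bottleneck(field, set(source), set(sink), 26)

    def test_empty_or_overlapping_endpoints_rejected(self):
        grid = grid_from_field(np.ones((2, 2, 2)))
        with pytest.raises(ValidationError):
            widest_bottleneck_path(grid, [], [(0, 0, 1)])
        with pytest.raises(ValidationError):
            widest_bottleneck_path(grid, [(0, 0, 0)], [(0, 0, 0)])


class TestAxialPore:
    @pytest.mark.parametrize("radius", [5.0, 10.0, 20.0])
    def test_planted_radius_recovered(self, radius):
        frame, truth = make_channel_phantom(radius)
        res = axial_pore_size(frame, spacing=2.0)
        assert abs(res.bottleneck_radius - truth.planted_pore_radius) <= 2.0

    def test_serial_bottlenecks_smaller_governs(self):
        frame, truth = make_channel_phantom([12.0, 8.0])
        res = axial_pore_size(frame, spacing=2.0)
        assert truth.planted_pore_radius == 8.0
        assert abs(res.bottleneck_radius - 8.0) <= 2.0

    def test_solid_wall_blocks(self):
        frame, _ = make_channel_phantom(0.0)
        res = axial_pore_size(frame, spacing=2.0)
        assert res.bottleneck_radius <= 2.0

    def test_empty_box_bounded_by_domain(self):
        frame = AssemblyFrame(chains=[],
                              geometry=BathGeometry((100.0,) * 3, False))
        res = axial_pore_size(frame, spacing=10.0)
        assert res.bottleneck_radius >= 50.0

    def test_adding_beads_never_widens(self, rng):
        frame, _ = make_channel_phantom(10.0)
        base = axial_pore_size(frame, spacing=2.0).bottleneck_radius
        lo, hi = frame.bounding_box()
        last = base
        for _ in range(10):
            pos = rng.uniform(lo, hi)
            extra = ChainRecord("z9", "A", pos.reshape(1, 3))
            frame = AssemblyFrame(chains=frame.chains + [extra],
                                  geometry=frame.geometry)
            frame.chains[-1].chain_id = f"z{len(frame.chains)}"
            got = axial_pore_size(frame, spacing=2.0).bottleneck_radius
            assert got <= last + 1e-9
            last = got

    def test_resolution_convergence(self):
        frame, truth = make_channel_phantom(10.0, wall_bead_spacing=1.0)
        errs = [abs(axial_pore_size(frame, spacing=s).bottleneck_radius
                    - truth.planted_pore_radius)
                for s in (4.0, 2.0, 1.0)]
        assert errs[2] <= errs[0] + 1e-9
        assert errs[2] <= 1.0


class TestRadialPore:
    def test_ring_bore_recovered(self):
        frame, truth = make_channel_phantom(20.0, geometry="ring_bore")
        res = radial_pore_size(frame, spacing=2.0)
        assert abs(res.bottleneck_radius - 20.0) <= 2.0

    def test_solid_chamber_blocks(self):
        frame, _ = make_channel_phantom(0.0, geometry="ring_bore")
        res = radial_pore_size(frame, spacing=2.0)
        assert res.bottleneck_radius <= 2.0

    def test_requires_ring_geometry(self):
        frame = AssemblyFrame(chains=[straight_chain("A", 5)])
        with pytest.raises(ValidationError):
            radial_pore_size(frame)


class TestPoreStats:
    def test_identical_frames_zero_std(self):
        frame, _ = make_channel_phantom(10.0)
        traj = Trajectory(frames=[frame] * 3)
        res = pore_size_stats(traj, window=3, spacing=2.0)
        assert res.std == 0.0 and len(res.per_frame) == 3

    def test_mean_and_std_of_planted_series(self):
        frames = []
        for r in (10.0, 12.0, 14.0):
            fr, _ = make_channel_phantom(r)
            frames.append(fr)
        # frames differ in bead counts, so analyze one by one
        radii = [axial_pore_size(fr, spacing=2.0).bottleneck_radius
                 for fr in frames]
        assert abs(np.mean(radii) - 12.0) <= 2.0
        assert abs(np.std(radii, ddof=1) - 2.0) <= 2.0

    def test_oversized_window_rejected(self):
        frame, _ = make_channel_phantom(10.0)
        traj = Trajectory(frames=[frame])
        with pytest.raises(ValidationError):
            pore_size_stats(traj, window=5, spacing=2.0)


class TestPoreMap:
    def test_phantom_map_is_connected_along_axis(self, tmp_path):
        frame, _ = make_channel_phantom(40.0)
        grid = build_clearance_grid(frame, spacing=2.0)
        n = export_pore_map(grid, tmp_path / "map.pdb", min_radius=35.0)
        assert n > 0
        # exported set percolates along z within the phantom channel
        mask = grid.clearance >= 35.0
        import networkx as nx
        g = nx.Graph()
        idx = np.argwhere(mask)
        nodes = {tuple(n) for n in idx}
        for node in nodes:
            for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                nb = tuple(np.add(node, off))
                if nb in nodes:
                    g.add_edge(node, nb)
        comps = list(nx.connected_components(g))
        spans = [max(n[2] for n in c) - min(n[2] for n in c) for c in comps]
        assert max(spans) == grid.dims[2] - 1

    def test_solid_block_empty_map(self, tmp_path):
        frame, _ = make_channel_phantom(0.0)
        grid = build_clearance_grid(frame, spacing=2.0)
        assert export_pore_map(grid, tmp_path / "m.pdb", 35.0) == 0
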