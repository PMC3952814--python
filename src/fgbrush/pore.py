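"""Lattice-based pore-size characterization.

The frame is mapped onto a cubic lattice; each node g gets a clearance
radius r(g) — the radius of the largest sphere centred at g without steric
clash, computed as the shortest distance from g to any protein bead
(optionally minus per-bead radii).  A sphere can move along a lattice path
if its radius does not exceed the path's bottleneck, the smallest r(g) on
the path.  The pore size is the widest such bottleneck over all
source-to-sink paths, found with a maximin variant of Dijkstra's algorithm
(max-heap on clearance; the value of a node is the best achievable
minimum-clearance along any path reaching it).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .models import (
    AssemblyFrame,
    BathGeometry,
    FgBrushError,
    RingGeometry,
    Trajectory,
    ValidationError,
)

#: Face-neighbour offsets (6-connectivity).
_OFFSETS_6 = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]
])
_OFFSETS_26 = np.array([
    [dx, dy, dz]
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
])


@dataclass
class ClearanceGrid:
    """Cubic lattice of clearance radii over a frame.

    ``clearance[i, j, k]`` is r(g) in Angstrom at node
    ``origin + (i, j, k) * spacing``.  The grid covers the analysis domain
    plus ``margin_layers`` extra layers on each side; ``interior`` marks
    the nodes inside the domain proper (path searches honour it so that a
    sphere cannot trivially walk around the structure outside the original
    box walls).
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    clearance: np.ndarray
    bead_radius_mode: str = "point"
    margin_layers: int = 1

    def node_position(self, node: tuple[int, int, int]) -> np.ndarray:
        return self.origin + np.asarray(node, dtype=float) * self.spacing

    def interior_slices(self, free_axes: tuple[int, ...] = ()) -> np.ndarray:
        """Boolean mask of in-domain nodes; ``free_axes`` keep their margin
        layers usable (e.g. the permeation axis)."""
        mask = np.zeros(self.dims, dtype=bool)
        m = self.margin_layers
        sl = []
        for ax in range(3):
            if ax in free_axes or m == 0:
                sl.append(slice(None))
            else:
                sl.append(slice(m, self.dims[ax] - m))
        mask[tuple(sl)] = True
        return mask


@dataclass
class PoreResult:
    """Bottleneck radius (A), a witness path, and window statistics."""

    bottleneck_radius: float
    witness_path: list[tuple[int, int, int]] = field(default_factory=list)
    spacing: float | None = None
    per_frame: list[float] | None = None
    mean: float | None = None
    std: float | None = None


def build_clearance_grid(
    frame: AssemblyFrame,
    spacing: float = 2.0,
    bead_radius_mode: str = "point",
    radii: dict[str, float] | None = None,
    default_radius: float = 2.3,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    margin_layers: int = 1,
) -> ClearanceGrid:
    """Exact nearest-bead clearance field on a cubic lattice.

    The lattice covers ``bounds`` (default: the frame's domain, i.e. the
    box for bath geometry, else the bead bounding box) plus
    ``margin_layers`` extra layers.  In ``subtract_radii`` mode the
    per-bead radius (by bead kind) is subtracted and the result clamped at
    zero.  For an empty frame every node gets the domain diagonal.
    """
    if spacing <= 0:
        raise ValidationError("grid spacing must be positive")
    if bead_radius_mode not in ("point", "subtract_radii"):
        raise ValidationError(f"unknown bead_radius_mode {bead_radius_mode!r}")
    lo, hi = bounds if bounds is not None else frame.bounding_box()
    lo = np.asarray(lo, dtype=float) - margin_layers * spacing
    hi = np.asarray(hi, dtype=float) + margin_layers * spacing
    dims = tuple(int(math.floor((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    axes = [lo[a] + spacing * np.arange(dims[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    coords, _owners, kinds = frame.all_beads()
    if coords.shape[0] == 0:
        diag = float(np.linalg.norm(hi - lo))
        clearance = np.full(dims, diag)
        return ClearanceGrid(origin=lo, spacing=spacing, dims=dims,
                             clearance=clearance,
                             bead_radius_mode=bead_radius_mode,
                             margin_layers=margin_layers)
    if bead_radius_mode == "point":
        dist, _ = cKDTree(coords).query(nodes, k=1)
        clearance = np.asarray(dist, dtype=float)
    else:
        radii = radii or {}
        rad = np.array([radii.get(k, default_radius) for k in kinds])
        clearance = np.full(nodes.shape[0], np.inf)
        for r in np.unique(rad):
            sub = coords[rad == r]
            d, _ = cKDTree(sub).query(nodes, k=1)
            clearance = np.minimum(clearance, d - r)
        clearance = np.maximum(clearance, 0.0)
    return ClearanceGrid(origin=lo, spacing=spacing, dims=dims,
                         clearance=clearance.reshape(dims),
                         bead_radius_mode=bead_radius_mode,
                         margin_layers=margin_layers)


def widest_bottleneck_path(
    grid: ClearanceGrid,
    source_nodes,
    sink_nodes,
    connectivity: int = 6,
    allowed_mask: np.ndarray | None = None,
) -> PoreResult:
    """Maximin (widest-bottleneck) path from any source to any sink node.

    Dijkstra variant on the lattice: a max-heap keyed on the best-known
    bottleneck value B(v) = max over paths of min clearance along the path
    (endpoints included).  Ties are broken by flat node index so the
    witness path is reproducible.  Returns bottleneck 0 with an empty path
    when no source reaches a sink.
    """
    if connectivity == 6:
        offsets = _OFFSETS_6
    elif connectivity == 26:
        offsets = _OFFSETS_26
    else:
        raise ValidationError("connectivity must be 6 or 26")
    dims = grid.dims
    nx_, ny_, nz_ = dims
    n_total = nx_ * ny_ * nz_
    clear = grid.clearance.ravel()

    def flat(node) -> int:
        i, j, k = node
        return (i * ny_ + j) * nz_ + k

    source = [flat(s) for s in source_nodes]
    sinks = {flat(s) for s in sink_nodes}
    if not source or not sinks:
        raise ValidationError("source and sink node sets must be non-empty")
    if sinks & set(source):
        raise ValidationError("source and sink node sets must be disjoint")
    allowed = None if allowed_mask is None else allowed_mask.ravel()

    best = np.full(n_total, -1.0)
    parent = np.full(n_total, -1, dtype=np.int64)
    heap: list[tuple[float, int]] = []
    for s in source:
        if allowed is not None and not allowed[s]:
            continue
        if clear[s] > best[s]:
            best[s] = clear[s]
            heapq.heappush(heap, (-clear[s], s))
    strides = (offsets[:, 0] * ny_ + offsets[:, 1]) * nz_ + offsets[:, 2]
    done = np.zeros(n_total, dtype=bool)
    hit = -1
    while heap:
        negv, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u in sinks:
            hit = u
            break
        ui = u // (ny_ * nz_)
        uj = (u // nz_) % ny_
        uk = u % nz_
        for o, st in zip(offsets, strides):
            vi, vj, vk = ui + o[0], uj + o[1], uk + o[2]
            if not (0 <= vi < nx_ and 0 <= vj < ny_ and 0 <= vk < nz_):
                continue
            v = u + st
            if done[v] or (allowed is not None and not allowed[v]):
                continue
            cand = min(best[u], clear[v])
            if cand > best[v]:
                best[v] = cand
                parent[v] = u
                heapq.heappush(heap, (-cand, v))
    if hit < 0:
        return PoreResult(bottleneck_radius=0.0, witness_path=[],
                          spacing=grid.spacing)
    path = []
    v = hit
    while v >= 0:
        path.append((v // (ny_ * nz_), (v // nz_) % ny_, v % nz_))
        v = parent[v]
    path.reverse()
    return PoreResult(bottleneck_radius=float(best[hit]), witness_path=path,
                      spacing=grid.spacing)


def axial_pore_size(
    frame: AssemblyFrame,
    spacing: float = 2.0,
    axis: int = 2,
    connectivity: int = 6,
    bead_radius_mode: str = "point",
    **grid_kwargs,
) -> PoreResult:
    """Largest sphere that can pass the structure along ``axis`` (default z).

    Source and sink are the full entry and exit faces; the lateral margin
    layers beyond the original domain are excluded so the sphere cannot
    walk around the structure outside the box walls.
    """
    grid = build_clearance_grid(frame, spacing=spacing,
                                bead_radius_mode=bead_radius_mode,
                                **grid_kwargs)
    allowed = grid.interior_slices(free_axes=(axis,))
    n_ax = grid.dims[axis]
    idx = np.argwhere(allowed)
    source = [tuple(n) for n in idx[idx[:, axis] == 0]]
    sink = [tuple(n) for n in idx[idx[:, axis] == n_ax - 1]]
    return widest_bottleneck_path(grid, source, sink,
                                  connectivity=connectivity,
                                  allowed_mask=allowed)


def radial_pore_size(
    frame: AssemblyFrame,
    spacing: float = 2.0,
    connectivity: int = 6,
    inner_radius: float | None = None,
    outer_radius: float | None = None,
    outer_padding: float | None = None,
    core_fraction: float = 0.25,
    center: tuple[float, float] | None = None,
    bead_radius_mode: str = "point",
    **grid_kwargs,
) -> PoreResult:
    """Largest sphere that can move radially out of a ring-like structure.

    Source nodes lie inside a cylindrical core of radius
    ``core_fraction * inner_radius`` around the ring (z) axis; sink nodes
    lie at cylindrical radius ``outer_radius``, by default ``outer_padding``
    beyond the structure's outermost bead.  Because the bottleneck includes
    its endpoints, the lateral grid domain is padded so the sink shell sits
    in open space (a sphere must be able to *stand* at the sink, not just
    squeeze past the outer wall).  ``inner_radius`` defaults to the frame's
    ring geometry.
    """
    if inner_radius is None:
        if not isinstance(frame.geometry, RingGeometry):
            raise ValidationError(
                "radial pore analysis needs a ring geometry or explicit "
                "inner_radius"
            )
        inner_radius = frame.geometry.inner_radius
    coords = frame.all_backbone_coords()
    if coords.size == 0:
        raise ValidationError("radial pore analysis needs a non-empty frame")
    if outer_padding is None:
        outer_padding = max(4.0 * spacing, 0.4 * inner_radius)
    if "bounds" not in grid_kwargs:
        lo = coords.min(axis=0).copy()
        hi = coords.max(axis=0).copy()
        pad = outer_padding + 2.0 * spacing
        lo[:2] -= pad
        hi[:2] += pad
        grid_kwargs["bounds"] = (lo, hi)
    grid = build_clearance_grid(frame, spacing=spacing,
                                bead_radius_mode=bead_radius_mode,
                                **grid_kwargs)
    if center is None:
        cx, cy = coords[:, 0].mean(), coords[:, 1].mean()
    else:
        cx, cy = center
    if outer_radius is None:
        rho_beads = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
        outer_radius = float(rho_beads.max()) + outer_padding
    allowed = grid.interior_slices(free_axes=())
    idx = np.argwhere(allowed)
    pos = grid.origin[None, :] + idx * grid.spacing
    rho = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    core = core_fraction * inner_radius
    source = [tuple(n) for n, r in zip(idx, rho) if r <= core]
    sink = [tuple(n) for n, r in zip(idx, rho) if r >= outer_radius]
    if not source:
        raise ValidationError("no grid nodes inside the cylindrical core")
    if not sink:
        raise ValidationError("no grid nodes beyond outer_radius")
    return widest_bottleneck_path(grid, source, sink,
                                  connectivity=connectivity,
                                  allowed_mask=allowed)


def pore_size_stats(
    trajectory: Trajectory,
    window: int | None = None,
    mode: str = "axial",
    **kwargs,
) -> PoreResult:
    """Per-frame pore sizes over the trailing window, with mean and sample
    standard deviation."""
    frames = trajectory.window_frames(window)
    func = {"axial": axial_pore_size, "radial": radial_pore_size}.get(mode)
    if func is None:
        raise ValidationError(f"unknown mode {mode!r}")
    radii = [func(fr, **kwargs).bottleneck_radius for fr in frames]
    mean = float(np.mean(radii))
    std = float(np.std(radii, ddof=1)) if len(radii) > 1 else 0.0
    return PoreResult(bottleneck_radius=radii[-1], witness_path=[],
                      spacing=kwargs.get("spacing"), per_frame=radii,
                      mean=mean, std=std)


def export_pore_map(grid: ClearanceGrid, path, min_radius: float = 35.0) -> int:
    """Write all nodes with clearance >= ``min_radius`` as pseudo-atoms
    (PDB HETATM, B-factor = clearance) for visualization.  Returns the
    number of exported nodes."""
    from .io import write_points_pdb

    idx = np.argwhere(grid.clearance >= min_radius)
    pos = grid.origin[None, :] + idx * grid.spacing
    values = grid.clearance[tuple(idx.T)] if idx.size else np.empty(0)
    write_points_pdb(pos, values, path, res_name="POR")
    return idx.shape[0]
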