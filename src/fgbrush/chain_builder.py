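"""Construction of initial chain states for FG-nup assemblies.

Chains are built either fully extended (straight lines of backbone beads) or
as worm-like-chain self-avoiding walks (SAW): fixed bond length between
consecutive backbone beads, fixed bend angle for every bead triple, uniform
random dihedral, and an excluded-volume rule that rejects any bead closer
than a clash cutoff to a non-neighbouring bead of the same chain or to any
bead of another chain.

Defaults follow the coarse-grained coil conventions this kind of model uses:
3.7 A bond length, 127 deg bend angle (the MARTINI coil backbone angle) and
an 8 A close-contact cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .models import (
    AA_ALPHABET,
    ArrayGeometry,
    AssemblyFrame,
    BathGeometry,
    ChainRecord,
    FgBrushError,
    Motif,
    RingGeometry,
    Tether,
    ValidationError,
    make_chain_ids,
    minimum_image,
)

log = logging.getLogger(__name__)


class GrowthFailure(FgBrushError):
    """SAW growth exhausted its restart budget.

    Attributes
    ----------
    deepest_residue : int
        1-based index of the furthest residue ever placed successfully.
    """

    def __init__(self, message: str, deepest_residue: int):
        super().__init__(message)
        self.deepest_residue = deepest_residue


class InfeasibleDensityError(FgBrushError):
    """Requested packing is too dense for rejection sampling to succeed."""


@dataclass
class SawParams:
    """Parameters of the worm-like-chain self-avoiding walk.

    bond_length and clash_cutoff are in Angstrom, bend_angle in degrees.
    ``sequence_separation_exempt`` exempts bonded neighbours (and, by
    default, next-nearest neighbours, whose distance is fixed by the bend
    angle) from the clash rule; applied literally to all pairs the 8 A rule
    would reject every chain, since bonded beads sit at 3.7 A.
    """

    bond_length: float = 3.7
    bend_angle: float = 127.0
    clash_cutoff: float = 8.0
    sequence_separation_exempt: int = 2
    max_step_retries: int = 50
    backtrack_depth: int = 5
    max_chain_restarts: int = 100
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValidationError("bond_length must be positive")
        if self.clash_cutoff > self.bond_length and self.sequence_separation_exempt < 1:
            raise ValidationError(
                "clash_cutoff exceeds bond_length: bonded neighbours must be "
                "exempt (sequence_separation_exempt >= 1) or every chain is "
                "rejected"
            )
        if self.max_step_retries < 1 or self.max_chain_restarts < 1:
            raise ValidationError("retry/restart budgets must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


class NeighborGrid:
    """Uniform cell list for O(1) clash queries, optionally periodic.

    Cells are at least ``cutoff`` wide so a clash partner always lies in
    one of the 27 neighbouring cells.
    """

    def __init__(self, cutoff: float, box: np.ndarray | None = None):
        self.cutoff = float(cutoff)
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None:
            self.ncells = np.maximum(1, np.floor(self.box / self.cutoff)).astype(int)
            self.cell_size = self.box / self.ncells
        else:
            self.cell_size = np.full(3, self.cutoff)
        self.cells: dict[tuple[int, int, int], list[tuple[int, np.ndarray]]] = {}

    def _key(self, pos: np.ndarray) -> tuple[int, int, int]:
        p = np.asarray(pos, dtype=float)
        if self.box is not None:
            p = np.mod(p, self.box)
            idx = np.minimum((p / self.cell_size).astype(int), self.ncells - 1)
        else:
            idx = np.floor(p / self.cell_size).astype(int)
        return tuple(int(v) for v in idx)

    def add(self, pos: np.ndarray, tag: int) -> None:
        """Insert a bead; ``tag`` is the caller's identifier (e.g. residue
        index for own beads, -1 for obstacle beads)."""
        self.cells.setdefault(self._key(pos), []).append((tag, np.asarray(pos, float)))

    def remove(self, pos: np.ndarray, tag: int) -> None:
        key = self._key(pos)
        bucket = self.cells.get(key, [])
        for i, (t, p) in enumerate(bucket):
            if t == tag and np.array_equal(p, pos):
                del bucket[i]
                return
        raise KeyError(f"bead tag {tag} not found in grid")

    def neighbors(self, pos: np.ndarray):
        """Yield (tag, distance) for beads within cutoff of ``pos``."""
        base = self._key(pos)
        pos = np.asarray(pos, dtype=float)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = (base[0] + dx, base[1] + dy, base[2] + dz)
                    if self.box is not None:
                        key = tuple(int(k % n) for k, n in zip(key, self.ncells))
                    for tag, p in self.cells.get(key, ()):
                        d = pos - p
                        if self.box is not None:
                            d = minimum_image(d, self.box)
                        dist = float(np.linalg.norm(d))
                        if dist < self.cutoff:
                            yield tag, dist


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero direction vector")
    return np.asarray(v, dtype=float) / n


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u and to each other."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(u, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(u, e2)
    return e2, e3


def build_extended_chain(
    sequence: str,
    anchor: np.ndarray,
    direction: np.ndarray,
    bond_length: float = 3.7,
    chain_id: str = "A",
) -> ChainRecord:
    """Straight chain: residue i at ``anchor + (i-1) * bond_length * direction``."""
    if not sequence:
        raise ValidationError("empty sequence")
    u = _unit(direction)
    anchor = np.asarray(anchor, dtype=float)
    steps = np.arange(len(sequence))[:, None] * bond_length
    coords = anchor[None, :] + steps * u[None, :]
    return ChainRecord(chain_id=chain_id, sequence=sequence, coords=coords,
                       motifs=annotate_motifs(sequence))


def _place_next_bead(
    coords: list[np.ndarray],
    params: SawParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Candidate position for the next bead.

    With one prior bead the direction is uniform on the sphere; with two or
    more, the bend angle at the last bead is fixed and the dihedral is drawn
    uniformly on the allowed circle.
    """
    b = params.bond_length
    if len(coords) == 1:
        v = rng.normal(size=3)
        return coords[0] + b * _unit(v)
    p_prev, p_last = coords[-2], coords[-1]
    v1 = _unit(p_prev - p_last)
    e2, e3 = _orthonormal_frame(v1)
    theta = math.radians(params.bend_angle)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    w = (math.cos(theta) * v1
         + math.sin(theta) * (math.cos(phi) * e2 + math.sin(phi) * e3))
    return p_last + b * w


def grow_saw_chain(
    sequence: str,
    start_beads: np.ndarray,
    params: SawParams,
    existing_obstacles: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    chain_id: str = "A",
    z_floor: float | None = None,
    box: np.ndarray | None = None,
    obstacle_grid: NeighborGrid | None = None,
) -> ChainRecord:
    """Grow a self-avoiding worm-like chain from fixed seed beads.

    Beads are appended one at a time; a candidate is rejected if it clashes
    (distance < ``params.clash_cutoff``) with any obstacle bead or with an
    own bead of sequence separation > ``params.sequence_separation_exempt``,
    or falls below ``z_floor`` when one is given.  After
    ``params.max_step_retries`` failed dihedral draws the walk backtracks
    ``params.backtrack_depth`` residues; when backtracking reaches the seed,
    the whole chain is restarted (up to ``params.max_chain_restarts`` times)
    before :class:`GrowthFailure` is raised.

    Periodic growth: pass ``box``; all clash distances then use the
    minimum-image convention.

    The returned chain's ``coords[i]`` is the (i+1)-th grown bead; callers
    that tether the C-terminus reverse the ordering themselves.
    """
    if rng is None:
        rng = params.rng()
    seeds = np.asarray(start_beads, dtype=float).reshape(-1, 3)
    n = len(sequence)
    if seeds.shape[0] > n:
        raise ValidationError("more seed beads than residues")
    if obstacle_grid is not None:
        grid_obstacles = obstacle_grid
    else:
        grid_obstacles = NeighborGrid(params.clash_cutoff, box)
        if existing_obstacles is not None:
            for p in np.asarray(existing_obstacles, dtype=float).reshape(-1, 3):
                grid_obstacles.add(p, -1)

    n_seed = seeds.shape[0]
    exempt = params.sequence_separation_exempt
    deepest = n_seed

    def clashes(pos: np.ndarray, own_grid: NeighborGrid, own_index: int) -> bool:
        if z_floor is not None and pos[2] < z_floor:
            return True
        for _tag, _d in grid_obstacles.neighbors(pos):
            return True
        for tag, _d in own_grid.neighbors(pos):
            if own_index - tag > exempt:
                return True
        return False

    for restart in range(params.max_chain_restarts):
        coords: list[np.ndarray] = [s.copy() for s in seeds]
        own = NeighborGrid(params.clash_cutoff, box)
        for i, p in enumerate(coords):
            own.add(p, i)
        # a restart is abandoned once its backtrack budget is spent
        backtracks_left = 20 * max(1, n // max(1, params.backtrack_depth))
        while len(coords) < n:
            i = len(coords)
            placed = False
            for _ in range(params.max_step_retries):
                cand = _place_next_bead(coords, params, rng)
                if not clashes(cand, own, i):
                    coords.append(cand)
                    own.add(cand, i)
                    placed = True
                    break
            if placed:
                deepest = max(deepest, len(coords))
                continue
            # backtrack, but never remove seed beads
            depth = min(params.backtrack_depth, len(coords) - n_seed)
            if depth <= 0 or backtracks_left <= 0:
                break
            backtracks_left -= 1
            for _ in range(depth):
                idx = len(coords) - 1
                own.remove(coords[idx], idx)
                coords.pop()
        if len(coords) == n:
            return ChainRecord(chain_id=chain_id, sequence=sequence,
                               coords=np.asarray(coords),
                               motifs=annotate_motifs(sequence))
        log.debug("SAW restart %d for chain %s (reached %d/%d)",
                  restart + 1, chain_id, len(coords), n)
    raise GrowthFailure(
        f"chain {chain_id}: SAW failed after {params.max_chain_restarts} "
        f"restarts (deepest residue reached: {deepest} of {n})",
        deepest_residue=deepest,
    )


# ---------------------------------------------------------------------------
# Assembly builders

def _grow_tethered(
    sequence: str,
    anchor: np.ndarray,
    mode: str,
    params: SawParams,
    rng: np.random.Generator,
    chain_id: str,
    obstacle_grid: NeighborGrid,
    z_floor: float | None = 0.0,
) -> ChainRecord:
    """One chain with its C-terminal residue fixed at ``anchor``.

    The chain is grown (or laid out) from the tether outward, then the bead
    order is reversed so that ``coords[i]`` corresponds to ``sequence[i]``
    with the last residue at the anchor.
    """
    n = len(sequence)
    anchor = np.asarray(anchor, dtype=float)
    if mode == "extended":
        steps = np.arange(n)[:, None] * params.bond_length
        grown = anchor[None, :] + steps * np.array([[0.0, 0.0, 1.0]])
    elif mode == "saw":
        rec = grow_saw_chain(sequence, anchor[None, :], params, rng=rng,
                             chain_id=chain_id, z_floor=z_floor,
                             obstacle_grid=obstacle_grid)
        grown = rec.coords
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    coords = grown[::-1].copy()
    return ChainRecord(
        chain_id=chain_id, sequence=sequence, coords=coords,
        tether=Tether(anchor=tuple(anchor.tolist()), residue_index=n),
        motifs=annotate_motifs(sequence),
    )


def ring_anchor_positions(
    n_chains: int,
    n_rows: int,
    anchor_spacing: float,
    inner_radius: float | None = None,
    row_spacing: float = 60.0,
) -> tuple[np.ndarray, RingGeometry]:
    """Anchor points on ``n_rows`` concentric circles in the z = 0 plane.

    When ``inner_radius`` is None it is derived so that the chord between
    adjacent anchors of the innermost row equals ``anchor_spacing`` exactly:
    r = s / (2 sin(pi / n_per_row)).
    """
    if n_chains % n_rows != 0:
        raise ValidationError("n_chains must be divisible by n_rows")
    per_row = n_chains // n_rows
    if inner_radius is None:
        inner_radius = (anchor_spacing if per_row == 1 else
                        anchor_spacing / (2.0 * math.sin(math.pi / per_row)))
    geom = RingGeometry(inner_radius=inner_radius, row_spacing=row_spacing,
                        n_rows=n_rows, anchor_spacing=anchor_spacing)
    anchors = []
    for row in range(n_rows):
        r = inner_radius + row * row_spacing
        chord = 2.0 * r * math.sin(math.pi / per_row)
        if per_row > 1 and chord < anchor_spacing * 0.99:
            raise ValidationError(
                f"ring row {row} (radius {r:.1f} A) too small for {per_row} "
                f"anchors at {anchor_spacing} A spacing (chord {chord:.1f} A)"
            )
        angles = 2.0 * math.pi * np.arange(per_row) / per_row
        anchors.append(np.column_stack([
            r * np.cos(angles), r * np.sin(angles), np.zeros(per_row)
        ]))
    return np.vstack(anchors), geom


def _build_anchored_assembly(
    sequence: str,
    anchors: np.ndarray,
    geometry,
    mode: str,
    params: SawParams,
    rng: np.random.Generator,
) -> AssemblyFrame:
    """Grow one chain per anchor; SAW chains are grown sequentially in a
    randomized order, each seeing all previously grown chains as obstacles."""
    ids = make_chain_ids(len(anchors))
    order = np.arange(len(anchors))
    if mode == "saw":
        order = rng.permutation(order)
    obstacle_grid = NeighborGrid(params.clash_cutoff)
    chains: dict[int, ChainRecord] = {}
    for k in order:
        rec = _grow_tethered(sequence, anchors[k], mode, params, rng,
                             chain_id=ids[k], obstacle_grid=obstacle_grid)
        for p in rec.coords:
            obstacle_grid.add(p, -1)
        chains[int(k)] = rec
    frame = AssemblyFrame(chains=[chains[k] for k in sorted(chains)],
                          geometry=geometry)
    frame.validate()
    return frame


def place_ring_assembly(
    sequence: str,
    n_chains: int = 120,
    n_rows: int = 3,
    anchor_spacing: float = 60.0,
    inner_radius: float | None = None,
    row_spacing: float = 60.0,
    mode: str = "extended",
    params: SawParams | None = None,
    rng: np.random.Generator | None = None,
) -> AssemblyFrame:
    """Chains grafted by their C-termini to concentric rings (NPC-mimetic
    nanopore layout): default 120 chains in 3 rows at 60 A spacing."""
    params = params or SawParams()
    rng = rng if rng is not None else params.rng()
    anchors, geom = ring_anchor_positions(n_chains, n_rows, anchor_spacing,
                                          inner_radius, row_spacing)
    return _build_anchored_assembly(sequence, anchors, geom, mode, params, rng)


def place_array_assembly(
    sequence: str,
    nx: int = 5,
    ny: int = 5,
    grid_spacing: float = 60.0,
    mode: str = "saw",
    params: SawParams | None = None,
    rng: np.random.Generator | None = None,
) -> AssemblyFrame:
    """Chains end-tethered on an ``nx x ny`` rectangular grid in the z = 0
    plane, growing into the +z half-space."""
    if nx < 1 or ny < 1:
        raise ValidationError("nx and ny must be >= 1")
    params = params or SawParams()
    rng = rng if rng is not None else params.rng()
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    anchors = np.column_stack([
        xs.ravel() * grid_spacing, ys.ravel() * grid_spacing,
        np.zeros(nx * ny)
    ])
    geom = ArrayGeometry(nx=nx, ny=ny, grid_spacing=grid_spacing)
    return _build_anchored_assembly(sequence, anchors, geom, mode, params, rng)


def place_bath_assembly(
    sequence: str,
    n_chains: int = 120,
    box_edge: float | tuple[float, float, float] = 725.0,
    params: SawParams | None = None,
    rng: np.random.Generator | None = None,
    max_packing_fraction: float = 0.35,
) -> AssemblyFrame:
    """Untethered self-avoiding chains in a periodic box.

    Each chain starts from a rigid three-bead seed (proper bond length and
    bend angle) placed at a uniform random position and orientation, then
    grows as a SAW seeing all previously grown chains as minimum-image
    obstacles.
    """
    params = params or SawParams()
    rng = rng if rng is not None else params.rng()
    box = np.asarray([box_edge] * 3 if np.isscalar(box_edge) else box_edge,
                     dtype=float)
    # rejection sampling becomes hopeless once the excluded volume of the
    # beads approaches a random-packing fraction
    vol_per_bead = (4.0 / 3.0) * math.pi * (params.clash_cutoff / 2.0) ** 3
    packing = n_chains * len(sequence) * vol_per_bead / float(np.prod(box))
    if packing > max_packing_fraction:
        raise InfeasibleDensityError(
            f"attempted packing fraction {packing:.2f} exceeds "
            f"{max_packing_fraction:.2f}; growth would not terminate"
        )
    if len(sequence) < 3:
        raise ValidationError("bath chains need at least 3 residues for the seed")

    obstacle_grid = NeighborGrid(params.clash_cutoff, box)
    ids = make_chain_ids(n_chains)
    chains: list[ChainRecord] = []
    theta = math.radians(params.bend_angle)
    b = params.bond_length
    # template seed: three beads with the proper bond length and bend angle
    seed_template = np.array([
        [0.0, 0.0, 0.0],
        [b, 0.0, 0.0],
        [b - b * math.cos(theta), b * math.sin(theta), 0.0],
    ])
    for cid in ids:
        for attempt in range(params.max_chain_restarts):
            origin = rng.uniform(0.0, 1.0, size=3) * box
            rot = Rotation.random(random_state=rng).as_matrix()
            seeds = origin + seed_template @ rot.T
            ok = all(
                next(iter(obstacle_grid.neighbors(p)), None) is None
                for p in seeds
            )
            if not ok:
                continue
            try:
                rec = grow_saw_chain(sequence, seeds, params, rng=rng,
                                     chain_id=cid, box=box,
                                     obstacle_grid=obstacle_grid)
            except GrowthFailure:
                continue
            for p in rec.coords:
                obstacle_grid.add(p, -1)
            chains.append(rec)
            break
        else:
            raise GrowthFailure(
                f"bath chain {cid} could not be placed", deepest_residue=0
            )
    frame = AssemblyFrame(chains=chains,
                          geometry=BathGeometry(tuple(box), periodic=True))
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# Sequence operations

def mutate_fg_to_ala(sequence: str) -> str:
    """Replace every phenylalanine and glycine by alanine (FG->AA mutant)."""
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ValidationError(f"non-amino-acid letters {sorted(bad)}")
    return sequence.translate(str.maketrans("FG", "AA"))


def annotate_motifs(sequence: str) -> list[Motif]:
    """Left-to-right non-overlapping scan for FxFG and FG motifs.

    At a given locus the four-residue FxFG pattern (F, any, F, G) takes
    precedence over a plain FG; matched residues are consumed, so motif
    spans never overlap.  Start indices are 1-based.
    """
    motifs: list[Motif] = []
    i = 0
    n = len(sequence)
    while i < n:
        if (i + 3 < n and sequence[i] == "F" and sequence[i + 2] == "F"
                and sequence[i + 3] == "G"):
            motifs.append(Motif("FxFG", i + 1))
            i += 4
        elif i + 1 < n and sequence[i] == "F" and sequence[i + 1] == "G":
            motifs.append(Motif("FG", i + 1))
            i += 2
        else:
            i += 1
    return motifs


#: Spacer composition of a typical FG domain between motifs: rich in small
#: polar residues, no F (so motifs are exactly where they were planted).
_SPACER_AA = "STNQAP"
_SPACER_W = np.array([0.28, 0.18, 0.18, 0.14, 0.14, 0.08])


def make_fg_sequence(
    length: int = 609,
    rng: np.random.Generator | None = None,
    motif_kinds: tuple[str, ...] = ("FSFG", "FG", "GLFG"),
    spacer_range: tuple[int, int] = (8, 16),
) -> str:
    """Synthetic FG-rich sequence: planted FG/FxFG-type repeats separated by
    random polar spacers.  Stands in for a natural FG domain; any real
    one-letter sequence is equally accepted by every builder."""
    rng = rng if rng is not None else np.random.default_rng()
    parts: list[str] = []
    total = 0
    while total < length:
        spacer_len = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        spacer = "".join(rng.choice(list(_SPACER_AA), size=spacer_len,
                                    p=_SPACER_W / _SPACER_W.sum()))
        motif = str(rng.choice(list(motif_kinds)))
        parts.append(spacer)
        parts.append(motif)
        total += spacer_len + len(motif)
    return "".join(parts)[:length]
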