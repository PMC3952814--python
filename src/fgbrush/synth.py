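"""Synthetic assemblies with known ground truth.

Three fixture families make the analysis modules testable without MD
trajectories: parallel-chain bundles planted on a close-packed lattice,
brushes of bundles joined by single cross-linking chains, and bead-wall
channel phantoms whose narrowest cross-section has a known clearance
radius.  Walls are built from beads (not analytic surfaces) so the pore
algorithm is exercised through exactly the same code path as real frames.

Ground truth uses the same residue addressing (chain_id, 1-based index) as
the analysis outputs, so comparisons are set equalities.  Truth labels are
derived from the construction geometry — which residues were built in
contact — plus the one-residue sequence-adjacency widening that the contact
graph applies to contact endpoints; they are never computed by running the
analysis code itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    AssemblyFrame,
    BathGeometry,
    ChainRecord,
    Residue,
    RingGeometry,
    ValidationError,
    make_chain_ids,
)

#: Filler residues for fixture sequences: small polar letters, no F or G,
#: so motif annotation finds exactly what a test plants.
_FILLER = "SANQT"


def _filler_sequence(n: int) -> str:
    return (_FILLER * (n // len(_FILLER) + 1))[:n]


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic frame."""

    bundle_membership: dict[Residue, str]  # bundle id or "crosslink"
    bundle_thicknesses: dict[str, int]
    crosslink_events: list[tuple[str, tuple[int, int], str, str]] = field(
        default_factory=list)
    planted_pore_radius: float | None = None

    def validate(self) -> None:
        per_bundle_chains: dict[str, set[str]] = {}
        for (cid, _), bid in self.bundle_membership.items():
            if bid != "crosslink":
                per_bundle_chains.setdefault(bid, set()).add(cid)
        for bid, chains in per_bundle_chains.items():
            if self.bundle_thicknesses.get(bid) != len(chains):
                raise ValidationError(
                    f"planted thickness of {bid} inconsistent with membership"
                )


def hex_lattice_points(n: int, pitch: float) -> np.ndarray:
    """First ``n`` sites of a triangular (close-packed) lattice, nearest the
    origin; nearest-neighbour distance is exactly ``pitch``."""
    pts = []
    extent = int(math.ceil(math.sqrt(n))) + 2
    for i in range(-extent, extent + 1):
        for j in range(-extent, extent + 1):
            x = pitch * (i + 0.5 * (j % 2))
            y = pitch * j * math.sqrt(3.0) / 2.0
            pts.append((x, y))
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p))
    return np.asarray(pts[:n])


def make_planted_bundle(
    k_chains: int,
    n_residues: int,
    lateral_spacing: float = 5.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    bond_length: float = 3.7,
    contact_cutoff: float = 6.0,
    rng: np.random.Generator | None = None,
    chain_ids: list[str] | None = None,
    sequence: str | None = None,
) -> tuple[AssemblyFrame, PlantedTruth]:
    """``k_chains`` straight parallel chains along z on a close-packed
    lattice of pitch ``lateral_spacing``.

    Truth: one bundle of thickness k when k >= 2 and the pitch is below
    ``contact_cutoff``; otherwise everything is cross-linking region (a
    bundle needs multiple chains in contact).
    """
    if k_chains < 1 or lateral_spacing <= 0:
        raise ValidationError("k_chains >= 1 and lateral_spacing > 0 required")
    seq = sequence or _filler_sequence(n_residues)
    ids = chain_ids or make_chain_ids(k_chains)
    sites = hex_lattice_points(k_chains, lateral_spacing)
    origin = np.asarray(origin, dtype=float)
    chains = []
    z = np.arange(n_residues) * bond_length
    for cid, (x, y) in zip(ids, sites):
        coords = np.column_stack([
            np.full(n_residues, origin[0] + x),
            np.full(n_residues, origin[1] + y),
            origin[2] + z,
        ])
        chains.append(ChainRecord(chain_id=cid, sequence=seq, coords=coords))
    frame = AssemblyFrame(chains=chains)
    frame.validate()
    bundled = k_chains >= 2 and lateral_spacing < contact_cutoff
    membership = {
        (cid, i + 1): ("B0" if bundled else "crosslink")
        for cid in ids[:k_chains] for i in range(n_residues)
    }
    truth = PlantedTruth(
        bundle_membership=membership,
        bundle_thicknesses={"B0": k_chains} if bundled else {},
    )
    truth.validate()
    return frame, truth


@dataclass
class BundleSpec:
    """One planted bundle: chain count, residues per chain, xy centre."""

    k_chains: int
    n_residues: int
    center: tuple[float, float] | None = None


@dataclass
class CrosslinkSpec:
    """One cross-linking chain from bundle ``a`` to bundle ``b`` (may be
    equal: the chain loops back to the bundle it left)."""

    a: int
    b: int


def make_crosslinked_brush(
    bundle_specs: list[BundleSpec],
    crosslink_specs: list[CrosslinkSpec] | None = None,
    lateral_spacing: float = 5.0,
    bond_length: float = 3.7,
    contact_cutoff: float = 6.0,
    clearance_margin: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[AssemblyFrame, PlantedTruth]:
    """Bundles of parallel chains plus single chains that leave one bundle,
    traverse free space above the brush, and join another bundle.

    Every traversal bead is kept at least ``contact_cutoff +
    clearance_margin`` away from all other chains, so the planted
    decomposition is stable for any analysis cutoff within the margin.
    Truth thicknesses count the cross-linking chain in both bundles it
    touches; the one sequence neighbour on each side of a contact run is
    counted into the bundle (the contact graph's adjacency rule pulls it
    in).
    """
    crosslink_specs = crosslink_specs or []
    if len(crosslink_specs) > 2:
        raise ValidationError("at most 2 cross-link chains are supported")
    n_b = len(bundle_specs)
    if n_b < 1:
        raise ValidationError("at least one bundle spec required")
    for xs in crosslink_specs:
        if not (0 <= xs.a < n_b and 0 <= xs.b < n_b):
            raise ValidationError("crosslink spec names an unknown bundle")

    # bundle extents and automatic centre placement along x
    extents = [lateral_spacing * (1.0 + math.sqrt(sp.k_chains)) for sp in bundle_specs]
    centers: list[np.ndarray] = []
    cursor = 0.0
    for sp, ext in zip(bundle_specs, extents):
        if sp.center is not None:
            centers.append(np.asarray(sp.center, dtype=float))
        else:
            centers.append(np.array([cursor, 0.0]))
            cursor += ext + 6.0 * (contact_cutoff + clearance_margin)
    # feasibility: chains of different bundles must stay clearly separated
    for i in range(n_b):
        for j in range(i + 1, n_b):
            gap = (np.linalg.norm(centers[i] - centers[j])
                   - extents[i] / 2.0 - extents[j] / 2.0)
            if gap < contact_cutoff + clearance_margin:
                raise ValidationError(
                    f"bundles {i} and {j} too close ({gap:.1f} A gap) for "
                    f"cutoff {contact_cutoff} + margin {clearance_margin}"
                )

    n_chains_total = sum(sp.k_chains for sp in bundle_specs) + len(crosslink_specs)
    ids = make_chain_ids(n_chains_total)
    next_id = 0
    chains: list[ChainRecord] = []
    membership: dict[Residue, str] = {}
    thick: dict[str, int] = {}
    events: list[tuple[str, tuple[int, int], str, str]] = []

    site_map: list[np.ndarray] = []
    for b_idx, sp in enumerate(bundle_specs):
        bid = f"B{b_idx}"
        sites = hex_lattice_points(sp.k_chains, lateral_spacing) + centers[b_idx]
        site_map.append(sites)
        z = np.arange(sp.n_residues) * bond_length
        seq = _filler_sequence(sp.n_residues)
        for x, y in sites:
            cid = ids[next_id]
            next_id += 1
            coords = np.column_stack([np.full_like(z, x), np.full_like(z, y), z])
            chains.append(ChainRecord(chain_id=cid, sequence=seq, coords=coords))
            for i in range(sp.n_residues):
                membership[(cid, i + 1)] = bid
        thick[bid] = sp.k_chains

    heights = [(sp.n_residues - 1) * bond_length for sp in bundle_specs]
    safe = contact_cutoff + clearance_margin
    for x_idx, xs in enumerate(crosslink_specs):
        cid = ids[next_id]
        next_id += 1
        sp_a, sp_b = bundle_specs[xs.a], bundle_specs[xs.b]
        c_a, c_b = centers[xs.a], centers[xs.b]
        if xs.a == xs.b:
            u = np.array([1.0, 0.0])
        else:
            u = c_b - c_a
            u = u / np.linalg.norm(u)
        # contact columns sit one lattice pitch outside the outermost chain
        # of each bundle; the second cross-link chain uses the opposite
        # sides so that the two free-space paths stay > cutoff + margin
        # apart everywhere
        side = 1.0 if x_idx % 2 == 0 else -1.0
        proj_a = site_map[xs.a] @ (side * u)
        edge_a = site_map[xs.a][int(np.argmax(proj_a))]
        q_a = edge_a + lateral_spacing * side * u
        proj_b = site_map[xs.b] @ (-side * u)
        edge_b = site_map[xs.b][int(np.argmax(proj_b))]
        q_b = edge_b - lateral_spacing * side * u
        h_a, h_b = heights[xs.a], heights[xs.b]
        # traverse lane above everything; stacked lanes for the second chain
        z_trav = max(heights) + safe + 2.6 + (safe + 2.0) * x_idx

        beads: list[np.ndarray] = []
        # ascending contact run in bundle a
        for i in range(sp_a.n_residues):
            beads.append(np.array([q_a[0], q_a[1], i * bond_length]))
        n_contact_a = sp_a.n_residues
        # departure: step away from the bundle while climbing
        away_xy = q_a + side * u * 3.0
        p = np.array([away_xy[0], away_xy[1], h_a + 2.2])
        beads.append(p.copy())
        while p[2] < z_trav - 1e-9:
            p = p + np.array([0.0, 0.0, min(bond_length, z_trav - p[2])])
            beads.append(p.copy())
        # traverse toward the arrival column
        target_xy = q_b - side * u * 3.0
        start_xy = p[:2]
        span = np.linalg.norm(target_xy - start_xy)
        n_steps = max(1, int(math.ceil(span / bond_length)))
        for s in range(1, n_steps + 1):
            xy = start_xy + (target_xy - start_xy) * s / n_steps
            beads.append(np.array([xy[0], xy[1], z_trav]))
        # descend to just above the arrival column
        p = beads[-1].copy()
        while p[2] > h_b + 2.2 + 1e-9:
            p = p - np.array([0.0, 0.0, min(bond_length, p[2] - (h_b + 2.2))])
            beads.append(p.copy())
        # descending contact run in bundle b
        first_b_contact = len(beads) + 1  # 1-based residue index
        for i in range(sp_b.n_residues):
            beads.append(np.array([q_b[0], q_b[1], h_b - i * bond_length]))
        coords = np.asarray(beads)
        n = coords.shape[0]
        seq = _filler_sequence(n)
        chains.append(ChainRecord(chain_id=cid, sequence=seq, coords=coords))

        bid_a, bid_b = f"B{xs.a}", f"B{xs.b}"
        for i in range(1, n + 1):
            membership[(cid, i)] = "crosslink"
        # contact runs plus the adjacency-widened neighbour on each side
        for i in range(1, n_contact_a + 2):
            membership[(cid, i)] = bid_a
        for i in range(first_b_contact - 1, n + 1):
            membership[(cid, i)] = bid_b
        thick[bid_a] = thick.get(bid_a, 0) + 1
        if xs.b != xs.a:
            thick[bid_b] = thick.get(bid_b, 0) + 1
        events.append((cid, (n_contact_a + 2, first_b_contact - 2), bid_a, bid_b))

    frame = AssemblyFrame(chains=chains)
    frame.validate()
    # construction-time verification: every residue planted as free-space
    # traversal must keep its clearance margin from all other chains, or
    # the requested routing is infeasible and the truth would be wrong
    for chain in chains:
        others = [c for c in frame.chains if c.chain_id != chain.chain_id]
        if not others:
            continue
        other_coords = np.vstack([c.coords for c in others])
        for i in range(1, len(chain) + 1):
            if membership[(chain.chain_id, i)] != "crosslink":
                continue
            d = np.linalg.norm(other_coords - chain.coords[i - 1], axis=1).min()
            if d < contact_cutoff + clearance_margin:
                raise ValidationError(
                    f"infeasible cross-link routing: residue "
                    f"({chain.chain_id}, {i}) is {d:.2f} A from another "
                    f"chain (< cutoff {contact_cutoff} + margin "
                    f"{clearance_margin})"
                )
    truth = PlantedTruth(bundle_membership=membership,
                         bundle_thicknesses=thick,
                         crosslink_events=events)
    truth.validate()
    return frame, truth


# ---------------------------------------------------------------------------
# Channel phantoms

def _disc_with_hole(
    half_width: float,
    hole_radius: float,
    spacing: float,
    z: float,
) -> list[np.ndarray]:
    """Square bead plate of half-width ``half_width`` at height ``z`` with a
    circular aperture of radius ``hole_radius`` centred on the z axis; rim
    beads are placed exactly on the aperture circle."""
    beads = []
    ax = np.arange(-half_width, half_width + spacing / 2.0, spacing)
    for x in ax:
        for y in ax:
            if hole_radius == 0 or math.hypot(x, y) >= hole_radius:
                beads.append(np.array([x, y, z]))
    if hole_radius > 0:
        n_rim = max(8, int(math.ceil(2.0 * math.pi * hole_radius / spacing)))
        ang = 2.0 * math.pi * np.arange(n_rim) / n_rim
        for a in ang:
            beads.append(np.array([hole_radius * math.cos(a),
                                   hole_radius * math.sin(a), z]))
    return beads


def _beads_to_frame(
    beads: np.ndarray,
    box: np.ndarray,
    geometry=None,
    chain_size: int = 500,
) -> AssemblyFrame:
    """Pack wall beads into dummy chains (PDB-friendly chunks) shifted so
    the box corner is at the origin."""
    beads = np.asarray(beads, dtype=float) + box / 2.0
    n = beads.shape[0]
    n_chains = max(1, int(math.ceil(n / chain_size)))
    ids = make_chain_ids(n_chains)
    chains = []
    for c in range(n_chains):
        chunk = beads[c * chain_size:(c + 1) * chain_size]
        seq = _filler_sequence(chunk.shape[0])
        chains.append(ChainRecord(chain_id=ids[c], sequence=seq, coords=chunk))
    geom = geometry if geometry is not None else BathGeometry(tuple(box), periodic=False)
    frame = AssemblyFrame(chains=chains, geometry=geom)
    frame.validate()
    return frame


def make_channel_phantom(
    bottleneck_radius: float | list[float],
    wall_bead_spacing: float = 2.0,
    geometry: str = "axial_slab",
    rng: np.random.Generator | None = None,
    chamber_radius: float = 60.0,
    chamber_height: float = 60.0,
) -> tuple[AssemblyFrame, PlantedTruth]:
    """Bead-wall channel with a known narrowest clearance radius.

    ``axial_slab``: one bead plate per requested radius, spanning the full
    box cross-section, each pierced by an axial circular hole; a list of
    radii plants bottlenecks in series (the smallest governs what can
    pass).  A radius of 0 builds a solid wall.

    ``ring_bore``: a closed cylindrical chamber (side wall plus end caps)
    whose side wall carries one circular porthole of the requested radius;
    the only way out of the chamber is radially through the porthole.
    """
    radii = ([bottleneck_radius] if np.isscalar(bottleneck_radius)
             else list(bottleneck_radius))
    for r in radii:
        if r < 0 or (0 < r <= wall_bead_spacing):
            raise ValidationError(
                "each bottleneck radius must be 0 (solid wall) or larger "
                "than the wall bead spacing"
            )
    s = wall_bead_spacing
    if geometry == "axial_slab":
        r_max = max(radii)
        half = max(2.0 * r_max + 20.0, 40.0)
        n_plates = len(radii)
        gap = max(4.0 * r_max, 30.0)
        z0 = -gap * (n_plates - 1) / 2.0
        beads: list[np.ndarray] = []
        for k, r in enumerate(radii):
            beads.extend(_disc_with_hole(half, r, s, z0 + k * gap))
        z_span = gap * (n_plates - 1) + 2.0 * max(2.0 * r_max, 25.0)
        box = np.array([2.0 * half, 2.0 * half, z_span])
        frame = _beads_to_frame(np.asarray(beads), box)
        truth = PlantedTruth(bundle_membership={}, bundle_thicknesses={},
                             planted_pore_radius=float(min(radii)))
        return frame, truth
    if geometry == "ring_bore":
        if len(radii) != 1:
            raise ValidationError("ring_bore supports a single bottleneck")
        r_hole = radii[0]
        rc, hc = chamber_radius, chamber_height
        beads = []
        # side wall with a porthole centred at angle 0, mid-height
        n_phi = max(16, int(math.ceil(2.0 * math.pi * rc / s)))
        zs = np.arange(-hc / 2.0, hc / 2.0 + s / 2.0, s)
        hole_center = np.array([rc, 0.0, 0.0])
        for phi in 2.0 * math.pi * np.arange(n_phi) / n_phi:
            for z in zs:
                p = np.array([rc * math.cos(phi), rc * math.sin(phi), z])
                if r_hole > 0 and np.linalg.norm(p - hole_center) < r_hole:
                    continue
                beads.append(p)
        if r_hole > 0:
            # rim of the porthole: circle of radius r_hole on the cylinder,
            # in the plane tangent at the hole centre (x ~ rc)
            n_rim = max(8, int(math.ceil(2.0 * math.pi * r_hole / s)))
            for a in 2.0 * math.pi * np.arange(n_rim) / n_rim:
                y = r_hole * math.cos(a)
                z = r_hole * math.sin(a)
                phi = y / rc
                beads.append(np.array([rc * math.cos(phi), rc * math.sin(phi), z]))
        # end caps: full discs at the top and bottom
        ax = np.arange(-rc, rc + s / 2.0, s)
        for x in ax:
            for y in ax:
                if math.hypot(x, y) <= rc:
                    beads.append(np.array([x, y, -hc / 2.0]))
                    beads.append(np.array([x, y, hc / 2.0]))
        box = np.array([2.0 * rc + 40.0, 2.0 * rc + 40.0, hc + 40.0])
        geom = RingGeometry(inner_radius=rc, row_spacing=0.0, n_rows=1,
                            anchor_spacing=0.0)
        frame = _beads_to_frame(np.asarray(beads), box, geometry=geom)
        truth = PlantedTruth(bundle_membership={}, bundle_thicknesses={},
                             planted_pore_radius=float(r_hole))
        return frame, truth
    raise ValidationError(f"unknown phantom geometry {geometry!r}")


def jitter(
    frame: AssemblyFrame,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> AssemblyFrame:
    """I.i.d. Gaussian displacement of every bead; constraints are NOT
    re-enforced, and planted truth labels carry over unchanged."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    chains = []
    for c in frame.chains:
        coords = c.coords + (rng.normal(0.0, sigma, size=c.coords.shape)
                             if sigma > 0 else 0.0)
        extra = None
        if c.extra_beads is not None:
            extra = [
                [(k, tuple(np.asarray(p) + rng.normal(0.0, sigma, size=3)))
                 for k, p in per_res]
                for per_res in c.extra_beads
            ]
        tether = c.tether
        if tether is not None:
            # keep the tether invariant: the anchored residue stays put
            coords[tether.residue_index - 1] = np.asarray(tether.anchor)
        chains.append(ChainRecord(chain_id=c.chain_id, sequence=c.sequence,
                                  coords=coords, tether=tether,
                                  motifs=list(c.motifs), extra_beads=extra))
    out = AssemblyFrame(chains=chains, geometry=frame.geometry,
                        time_label=frame.time_label)
    out.validate()
    return out
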