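"""Brush height, radius of gyration, and solvent accessibility.

Brush height is the per-chain end-to-end distance of the backbone beads
along the brush (z) axis.  SASA uses the Shrake–Rupley sphere-point scheme
on the coarse-grained beads; at one bead per residue it measures how buried
a residue is within the bead packing, which is what the bundle-versus-
cross-link accessibility comparison of FG motifs needs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .bundles import CROSSLINK, BundleDecomposition
from .models import AssemblyFrame, ChainRecord, Trajectory, ValidationError


def brush_height(
    frame: AssemblyFrame,
    chain_ids: list[str] | None = None,
    axis: int = 2,
) -> tuple[dict[str, float], float]:
    """Per-chain |z_last - z_first| of the backbone beads, and their mean."""
    chains = frame.chains if chain_ids is None else [frame.chain(c) for c in chain_ids]
    if not chains:
        raise ValidationError("no chains selected")
    heights = {
        c.chain_id: float(abs(c.coords[-1, axis] - c.coords[0, axis]))
        for c in chains
    }
    return heights, float(np.mean(list(heights.values())))


def brush_height_series(
    trajectory: Trajectory,
    chain_ids: list[str] | None = None,
    axis: int = 2,
) -> list[float]:
    """Mean brush height per frame."""
    return [brush_height(fr, chain_ids, axis)[1] for fr in trajectory.frames]


def radius_of_gyration(chain: ChainRecord | np.ndarray) -> float:
    """Root-mean-square bead distance from the unweighted centroid."""
    coords = chain.coords if isinstance(chain, ChainRecord) else np.asarray(chain)
    coords = coords.reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValidationError("no beads")
    delta = coords - coords.mean(axis=0)
    return float(np.sqrt((delta ** 2).sum(axis=1).mean()))


def extended_rg_closed_form(n_beads: int, bond_length: float) -> float:
    """Rg of N equally spaced collinear unit-mass beads:
    b * sqrt((N^2 - 1) / 12)."""
    return bond_length * math.sqrt((n_beads ** 2 - 1) / 12.0)


@dataclass
class SasaParams:
    """Shrake–Rupley inputs for coarse-grained beads.

    The probe radius defaults to 2.6 A (a coarse-grained water bead; use
    1.4 A for atomistic realism) and bead radii default to 2.3 A per bead,
    overridable per bead kind.
    """

    probe_radius: float = 2.6
    radii: dict[str, float] = field(default_factory=dict)
    default_radius: float = 2.3
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius <= 0 or self.default_radius <= 0:
            raise ValidationError("radii must be positive")
        if any(r <= 0 for r in self.radii.values()):
            raise ValidationError("radii must be positive")
        if self.n_sphere_points < 92:
            raise ValidationError("n_sphere_points must be >= 92")


def shrake_rupley_sasa(
    frame: AssemblyFrame,
    params: SasaParams | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue solvent-accessible surface area in A^2.

    Sphere-point quadrature over every bead (backbone and side-chain),
    summed per residue.
    """
    import biotite.structure as struc

    params = params or SasaParams()
    coords, owners, kinds = frame.all_beads()
    if coords.shape[0] == 0:
        return {}
    radii = np.array([params.radii.get(k, params.default_radius) for k in kinds])
    atoms = struc.AtomArray(coords.shape[0])
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.array(["A"] * len(owners))
    atoms.res_id = np.arange(1, len(owners) + 1)
    atoms.res_name = np.array(["ALA"] * len(owners))
    atoms.atom_name = np.array(["CA"] * len(owners))
    atoms.element = np.array(["C"] * len(owners))
    per_atom = struc.sasa(atoms, probe_radius=params.probe_radius,
                          ignore_ions=False,
                          point_number=params.n_sphere_points,
                          vdw_radii=radii)
    out: defaultdict[tuple[str, int], float] = defaultdict(float)
    for area, owner in zip(per_atom, owners):
        out[owner] += float(area)
    return dict(out)


def isolated_bead_sasa(radius: float, probe: float) -> float:
    """Closed-form SASA of one isolated bead: 4 pi (R + p)^2."""
    return 4.0 * math.pi * (radius + probe) ** 2


def motif_accessibility_report(
    frame: AssemblyFrame,
    decomposition: BundleDecomposition,
    params: SasaParams | None = None,
    sasa: dict[tuple[str, int], float] | None = None,
) -> dict[tuple[str, str], dict[str, float]]:
    """SASA of the first phenylalanine of each FG / FxFG motif, grouped by
    motif kind and region (bundle vs cross-linking).

    The first phenylalanine is the residue at the motif start index.
    Returns ``{(kind, region): {"mean": .., "std": .., "n": ..}}``; groups
    with no members are absent.
    """
    if sasa is None:
        sasa = shrake_rupley_sasa(frame, params)
    groups: defaultdict[tuple[str, str], list[float]] = defaultdict(list)
    for chain in frame.chains:
        for m in chain.motifs:
            residue = (chain.chain_id, m.start)
            label = decomposition.labels.get(residue, CROSSLINK)
            region = "crosslink" if label == CROSSLINK else "bundle"
            groups[(m.kind, region)].append(sasa[residue])
    report = {}
    for key, vals in sorted(groups.items()):
        arr = np.asarray(vals)
        report[key] = {
            "mean": float(arr.mean()),
            "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": float(len(arr)),
        }
    return report
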