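"""Core data model for coarse-grained FG-nucleoporin assemblies.

The canonical representation is one backbone bead per residue (the C-alpha
bead of a coarse-grained polypeptide).  An optional list of extra beads per
residue (side-chain beads) is carried through untouched; only solvent
accessibility consumes it.  All coordinates are in Angstrom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

#: One-letter alphabet of the 20 standard amino acids.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues spanned by each motif kind, counted from the motif start.
MOTIF_SPAN = {"FG": 2, "FxFG": 4}

#: Residue address: (chain_id, 1-based residue index).
Residue = tuple[str, int]


class FgBrushError(Exception):
    """Base class for all package errors."""


class ValidationError(FgBrushError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class Tether:
    """Rigid anchor of one residue to a fixed point (e.g. a gold surface)."""

    anchor: tuple[float, float, float]
    residue_index: int  # 1-based


@dataclass(frozen=True)
class Motif:
    """An FG-repeat motif occurrence; ``start`` is 1-based."""

    kind: str  # "FG" or "FxFG"
    start: int

    @property
    def span(self) -> int:
        return MOTIF_SPAN[self.kind]

    @property
    def end(self) -> int:
        """Last residue index (inclusive) covered by the motif."""
        return self.start + self.span - 1


@dataclass
class ChainRecord:
    """One polymer chain: sequence, backbone bead coordinates, metadata.

    Parameters
    ----------
    chain_id : str
        Short unique identifier within a frame.
    sequence : str
        One-letter amino-acid string.
    coords : (N, 3) ndarray
        Backbone bead position per residue, Angstrom.
    tether : Tether, optional
        If present, ``coords[residue_index - 1]`` must equal the anchor.
    motifs : list of Motif
        Non-overlapping FG / FxFG motif annotations.
    extra_beads : list, optional
        Per-residue list of ``(kind, (x, y, z))`` side-chain beads.
    """

    chain_id: str
    sequence: str
    coords: np.ndarray
    tether: Tether | None = None
    motifs: list[Motif] = field(default_factory=list)
    extra_beads: list[list[tuple[str, tuple[float, float, float]]]] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"chain {self.chain_id}: {self.coords.shape[0]} coordinates "
                f"for {n} residues"
            )
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"chain {self.chain_id}: non-amino-acid letters {sorted(bad)}"
            )
        covered: set[int] = set()
        for m in self.motifs:
            if m.kind not in MOTIF_SPAN:
                raise ValidationError(f"unknown motif kind {m.kind!r}")
            span = set(range(m.start, m.end + 1))
            if m.start < 1 or m.end > n:
                raise ValidationError(
                    f"chain {self.chain_id}: motif {m} outside [1, {n}]"
                )
            if covered & span:
                raise ValidationError(
                    f"chain {self.chain_id}: overlapping motif {m}"
                )
            covered |= span
        if self.tether is not None:
            i = self.tether.residue_index
            if not 1 <= i <= n:
                raise ValidationError(
                    f"chain {self.chain_id}: tether index {i} outside [1, {n}]"
                )
            if not np.array_equal(self.coords[i - 1], np.asarray(self.tether.anchor)):
                raise ValidationError(
                    f"chain {self.chain_id}: tethered residue {i} is not at "
                    f"its anchor position"
                )
        if self.extra_beads is not None and len(self.extra_beads) != n:
            raise ValidationError(
                f"chain {self.chain_id}: extra_beads length mismatch"
            )

    def residue_beads(self, index: int) -> np.ndarray:
        """All bead positions of residue ``index`` (1-based), backbone first."""
        beads = [self.coords[index - 1]]
        if self.extra_beads is not None:
            beads.extend(np.asarray(p) for _, p in self.extra_beads[index - 1])
        return np.asarray(beads, dtype=float)


# ---------------------------------------------------------------------------
# Geometry descriptors

@dataclass(frozen=True)
class RingGeometry:
    """Anchors on concentric circles in the z = 0 plane; brush axis is +z."""

    inner_radius: float
    row_spacing: float
    n_rows: int
    anchor_spacing: float

    kind = "ring"


@dataclass(frozen=True)
class ArrayGeometry:
    """Anchors on a rectangular grid in the z = 0 plane; brush axis is +z."""

    nx: int
    ny: int
    grid_spacing: float

    kind = "array"


@dataclass(frozen=True)
class BathGeometry:
    """A rectangular box; minimum-image convention when ``periodic``."""

    box: tuple[float, float, float]
    periodic: bool = True

    kind = "bath"


Geometry = RingGeometry | ArrayGeometry | BathGeometry


def geometry_to_dict(geom: Geometry | None) -> dict | None:
    if geom is None:
        return None
    if isinstance(geom, RingGeometry):
        return {"kind": "ring", "inner_radius": geom.inner_radius,
                "row_spacing": geom.row_spacing, "n_rows": geom.n_rows,
                "anchor_spacing": geom.anchor_spacing}
    if isinstance(geom, ArrayGeometry):
        return {"kind": "array", "nx": geom.nx, "ny": geom.ny,
                "grid_spacing": geom.grid_spacing}
    if isinstance(geom, BathGeometry):
        return {"kind": "bath", "box": list(geom.box), "periodic": geom.periodic}
    raise TypeError(f"unknown geometry {geom!r}")


def geometry_from_dict(d: dict | None) -> Geometry | None:
    if d is None:
        return None
    kind = d["kind"]
    if kind == "ring":
        return RingGeometry(d["inner_radius"], d["row_spacing"], d["n_rows"],
                            d["anchor_spacing"])
    if kind == "array":
        return ArrayGeometry(d["nx"], d["ny"], d["grid_spacing"])
    if kind == "bath":
        return BathGeometry(tuple(d["box"]), bool(d.get("periodic", True)))
    raise ValidationError(f"unknown geometry kind {kind!r}")


# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) into the minimum-image convention."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


@dataclass
class AssemblyFrame:
    """One time point of a multi-chain assembly."""

    chains: list[ChainRecord]
    geometry: Geometry | None = None
    time_label: float = 0.0

    def validate(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate chain_ids within frame")
        for c in self.chains:
            c.validate()

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residues(self) -> list[Residue]:
        """All residue addresses in chain-then-sequence order."""
        return [(c.chain_id, i + 1) for c in self.chains for i in range(len(c))]

    def residue_beads(self, residue: Residue) -> np.ndarray:
        cid, idx = residue
        chain = self.chain(cid)
        if not 1 <= idx <= len(chain):
            raise KeyError(f"residue {residue} out of range")
        return chain.residue_beads(idx)

    def all_backbone_coords(self) -> np.ndarray:
        """Stacked backbone bead coordinates in chain-then-sequence order."""
        if not self.chains:
            return np.empty((0, 3))
        return np.vstack([c.coords for c in self.chains])

    def all_beads(self) -> tuple[np.ndarray, list[Residue], list[str]]:
        """Every bead (backbone and extra) with its residue address and kind."""
        coords: list[np.ndarray] = []
        owners: list[Residue] = []
        kinds: list[str] = []
        for c in self.chains:
            for i in range(len(c)):
                coords.append(c.coords[i])
                owners.append((c.chain_id, i + 1))
                kinds.append("CA")
                if c.extra_beads is not None:
                    for kind, pos in c.extra_beads[i]:
                        coords.append(np.asarray(pos, dtype=float))
                        owners.append((c.chain_id, i + 1))
                        kinds.append(kind)
        arr = np.asarray(coords, dtype=float).reshape(-1, 3)
        return arr, owners, kinds

    @property
    def periodic_box(self) -> np.ndarray | None:
        if isinstance(self.geometry, BathGeometry) and self.geometry.periodic:
            return np.asarray(self.geometry.box, dtype=float)
        return None

    def bounding_box(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of the frame.

        For bath geometry the box itself defines the domain (so an empty
        bath frame still has a well-defined extent); otherwise the bead
        bounding box, padded by ``pad``.
        """
        if isinstance(self.geometry, BathGeometry):
            return np.zeros(3), np.asarray(self.geometry.box, dtype=float)
        coords = self.all_backbone_coords()
        if coords.size == 0:
            raise ValidationError("empty frame without a box geometry")
        return coords.min(axis=0) - pad, coords.max(axis=0) + pad


@dataclass
class Trajectory:
    """Ordered frames sharing one chain topology.

    ``analysis_window`` is the number of trailing frames over which averaged
    statistics (thickness histograms, pore size) are computed.
    """

    frames: list[AssemblyFrame]
    analysis_window: int = 1

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("trajectory needs at least one frame")
        ref = self.frames[0]
        ref_top = [(c.chain_id, c.sequence) for c in ref.chains]
        for k, fr in enumerate(self.frames[1:], start=1):
            top = [(c.chain_id, c.sequence) for c in fr.chains]
            if top != ref_top:
                raise ValidationError(
                    f"frame {k} topology differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def window_frames(self, window: int | None = None) -> list[AssemblyFrame]:
        """The trailing analysis window."""
        w = self.analysis_window if window is None else window
        if w < 1 or w > len(self.frames):
            raise ValidationError(
                f"window {w} invalid for trajectory of {len(self.frames)} frames"
            )
        return self.frames[-w:]


def make_chain_ids(n: int) -> list[str]:
    """Deterministic unique chain ids: A..Z, a..z, 0..9 then two-letter."""
    alphabet = (
        "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    )
    ids: list[str] = []
    width = 1
    while len(ids) < n:
        for combo in itertools.product(alphabet, repeat=width):
            ids.append("".join(combo))
            if len(ids) == n:
                break
        width += 1
    return ids
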