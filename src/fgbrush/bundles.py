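"""Bundle / cross-link decomposition of FG-nup assemblies.

A residue-level contact graph is built from a frame: residues of *different*
chains closer than a cutoff (default 6 A, strict inequality) are connected,
and every contact endpoint is additionally connected to its immediate
sequence neighbours.  Connected components spanning at least ``min_chains``
distinct chains are *bundles*; their *thickness* is the number of distinct
chains involved.  Every residue outside a bundle belongs to the
*cross-linking region* — typically a single chain leaving one bundle and
joining a nearby one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .models import (
    AssemblyFrame,
    FgBrushError,
    Residue,
    Trajectory,
    ValidationError,
)

#: Edge provenance labels.
INTERCHAIN = "interchain_contact"
ADJACENCY = "sequence_adjacency"

CROSSLINK = "crosslink"


@dataclass
class ContactGraph:
    """Residue contact graph of one frame.

    ``graph`` nodes are residue addresses ``(chain_id, index)``; every node
    is incident to at least one edge (isolated residues are not part of the
    graph — they are cross-linking region by definition).  Edge attribute
    ``provenance`` is :data:`INTERCHAIN` or :data:`ADJACENCY`.
    """

    graph: nx.Graph
    cutoff: float
    frame: AssemblyFrame

    @property
    def n_interchain_edges(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True)
                   if d["provenance"] == INTERCHAIN)


@dataclass
class BundleDecomposition:
    """Bundle vs cross-link labelling of one frame."""

    components: list[set[Residue]]
    bundles: dict[str, set[Residue]]
    thickness: dict[str, int]
    labels: dict[Residue, str]  # bundle id or CROSSLINK
    crosslink_events: list[tuple[str, tuple[int, int], str, str]]
    anisotropy: dict[str, float] = field(default_factory=dict)

    def thickness_multiset(self) -> list[int]:
        return sorted(self.thickness.values())


def residue_distance(frame: AssemblyFrame, a: Residue, b: Residue) -> float:
    """Minimum distance over all bead pairs of residues ``a`` and ``b``.

    Reduces to the backbone-bead distance in the single-bead model; uses
    the minimum-image convention when the frame is periodic.
    """
    pa = frame.residue_beads(a)
    pb = frame.residue_beads(b)
    delta = pa[:, None, :] - pb[None, :, :]
    box = frame.periodic_box
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return float(np.sqrt((delta ** 2).sum(axis=-1)).min())


def build_contact_graph(frame: AssemblyFrame, cutoff: float = 6.0) -> ContactGraph:
    """Contact graph at ``cutoff`` (strict ``<``), with sequence-adjacency
    augmentation applied once to contact endpoints.

    Neighbour search uses a k-d tree; the result equals the all-pairs
    definition exactly (pairs at exactly the cutoff are excluded).
    """
    coords, owners, _ = frame.all_beads()
    g = nx.Graph()
    if coords.shape[0] == 0:
        return ContactGraph(graph=g, cutoff=cutoff, frame=frame)
    box = frame.periodic_box
    if box is not None:
        tree = cKDTree(np.mod(coords, box), boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    chain_len = {c.chain_id: len(c) for c in frame.chains}
    contact_residues: set[Residue] = set()
    for i, j in pairs:
        ra, rb = owners[i], owners[j]
        if ra[0] == rb[0]:
            continue
        # k-d tree returns pairs at distance <= r; the rule is strict
        if residue_distance(frame, ra, rb) >= cutoff:
            continue
        g.add_edge(ra, rb, provenance=INTERCHAIN)
        contact_residues.update((ra, rb))
    for cid, idx in contact_residues:
        for nb in (idx - 1, idx + 1):
            if 1 <= nb <= chain_len[cid]:
                if not g.has_edge((cid, idx), (cid, nb)):
                    g.add_edge((cid, idx), (cid, nb), provenance=ADJACENCY)
    return ContactGraph(graph=g, cutoff=cutoff, frame=frame)


def find_components(contact_graph: ContactGraph) -> list[set[Residue]]:
    """Maximal connected sets of residues incident to at least one edge,
    sorted deterministically by their smallest residue address."""
    comps = [set(c) for c in nx.connected_components(contact_graph.graph)]
    return sorted(comps, key=lambda c: min(c))


def _bundle_anisotropy(frame: AssemblyFrame, residues: set[Residue]) -> float:
    """Principal-axis elongation of a bundle: sqrt(l1 / l3) of the gyration
    tensor eigenvalues (descriptive only, never used as a filter)."""
    pts = np.asarray([frame.residue_beads(r)[0] for r in residues])
    if pts.shape[0] < 2:
        return 1.0
    cov = np.cov((pts - pts.mean(axis=0)).T)
    ev = np.sort(np.linalg.eigvalsh(cov))
    if ev[-1] <= 0:
        return 1.0
    return float(np.sqrt(ev[-1] / max(ev[0], 1e-12)))


def decompose(
    frame: AssemblyFrame,
    cutoff: float = 6.0,
    min_chains: int = 2,
) -> BundleDecomposition:
    """Full bundle / cross-link decomposition of a frame.

    Components with at least ``min_chains`` distinct chains become bundles
    ``B0, B1, ...`` (ordered by smallest residue address); every other
    residue — isolated or in a single-chain component — is labelled
    cross-link.  A cross-link event is a maximal cross-link-labelled run of
    one chain whose two flanking sequence neighbours both lie in bundles
    (possibly the same bundle).
    """
    cg = build_contact_graph(frame, cutoff)
    comps = find_components(cg)
    labels: dict[Residue, str] = {r: CROSSLINK for r in frame.residues()}
    bundles: dict[str, set[Residue]] = {}
    thickness: dict[str, int] = {}
    anisotropy: dict[str, float] = {}
    b = 0
    for comp in comps:
        chains = {cid for cid, _ in comp}
        if len(chains) >= min_chains:
            bid = f"B{b}"
            b += 1
            bundles[bid] = comp
            thickness[bid] = len(chains)
            anisotropy[bid] = _bundle_anisotropy(frame, comp)
            for r in comp:
                labels[r] = bid
    events: list[tuple[str, tuple[int, int], str, str]] = []
    for chain in frame.chains:
        cid = chain.chain_id
        n = len(chain)
        i = 1
        while i <= n:
            if labels[(cid, i)] == CROSSLINK:
                start = i
                while i <= n and labels[(cid, i)] == CROSSLINK:
                    i += 1
                end = i - 1
                left = labels.get((cid, start - 1))
                right = labels.get((cid, end + 1))
                if (left is not None and left != CROSSLINK
                        and right is not None and right != CROSSLINK):
                    events.append((cid, (start, end), left, right))
            else:
                i += 1
    return BundleDecomposition(components=comps, bundles=bundles,
                               thickness=thickness, labels=labels,
                               crosslink_events=events, anisotropy=anisotropy)


def thickness_distribution(
    trajectory: Trajectory,
    window: int | None = None,
    cutoff: float = 6.0,
    min_chains: int = 2,
    per_frame_normalized: bool = True,
) -> dict[int, float]:
    """Bundle-thickness histogram averaged over the trailing window.

    Each frame's thickness counts are normalized to sum 1 before averaging
    (equal frame weight); set ``per_frame_normalized=False`` to average raw
    counts and normalize once at the end.
    """
    frames = trajectory.window_frames(window)
    acc: defaultdict[int, float] = defaultdict(float)
    for fr in frames:
        dec = decompose(fr, cutoff=cutoff, min_chains=min_chains)
        counts: defaultdict[int, float] = defaultdict(float)
        for t in dec.thickness.values():
            counts[t] += 1.0
        total = sum(counts.values())
        for k, v in counts.items():
            acc[k] += (v / total) if (per_frame_normalized and total > 0) else v
    total = sum(acc.values())
    if total == 0:
        return {}
    return {k: acc[k] / (len(frames) if per_frame_normalized else total)
            for k in sorted(acc)}


def aa_bundle_propensity(
    decomposition: BundleDecomposition,
    frame: AssemblyFrame,
) -> dict[str, float]:
    """Fraction of each amino-acid category found inside bundle regions.

    Categories are the 20 amino acids, except that residues belonging to
    annotated FG / FxFG motifs are pooled into the ``FG`` and ``FxFG``
    categories (for FxFG: its two F and its G; the variable x residue stays
    under its own letter).  ``G*`` and ``F*`` denote glycines and
    phenylalanines outside any motif.  Categories with no residues in the
    frame are omitted.
    """
    in_bundle: defaultdict[str, int] = defaultdict(int)
    total: defaultdict[str, int] = defaultdict(int)
    for chain in frame.chains:
        motif_member: dict[int, str] = {}
        for m in chain.motifs:
            if m.kind == "FG":
                members = (m.start, m.start + 1)
            else:  # FxFG: F _ F G; x stays its own letter
                members = (m.start, m.start + 2, m.start + 3)
            for idx in members:
                motif_member[idx] = m.kind
        for i, aa in enumerate(chain.sequence, start=1):
            cat = motif_member.get(i)
            if cat is None:
                cat = {"F": "F*", "G": "G*"}.get(aa, aa)
            total[cat] += 1
            if decomposition.labels[(chain.chain_id, i)] != CROSSLINK:
                in_bundle[cat] += 1
    return {cat: in_bundle[cat] / total[cat] for cat in sorted(total)}
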