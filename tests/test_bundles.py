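"""Contact graph, component detection and bundle/cross-link labelling,
checked against an independent brute-force union-find oracle."""

import numpy as np
import pytest

from fgbrush.bundles import (
    ADJACENCY,
    CROSSLINK,
    INTERCHAIN,
    aa_bundle_propensity,
    build_contact_graph,
    decompose,
    find_components,
    residue_distance,
    thickness_distribution,
)
from fgbrush.models import (
    AssemblyFrame,
    BathGeometry,
    ChainRecord,
    Motif,
    Trajectory,
)

from conftest import straight_chain, two_parallel_chains


# ---------------------------------------------------------------------------
# independent oracle: all-pairs distances + union-find

class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def oracle_components(frame, cutoff=6.0):
    """All-pairs contact scan, single adjacency widening, union-find."""
    residues = frame.residues()
    uf = _UnionFind()
    contacts = set()
    edges = []
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            if ra[0] == rb[0]:
                continue
            if residue_distance(frame, ra, rb) < cutoff:
                edges.append((ra, rb))
                contacts.update((ra, rb))
    chain_len = {c.chain_id: len(c) for c in frame.chains}
    for cid, idx in list(contacts):
        for nb in (idx - 1, idx + 1):
            if 1 <= nb <= chain_len[cid]:
                edges.append(((cid, idx), (cid, nb)))
    touched = set()
    for a, b in edges:
        uf.union(a, b)
        touched.update((a, b))
    comps = {}
    for r in touched:
        comps.setdefault(uf.find(r), set()).add(r)
    return sorted(comps.values(), key=min)


def random_frame(rng, n_chains=4, n_res=12, box=40.0):
    chains = []
    for k in range(n_chains):
        start = rng.uniform(0, box, size=3)
        steps = rng.normal(size=(n_res - 1, 3))
        steps = 3.7 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([start, start + np.cumsum(steps, axis=0)])
        chains.append(ChainRecord(chr(65 + k), "A" * n_res, coords))
    return AssemblyFrame(chains=chains)


# ---------------------------------------------------------------------------

class TestResidueDistance:
    def test_single_bead_euclidean(self):
        a = ChainRecord("A", "A", np.array([[0.0, 0.0, 0.0]]))
        b = ChainRecord("B", "A", np.array([[3.0, 4.0, 0.0]]))
        frame = AssemblyFrame(chains=[a, b])
        assert residue_distance(frame, ("A", 1), ("B", 1)) == 5.0

    def test_min_over_beads(self):
        a = ChainRecord("A", "A", np.array([[0.0, 0.0, 0.0]]),
                        extra_beads=[[("SC1", (8.0, 0.0, 0.0))]])
        b = ChainRecord("B", "A", np.array([[10.0, 0.0, 0.0]]))
        frame = AssemblyFrame(chains=[a, b])
        assert residue_distance(frame, ("A", 1), ("B", 1)) == 2.0

    def test_periodic_minimum_image(self):
        a = ChainRecord("A", "A", np.array([[1.0, 5.0, 5.0]]))
        b = ChainRecord("B", "A", np.array([[9.0, 5.0, 5.0]]))
        frame = AssemblyFrame(chains=[a, b],
                              geometry=BathGeometry((10.0, 10.0, 10.0)))
        assert np.isclose(residue_distance(frame, ("A", 1), ("B", 1)), 2.0)

    def test_unknown_residue(self):
        frame = two_parallel_chains()
        with pytest.raises(KeyError):
            residue_distance(frame, ("A", 99), ("B", 1))


class TestContactGraph:
    def test_parallel_chains_at_5A(self):
        frame = two_parallel_chains(n=10, separation=5.0)
        cg = build_contact_graph(frame, cutoff=6.0)
        inter = [(u, v) for u, v, d in cg.graph.edges(data=True)
                 if d["provenance"] == INTERCHAIN]
        # only corresponding residues are within 6 A (next offset is 6.22 A)
        assert len(inter) == 10
        assert all(u[1] == v[1] for u, v in inter)
        comps = find_components(cg)
        assert len(comps) == 1 and len(comps[0]) == 20

    def test_no_edges_beyond_cutoff(self):
        frame = two_parallel_chains(n=10, separation=7.0)
        cg = build_contact_graph(frame, cutoff=6.0)
        assert cg.graph.number_of_edges() == 0
        assert find_components(cg) == []

    def test_cutoff_is_strict(self):
        frame = two_parallel_chains(n=1, separation=6.0)
        assert build_contact_graph(frame, 6.0).graph.number_of_edges() == 0

    def test_adjacency_rule_applied_once(self):
        # single contact pair (A5, B5): widening adds only +-1 neighbours
        a = straight_chain("A", 10, pitch=10.0)
        b = straight_chain("B", 10, origin=(20.0, 0, 0), pitch=10.0)
        b.coords[4] = a.coords[4] + np.array([5.0, 0.0, 0.0])
        frame = AssemblyFrame(chains=[a, b])
        cg = build_contact_graph(frame, cutoff=6.0)
        g = cg.graph
        assert g.has_edge(("A", 5), ("B", 5))
        for cid in "AB":
            assert g.has_edge((cid, 4), (cid, 5))
            assert g.has_edge((cid, 5), (cid, 6))
            assert not g.has_edge((cid, 3), (cid, 4))
        assert all(d["provenance"] == ADJACENCY
                   for u, v, d in g.edges(data=True)
                   if u[0] == v[0])

    def test_interchain_edges_never_within_chain(self, rng):
        frame = random_frame(rng)
        cg = build_contact_graph(frame)
        for u, v, d in cg.graph.edges(data=True):
            if d["provenance"] == INTERCHAIN:
                assert u[0] != v[0]
            else:
                assert u[0] == v[0] and abs(u[1] - v[1]) == 1

    def test_components_match_bruteforce_oracle(self, rng):
        for _ in range(25):
            frame = random_frame(rng, n_chains=int(rng.integers(2, 5)),
                                 n_res=int(rng.integers(5, 15)))
            got = find_components(build_contact_graph(frame, 6.0))
            assert got == oracle_components(frame, 6.0)

    def test_edge_count_monotone_in_cutoff(self, rng):
        frame = random_frame(rng)
        last = -1
        for cutoff in (4.0, 6.0, 8.0, 12.0):
            n = build_contact_graph(frame, cutoff).n_interchain_edges
            assert n >= last
            last = n


class TestDecompose:
    def test_isolated_chain_is_all_crosslink(self):
        frame = AssemblyFrame(chains=[straight_chain("A", 20)])
        dec = decompose(frame)
        assert dec.bundles == {}
        assert all(lab == CROSSLINK for lab in dec.labels.values())

    def test_labels_partition_residues(self, rng):
        frame = random_frame(rng, n_chains=5, n_res=15)
        dec = decompose(frame)
        assert set(dec.labels) == set(frame.residues())
        n_bundle = sum(1 for v in dec.labels.values() if v != CROSSLINK)
        n_cross = sum(1 for v in dec.labels.values() if v == CROSSLINK)
        assert n_bundle + n_cross == frame.n_residues

    def test_single_touch_point(self):
        # two chains touching at exactly one residue pair form one
        # thickness-2 bundle around the contact; distal residues stay
        # cross-link (verified against the all-pairs oracle)
        a = straight_chain("A", 10, pitch=10.0)
        b = straight_chain("B", 10, origin=(20.0, 0, 0), pitch=10.0)
        b.coords[4] = a.coords[4] + np.array([5.0, 0.0, 0.0])
        frame = AssemblyFrame(chains=[a, b])
        dec = decompose(frame)
        assert len(dec.bundles) == 1 and dec.thickness == {"B0": 2}
        assert dec.bundles["B0"] == oracle_components(frame)[0]
        assert dec.labels[("A", 1)] == CROSSLINK

    def test_thickness_equals_distinct_chain_count(self, rng):
        frame = random_frame(rng, n_chains=6, n_res=12)
        dec = decompose(frame)
        for bid, members in dec.bundles.items():
            assert dec.thickness[bid] == len({cid for cid, _ in members})
            assert dec.thickness[bid] >= 2


class TestThicknessDistribution:
    def test_static_frame(self):
        frame, _ = _two_bundles_frame()
        traj = Trajectory(frames=[frame])
        assert thickness_distribution(traj, window=1) == {3: 1.0}

    def test_per_frame_normalization(self):
        # frame 1 has thicknesses {2, 2}; frame 2 has {4}: equal frame
        # weights give {2: 0.5, 4: 0.5}
        f1 = AssemblyFrame(chains=[
            straight_chain("A", 6), straight_chain("B", 6, origin=(5, 0, 0)),
            straight_chain("C", 6, origin=(100, 0, 0)),
            straight_chain("D", 6, origin=(105, 0, 0))])
        f2 = AssemblyFrame(chains=[
            straight_chain("A", 6), straight_chain("B", 6, origin=(5, 0, 0)),
            straight_chain("C", 6, origin=(10, 0, 0)),
            straight_chain("D", 6, origin=(15, 0, 0))])
        traj = Trajectory(frames=[f1, f2])
        assert thickness_distribution(traj, window=2) == {2: 0.5, 4: 0.5}

    def test_empty_window_rejected(self):
        traj = Trajectory(frames=[two_parallel_chains()])
        with pytest.raises(Exception):
            thickness_distribution(traj, window=0)


def _two_bundles_frame():
    chains = []
    for k, cid in enumerate("ABC"):
        chains.append(straight_chain(cid, 8, origin=(5.0 * k, 0, 0)))
    for k, cid in enumerate("DEF"):
        chains.append(straight_chain(cid, 8, origin=(100 + 5.0 * k, 0, 0)))
    return AssemblyFrame(chains=chains), 2


class TestPropensity:
    def test_all_bundled(self):
        frame, _ = _two_bundles_frame()
        dec = decompose(frame)
        prop = aa_bundle_propensity(dec, frame)
        assert prop and all(v == 1.0 for v in prop.values())

    def test_no_bundles(self):
        frame = AssemblyFrame(chains=[straight_chain("A", 10)])
        dec = decompose(frame)
        prop = aa_bundle_propensity(dec, frame)
        assert prop and all(v == 0.0 for v in prop.values())

    def test_motif_vs_star_categories(self):
        # chain FGAG with the FG motif bundled and the trailing A, G not:
        # FG fraction 1, G* (non-motif glycine) 0, A 0
        a = ChainRecord("A", "FGAG",
                        np.array([[0, 0, 0], [0, 0, 3.7],
                                  [0, 0, 30.0], [0, 0, 33.7]], dtype=float),
                        motifs=[Motif("FG", 1)])
        b = straight_chain("B", 1, origin=(5.0, 0, 0), sequence="S")
        frame = AssemblyFrame(chains=[a, b])
        dec = decompose(frame)
        assert dec.labels[("A", 1)] != CROSSLINK
        assert dec.labels[("A", 4)] == CROSSLINK
        prop = aa_bundle_propensity(dec, frame)
        assert prop["FG"] == 1.0
        assert prop["G*"] == 0.0
        assert prop["A"] == 0.0
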