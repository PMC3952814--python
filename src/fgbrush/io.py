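"""Structure, trajectory, config and results I/O.

Single frames are serialized as PDB (one ATOM record per bead, residue
numbering 1-based, tether anchors as HETATM records with the reserved
residue name ``TTH``); package metadata that PDB cannot hold natively
(original chain ids, tether indices, motif annotations, geometry) travels
in ``REMARK 300 FGBRUSH`` lines.  The PDB chain-id column holds a single
character, so frames with more than 62 chains are split across files with
a ``_partNNN`` suffix.

Trajectories use an extended-XYZ dialect: the per-frame comment line
carries ``key=value`` tokens for the time label, chain segmentation,
geometry and (on the first frame) sequences, tethers and motifs.  Only the
single-bead backbone representation is supported there.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .models import (
    AssemblyFrame,
    ChainRecord,
    FgBrushError,
    Motif,
    Tether,
    Trajectory,
    ValidationError,
    geometry_from_dict,
    geometry_to_dict,
)

log = logging.getLogger(__name__)

#: PDB chain-id alphabet (single column => at most 62 chains per file).
PDB_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

#: Reserved residue name for tether-anchor HETATM records.
TETHER_RES_NAME = "TTH"

_REMARK_PREFIX = "REMARK 300 FGBRUSH"


class FieldWidthError(FgBrushError):
    """A value does not fit its fixed-width PDB column."""


def _check_pdb_coords(coords: np.ndarray) -> None:
    # the %8.3f coordinate columns hold [-999.999, 9999.999]
    if coords.size and (coords.max() > 9999.999 or coords.min() < -999.999):
        raise FieldWidthError(
            f"coordinate outside the PDB %8.3f field range "
            f"[-999.999, 9999.999]: min {coords.min():.3f}, "
            f"max {coords.max():.3f}"
        )


def _one_to_three(letter: str) -> str:
    from biotite.sequence import ProteinSequence

    return ProteinSequence.convert_letter_1to3(letter)


def _three_to_one(name: str) -> str:
    from biotite.sequence import ProteinSequence

    return ProteinSequence.convert_letter_3to1(name)


def _frame_chunk_to_pdb_lines(frame: AssemblyFrame, chain_map: dict[str, str]) -> list[str]:
    """ATOM/HETATM lines for one <=62-chain chunk via biotite."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    records = []
    for chain in frame.chains:
        pdb_id = chain_map[chain.chain_id]
        for i in range(len(chain)):
            records.append((pdb_id, i + 1, _one_to_three(chain.sequence[i]),
                            "CA", False, chain.coords[i]))
            if chain.extra_beads is not None:
                for kind, pos in chain.extra_beads[i]:
                    records.append((pdb_id, i + 1,
                                    _one_to_three(chain.sequence[i]),
                                    kind, False, np.asarray(pos)))
        if chain.tether is not None:
            records.append((pdb_id, chain.tether.residue_index,
                            TETHER_RES_NAME, "ANC", True,
                            np.asarray(chain.tether.anchor)))
    atoms = struc.AtomArray(len(records))
    atoms.coord = np.asarray([r[5] for r in records], dtype=np.float32)
    atoms.chain_id = np.array([r[0] for r in records])
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array([r[2] for r in records])
    atoms.atom_name = np.array([r[3] for r in records])
    atoms.hetero = np.array([r[4] for r in records])
    atoms.element = np.array(["C"] * len(records))
    f = pdb.PDBFile()
    f.set_structure(atoms)
    return list(f.lines)


def _metadata_remarks(frame: AssemblyFrame, chain_map: dict[str, str]) -> list[str]:
    lines = [f"{_REMARK_PREFIX} TIME {frame.time_label}"]
    geom = geometry_to_dict(frame.geometry)
    if geom is not None:
        lines.append(f"{_REMARK_PREFIX} GEOMETRY "
                     + json.dumps(geom, separators=(',', ':')))
    for chain in frame.chains:
        tether = (str(chain.tether.residue_index)
                  if chain.tether is not None else "-")
        motifs = ("+".join(f"{m.kind}:{m.start}" for m in chain.motifs)
                  or "-")
        lines.append(f"{_REMARK_PREFIX} CHAIN {chain_map[chain.chain_id]} "
                     f"ID={chain.chain_id} TETHER={tether} MOTIFS={motifs}")
    return lines


def write_assembly_pdb(frame: AssemblyFrame, path) -> list[Path]:
    """Write a frame as one or more PDB files.

    Returns the list of written paths: ``[path]`` for up to 62 chains,
    otherwise ``path`` with ``_part001`` etc. inserted before the suffix.
    """
    frame.validate()
    _check_pdb_coords(frame.all_backbone_coords())
    path = Path(path)
    n = len(frame.chains)
    if n == 0:
        path.write_text("\n".join(_metadata_remarks(frame, {}) + ["END", ""]))
        return [path]
    chunks = [frame.chains[i:i + 62] for i in range(0, n, 62)]
    paths = []
    for k, chunk in enumerate(chunks):
        if len(chunks) == 1:
            out = path
        else:
            out = path.with_name(f"{path.stem}_part{k + 1:03d}{path.suffix}")
        sub = AssemblyFrame(chains=chunk, geometry=frame.geometry,
                            time_label=frame.time_label)
        chain_map = {c.chain_id: PDB_CHAIN_ALPHABET[i]
                     for i, c in enumerate(chunk)}
        lines = (_metadata_remarks(sub, chain_map)
                 + _frame_chunk_to_pdb_lines(sub, chain_map))
        out.write_text("\n".join(lines) + "\n")
        paths.append(out)
    return paths


def read_assembly_pdb(path) -> AssemblyFrame:
    """Read a frame written by :func:`write_assembly_pdb` (or accept a list
    of part files, merged in order)."""
    import biotite.structure.io.pdb as pdb

    paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
    chains: list[ChainRecord] = []
    time_label = 0.0
    geometry = None
    for p in paths:
        text = p.read_text()
        meta_chain: dict[str, dict] = {}
        for line in text.splitlines():
            if not line.startswith(_REMARK_PREFIX):
                continue
            body = line[len(_REMARK_PREFIX):].strip()
            if body.startswith("TIME "):
                time_label = float(body.split()[1])
            elif body.startswith("GEOMETRY "):
                geometry = geometry_from_dict(json.loads(body.split(" ", 1)[1]))
            elif body.startswith("CHAIN "):
                toks = body.split()
                entry = {t.split("=", 1)[0]: t.split("=", 1)[1]
                         for t in toks[2:]}
                meta_chain[toks[1]] = entry
        if not [ln for ln in text.splitlines()
                if ln.startswith(("ATOM", "HETATM"))]:
            continue
        f = pdb.PDBFile.read(str(p))
        atoms = f.get_structure(model=1)
        for pdb_id in dict.fromkeys(atoms.chain_id):
            sel = atoms[atoms.chain_id == pdb_id]
            regular = sel[~sel.hetero]
            meta = meta_chain.get(pdb_id, {})
            orig_id = meta.get("ID", pdb_id)
            res_ids = sorted(dict.fromkeys(regular.res_id))
            seq = []
            coords = []
            extra: list[list] = []
            has_extra = False
            for rid in res_ids:
                res = regular[regular.res_id == rid]
                seq.append(_three_to_one(str(res.res_name[0])))
                ca = res[res.atom_name == "CA"]
                coords.append(np.asarray(ca.coord[0], dtype=float))
                beads = [(str(a), tuple(np.asarray(c, dtype=float)))
                         for a, c in zip(res.atom_name, res.coord)
                         if a != "CA"]
                extra.append(beads)
                has_extra = has_extra or bool(beads)
            tether = None
            anchors = sel[sel.hetero & (sel.res_name == TETHER_RES_NAME)]
            if meta.get("TETHER", "-") != "-" and len(anchors):
                idx = int(meta["TETHER"])
                tether = Tether(anchor=tuple(np.asarray(anchors.coord[0],
                                                        dtype=float)),
                                residue_index=idx)
                # re-impose the exact-equality invariant after fixed-
                # precision rounding
                coords[idx - 1] = np.asarray(tether.anchor)
            motifs = []
            if meta.get("MOTIFS", "-") != "-":
                for tok in meta["MOTIFS"].split("+"):
                    kind, start = tok.split(":")
                    motifs.append(Motif(kind, int(start)))
            chains.append(ChainRecord(
                chain_id=orig_id, sequence="".join(seq),
                coords=np.asarray(coords), tether=tether, motifs=motifs,
                extra_beads=extra if has_extra else None))
    frame = AssemblyFrame(chains=chains, geometry=geometry,
                          time_label=time_label)
    frame.validate()
    return frame


def write_points_pdb(points: np.ndarray, values: np.ndarray, path,
                     res_name: str = "POR") -> None:
    """Pseudo-atom PDB (HETATM, B-factor = value) for visualization."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    points = np.asarray(points, dtype=float).reshape(-1, 3)
    _check_pdb_coords(points)
    if points.shape[0] == 0:
        Path(path).write_text("END\n")
        return
    atoms = struc.AtomArray(points.shape[0])
    atoms.coord = points.astype(np.float32)
    atoms.chain_id = np.array(["A"] * len(points))
    atoms.res_id = np.arange(1, len(points) + 1)
    atoms.res_name = np.array([res_name] * len(points))
    atoms.atom_name = np.array(["PSE"] * len(points))
    atoms.hetero = np.array([True] * len(points))
    atoms.element = np.array(["C"] * len(points))
    atoms.set_annotation("b_factor", np.asarray(values, dtype=float))
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Extended-XYZ trajectories

def _frame_comment(frame: AssemblyFrame, first: bool) -> str:
    toks = [f"time={frame.time_label}"]
    toks.append("chains=" + ",".join(f"{c.chain_id}:{len(c)}"
                                     for c in frame.chains))
    geom = geometry_to_dict(frame.geometry)
    if geom is not None:
        toks.append("geometry=" + json.dumps(geom, separators=(',', ':')))
    if first:
        toks.append("sequences=" + ",".join(f"{c.chain_id}:{c.sequence}"
                                            for c in frame.chains))
        toks.append("tethers=" + ",".join(
            f"{c.chain_id}:{c.tether.residue_index if c.tether else '-'}"
            for c in frame.chains))
        toks.append("motifs=" + ",".join(
            f"{c.chain_id}:" + ("+".join(f"{m.kind}.{m.start}"
                                         for m in c.motifs) or "-")
            for c in frame.chains))
    return " ".join(toks)


def write_trajectory_xyz(trajectory: Trajectory, path) -> None:
    """Write a trajectory in the package's extended-XYZ dialect.

    Backbone beads only; frames with extra (side-chain) beads are rejected
    rather than silently truncated.
    """
    lines: list[str] = []
    for k, frame in enumerate(trajectory.frames):
        if any(c.extra_beads for c in frame.chains):
            raise ValidationError(
                "XYZ trajectories hold backbone beads only; frame "
                f"{k} carries extra beads"
            )
        lines.append(str(frame.n_residues))
        lines.append(_frame_comment(frame, first=(k == 0)))
        for c in frame.chains:
            for x, y, z in c.coords:
                lines.append(f"CA {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_xyz(path, analysis_window: int = 1) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_xyz`."""
    lines = Path(path).read_text().splitlines()
    frames: list[AssemblyFrame] = []
    sequences: dict[str, str] = {}
    tethers: dict[str, int | None] = {}
    motifs: dict[str, list[Motif]] = {}
    pos = 0
    k = 0
    ref_counts: list[tuple[str, int]] | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n_beads = int(lines[pos].strip())
        toks = dict(t.split("=", 1) for t in lines[pos + 1].split())
        counts = [(cid, int(c)) for cid, c in
                  (e.split(":") for e in toks["chains"].split(","))]
        if sum(c for _, c in counts) != n_beads:
            raise ValidationError(
                f"frame {k}: chain segmentation sums to "
                f"{sum(c for _, c in counts)} but header declares {n_beads}"
            )
        if ref_counts is None:
            ref_counts = counts
        elif counts != ref_counts:
            raise ValidationError(
                f"frame {k}: bead count or segmentation differs from frame 0"
            )
        if "sequences" in toks:
            sequences = dict(e.split(":") for e in toks["sequences"].split(","))
            tethers = {cid: (None if v == "-" else int(v)) for cid, v in
                       (e.split(":") for e in toks["tethers"].split(","))}
            for cid, v in (e.split(":", 1) for e in toks["motifs"].split(",")):
                motifs[cid] = ([] if v == "-" else
                               [Motif(t.split(".")[0], int(t.split(".")[1]))
                                for t in v.split("+")])
        geometry = (geometry_from_dict(json.loads(toks["geometry"]))
                    if "geometry" in toks else None)
        body = lines[pos + 2: pos + 2 + n_beads]
        if len(body) < n_beads:
            raise ValidationError(f"frame {k}: truncated coordinate block")
        coords = np.asarray([[float(v) for v in ln.split()[1:4]]
                             for ln in body])
        chains = []
        offset = 0
        for cid, cnt in counts:
            seq = sequences.get(cid)
            if seq is None or len(seq) != cnt:
                raise ValidationError(
                    f"frame {k}: no sequence of length {cnt} for chain {cid}"
                )
            ccoords = coords[offset:offset + cnt]
            tether = None
            t_idx = tethers.get(cid)
            if t_idx is not None:
                tether = Tether(anchor=tuple(ccoords[t_idx - 1]),
                                residue_index=t_idx)
            chains.append(ChainRecord(chain_id=cid, sequence=seq,
                                      coords=ccoords, tether=tether,
                                      motifs=list(motifs.get(cid, []))))
            offset += cnt
        frames.append(AssemblyFrame(chains=chains, geometry=geometry,
                                    time_label=float(toks.get("time", k))))
        pos += 2 + n_beads
        k += 1
    return Trajectory(frames=frames, analysis_window=analysis_window)


# ---------------------------------------------------------------------------
# Config, sequences, results

def load_config(path) -> dict:
    """YAML config; any scalar key ending in ``_nm`` is converted to an
    Angstrom-named key (internal unit is Angstrom everywhere)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {}
    for key, value in cfg.items():
        if key.endswith("_nm") and isinstance(value, (int, float)):
            out[key[:-3]] = float(value) * 10.0
        else:
            out[key] = value
    return out


def read_sequence(path_or_builtin, rng=None, length: int = 609) -> str:
    """Sequence input: ``builtin:fg_rich`` for the synthetic FG-rich
    generator, else a plain-text or FASTA file (first record)."""
    from .chain_builder import make_fg_sequence

    if str(path_or_builtin) == "builtin:fg_rich":
        return make_fg_sequence(length=length, rng=rng)
    text = Path(path_or_builtin).read_text().strip()
    if text.startswith(">"):
        seq_lines = []
        for line in text.splitlines()[1:]:
            if line.startswith(">"):
                break
            seq_lines.append(line.strip())
        return "".join(seq_lines)
    return "".join(text.split())


def write_results_json(path, analysis: str, parameters: dict,
                       per_frame=None, mean=None, std=None, **extra) -> None:
    """Uniform JSON result schema for the CLI subcommands."""
    payload = {"analysis": analysis, "parameters": parameters,
               "per_frame": per_frame, "mean": mean, "std": std}
    payload.update(extra)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default,
                                     sort_keys=False) + "\n")
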