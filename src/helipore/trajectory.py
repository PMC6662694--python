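"""Trajectory data model, readers/writers and leaflet assignment.

In-memory model: a flat atom table (topology) plus per-frame coordinate
arrays. Internal units are Å for coordinates and box edges and picoseconds
for time, with the membrane normal along z. Supported on-disk formats are
multi-model PDB, (multi-frame) GRO coordinate series, and a simple
documented delimited text format used by the synthetic generator::

    # helipore frames v1
    natoms N
    atom <chain_id> <residue_index> <residue_name> <atom_name>   (N lines)
    frame <time_ps> <box_x> <box_y> <box_z>
    <x> <y> <z>                                                  (N lines)
    ... further frame blocks ...

Peptide atoms are recognized by standard amino-acid residue names; lipid
phosphates by a configurable atom name (default ``P``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

FormatTag = Literal["pdb_multimodel", "gro_series", "delimited_frames"]


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    residue_index: int  # 1-based within its chain
    residue_name: str
    chain_id: str
    is_peptide: bool


@dataclass
class Frame:
    time: float  # ps
    box: np.ndarray  # (3,) orthorhombic edges, Å
    coordinates: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")


@dataclass
class TrajectorySet:
    """Topology plus ordered frames, partitioned into peptide chains and lipids."""

    topology: list[AtomRecord]
    frames: list[Frame]
    phosphate_atom_name: str = "P"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = len(self.topology)
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape != (n, 3):
                raise ValueError(
                    f"frame {k}: {fr.coordinates.shape[0]} coordinates for {n} topology atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def peptide_chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.topology:
            if a.is_peptide:
                seen.setdefault(a.chain_id, None)
        return list(seen)

    def atom_indices(
        self,
        chain_id: str | None = None,
        atom_name: str | None = None,
        peptide: bool | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        idx = [
            i
            for i, a in enumerate(self.topology)
            if (chain_id is None or a.chain_id == chain_id)
            and (atom_name is None or a.atom_name == atom_name)
            and (peptide is None or a.is_peptide == peptide)
        ]
        return np.asarray(idx, dtype=int)

    @property
    def phosphate_indices(self) -> np.ndarray:
        return self.atom_indices(atom_name=self.phosphate_atom_name, peptide=False)

    def coordinates_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates (cached)."""
        cache = getattr(self, "_coords_cache", None)
        if cache is None or len(cache) != self.n_frames:
            cache = np.stack([fr.coordinates for fr in self.frames])
            object.__setattr__(self, "_coords_cache", cache)
        return cache

    def chain_residue_indices(self, chain_id: str) -> list[int]:
        out: dict[int, None] = {}
        for a in self.topology:
            if a.chain_id == chain_id and a.is_peptide:
                out.setdefault(a.residue_index, None)
        return sorted(out)


def assign_leaflets(frame: Frame, traj: TrajectorySet) -> dict[int, str]:
    """Label each phosphate atom ``upper`` or ``lower`` by its z relative
    to the mean phosphate z (the bilayer midplane) in this frame.

    Returns a map atom index → leaflet label. Degenerate single-sided
    bilayers produce a warning and a lower-only assignment.
    """
    pidx = traj.phosphate_indices
    if len(pidx) < 2:
        raise ValueError("need at least two phosphate atoms to define leaflets")
    z = frame.coordinates[pidx, 2]
    mid = float(z.mean())
    labels = {int(i): ("upper" if zi > mid else "lower") for i, zi in zip(pidx, z)}
    if all(v == "lower" for v in labels.values()) or all(
        v == "upper" for v in labels.values()
    ):
        warnings.warn(
            "all phosphates on one side of their mean plane: single-leaflet mode",
            stacklevel=2,
        )
    return labels


def leaflet_indices(frame: Frame, traj: TrajectorySet, leaflet: str) -> np.ndarray:
    labels = assign_leaflets(frame, traj)
    return np.asarray([i for i, lab in labels.items() if lab == leaflet], dtype=int)


def minimum_image_xy(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary periodic image in x,y.

    z is left unwrapped: depth relative to the bilayer must keep its sign.
    """
    out = np.array(disp, dtype=float, copy=True)
    for ax in (0, 1):
        out[..., ax] -= box[ax] * np.round(out[..., ax] / box[ax])
    return out


# ---------------------------------------------------------------------------
# readers

def read_trajectory(
    topology_source: str | Path,
    frames_source: str | Path | None = None,
    format_tag: FormatTag = "pdb_multimodel",
    phosphate_atom_name: str = "P",
) -> TrajectorySet:
    """Read a trajectory; coordinates converted to Å, times to ps.

    ``frames_source`` defaults to ``topology_source`` (single-file formats).
    """
    src = Path(topology_source)
    frames_src = Path(frames_source) if frames_source is not None else src
    if format_tag == "pdb_multimodel":
        traj = _read_pdb_multimodel(src)
    elif format_tag == "gro_series":
        traj = _read_gro_series(frames_src)
    elif format_tag == "delimited_frames":
        traj = _read_delimited(src)
    else:
        raise ValueError(f"unknown format_tag {format_tag!r}")
    traj.phosphate_atom_name = phosphate_atom_name
    times = [fr.time for fr in traj.frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        # synthesize a monotone time base when the file carries none
        for k, fr in enumerate(traj.frames):
            fr.time = float(k)
    return traj


def _records_from_mda(universe) -> list[AtomRecord]:
    recs = []
    per_chain_resid: dict[tuple[str, int], int] = {}
    chain_counters: dict[str, dict[int, int]] = {}
    for atom in universe.atoms:
        chain = str(getattr(atom, "chainID", "") or atom.segid or "A").strip() or "A"
        resname = atom.resname.strip().upper()
        is_pep = resname in STANDARD_AA3
        cmap = chain_counters.setdefault(chain, {})
        if atom.resid not in cmap:
            cmap[atom.resid] = len(cmap) + 1
        recs.append(
            AtomRecord(
                atom_name=atom.name.strip(),
                residue_index=cmap[atom.resid],
                residue_name=resname,
                chain_id=chain,
                is_peptide=is_pep,
            )
        )
    return recs


def _read_pdb_multimodel(path: Path) -> TrajectorySet:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        topology = _records_from_mda(u)
        frames = []
        for ts in u.trajectory:
            box = ts.dimensions[:3] if ts.dimensions is not None else None
            if box is None or np.any(box <= 0):
                box = _bounding_box(ts.positions)
            frames.append(
                Frame(
                    time=float(ts.time),
                    box=np.asarray(box, dtype=float),
                    coordinates=ts.positions.astype(float),
                )
            )
    return TrajectorySet(topology=topology, frames=frames)


def _bounding_box(coords: np.ndarray) -> np.ndarray:
    span = coords.max(axis=0) - coords.min(axis=0)
    return np.maximum(span, 1.0) + 10.0


def _read_gro_series(path: Path) -> TrajectorySet:
    """Multi-frame GRO via mdtraj (nm → Å)."""
    import mdtraj as md

    t = md.load(str(path))
    # GRO has no chain records: start a new chain whenever the residue
    # number resets or the peptide/non-peptide character changes
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    res_chain: dict[int, tuple[str, int]] = {}
    chain_no = -1
    prev_seq, prev_pep, local = None, None, 0
    for res in t.topology.residues:
        pep = res.name.strip().upper() in STANDARD_AA3
        if prev_seq is None or res.resSeq <= prev_seq or pep != prev_pep:
            chain_no += 1
            local = 0
        local += 1
        res_chain[res.index] = (chain_letters[chain_no % len(chain_letters)], local)
        prev_seq, prev_pep = res.resSeq, pep
    topology = []
    for atom in t.topology.atoms:
        chain, ridx = res_chain[atom.residue.index]
        resname = atom.residue.name.strip().upper()
        topology.append(
            AtomRecord(
                atom_name=atom.name.strip(),
                residue_index=ridx,
                residue_name=resname,
                chain_id=chain,
                is_peptide=resname in STANDARD_AA3,
            )
        )
    frames = []
    for k in range(t.n_frames):
        box = (
            t.unitcell_lengths[k] * 10.0
            if t.unitcell_lengths is not None
            else _bounding_box(t.xyz[k] * 10.0)
        )
        frames.append(
            Frame(
                time=float(t.time[k]) if t.time is not None else float(k),
                box=np.asarray(box, dtype=float),
                coordinates=(t.xyz[k] * 10.0).astype(float),
            )
        )
    return TrajectorySet(topology=topology, frames=frames)


def _read_delimited(path: Path) -> TrajectorySet:
    lines = Path(path).read_text().splitlines()
    it = iter(l for l in lines if l.strip() and not l.startswith("#"))
    head = next(it).split()
    if head[0] != "natoms":
        raise ValueError("delimited frames: expected 'natoms N' header")
    n = int(head[1])
    topology = []
    for _ in range(n):
        tok = next(it).split()
        if tok[0] != "atom":
            raise ValueError("delimited frames: malformed atom table")
        _, chain, ridx, rname, aname = tok[:5]
        topology.append(
            AtomRecord(
                atom_name=aname,
                residue_index=int(ridx),
                residue_name=rname.upper(),
                chain_id=chain,
                is_peptide=rname.upper() in STANDARD_AA3,
            )
        )
    frames = []
    while True:
        try:
            tok = next(it).split()
        except StopIteration:
            break
        if tok[0] != "frame":
            raise ValueError(f"delimited frames: expected frame header, got {tok[0]!r}")
        time, bx, by, bz = map(float, tok[1:5])
        coords = np.empty((n, 3))
        for i in range(n):
            try:
                coords[i] = [float(v) for v in next(it).split()[:3]]
            except StopIteration:
                raise ValueError(
                    f"frame at t={time}: expected {n} coordinate lines, got {i}"
                ) from None
        frames.append(Frame(time=time, box=np.array([bx, by, bz]), coordinates=coords))
    return TrajectorySet(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# writers

def write_delimited(traj: TrajectorySet, path: str | Path) -> None:
    out = ["# helipore frames v1", f"natoms {traj.n_atoms}"]
    for a in traj.topology:
        out.append(
            f"atom {a.chain_id} {a.residue_index} {a.residue_name} {a.atom_name}"
        )
    for fr in traj.frames:
        out.append(
            f"frame {fr.time:.3f} {fr.box[0]:.3f} {fr.box[1]:.3f} {fr.box[2]:.3f}"
        )
        out.extend(f"{x:.3f} {y:.3f} {z:.3f}" for x, y, z in fr.coordinates)
    Path(path).write_text("\n".join(out) + "\n")


def _mda_universe(traj: TrajectorySet):
    import MDAnalysis as mda

    n_atoms = traj.n_atoms
    res_key = [(a.chain_id, a.residue_index) for a in traj.topology]
    res_order: dict[tuple[str, int], int] = {}
    for key in res_key:
        res_order.setdefault(key, len(res_order))
    atom_resindex = np.array([res_order[k] for k in res_key])
    n_res = len(res_order)
    chains = [k[0] for k in res_order]
    seg_order: dict[str, int] = {}
    for c in chains:
        seg_order.setdefault(c, len(seg_order))
    residue_segindex = np.array([seg_order[c] for c in chains])

    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_res,
        n_segments=len(seg_order),
        atom_resindex=atom_resindex,
        residue_segindex=residue_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in traj.topology])
    u.add_TopologyAttr("resnames", [
        next(a.residue_name for a in traj.topology if (a.chain_id, a.residue_index) == key)
        for key in res_order
    ])
    u.add_TopologyAttr("resids", [key[1] for key in res_order])
    u.add_TopologyAttr("segids", list(seg_order))
    u.add_TopologyAttr("chainIDs", [a.chain_id[:1] for a in traj.topology])
    return u


def write_pdb_multimodel(traj: TrajectorySet, path: str | Path) -> None:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = _mda_universe(traj)
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates
                u.dimensions = np.concatenate([fr.box, [90.0, 90.0, 90.0]])
                w.write(u.atoms)


def write_gro_series(traj: TrajectorySet, path: str | Path) -> None:
    """Concatenated GRO frames (Å → nm)."""
    import MDAnalysis as mda

    path = Path(path)
    chunks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = _mda_universe(traj)
        for k, fr in enumerate(traj.frames):
            u.atoms.positions = fr.coordinates
            u.dimensions = np.concatenate([fr.box, [90.0, 90.0, 90.0]])
            tmp = path.with_suffix(f".frame{k}.gro.tmp")
            with mda.Writer(str(tmp), format="GRO", n_atoms=traj.n_atoms) as w:
                w.write(u.atoms)
            text = tmp.read_text()
            first, rest = text.split("\n", 1)
            chunks.append(f"frame t= {fr.time:.3f}\n{rest.rstrip()}\n")
            tmp.unlink()
    path.write_text("".join(chunks))
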