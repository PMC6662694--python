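"""Inter-peptide contacts, Cα–Cα distance heatmaps and oligomer states.

Self-association of membrane-bound peptide copies is read out three ways:
residue-resolved heatmaps of time-averaged inter-copy Cα–Cα distances (which
residues mediate each interface), per-frame oligomer partitions (connected
components of a copy-level contact graph), and population series of cluster
sizes (monomer / dimer / trimer / tetramer / ≥5) with a persistence filter
that separates stable aggregates from transient brushes.

Distances use the minimum-image convention in x,y (the membrane plane);
z is non-periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import Frame, TrajectorySet, minimum_image_xy

SIZE_CLASSES = ["monomer", "dimer", "trimer", "tetramer", "ge5"]


@dataclass
class InterPeptideHeatmap:
    """Square matrix of time-averaged Cα–Cα distances over (copy, residue) pairs.

    Intra-copy blocks are masked (NaN): only inter-peptide geometry is
    meaningful for aggregation.
    """

    labels: list[tuple[str, int]]  # (chain_id, residue_index) per row
    matrix: np.ndarray  # (M, M) Å, symmetric, NaN on intra-copy blocks
    metadata: dict = field(default_factory=dict)

    def block(self, chain_a: str, chain_b: str) -> tuple[np.ndarray, list[int], list[int]]:
        """The (residues_a × residues_b) sub-matrix for one copy pair."""
        ia = [k for k, (c, _) in enumerate(self.labels) if c == chain_a]
        ib = [k for k, (c, _) in enumerate(self.labels) if c == chain_b]
        sub = self.matrix[np.ix_(ia, ib)]
        return sub, [self.labels[k][1] for k in ia], [self.labels[k][1] for k in ib]

    def to_frame(self) -> pd.DataFrame:
        names = [f"{c}:{r}" for c, r in self.labels]
        return pd.DataFrame(self.matrix, index=names, columns=names)


@dataclass(frozen=True)
class OligomerPartition:
    """Disjoint clusters of peptide copy ids at one frame."""

    time: float
    clusters: tuple[frozenset[str], ...]

    @property
    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)


def _ca_layout(traj: TrajectorySet) -> tuple[list[tuple[str, int]], np.ndarray]:
    labels, idx = [], []
    for chain in traj.peptide_chains:
        for i, a in enumerate(traj.topology):
            if a.chain_id == chain and a.is_peptide and a.atom_name == "CA":
                labels.append((chain, a.residue_index))
                idx.append(i)
    return labels, np.asarray(idx, dtype=int)


def ca_distance_matrix(
    frame: Frame, traj: TrajectorySet
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Pairwise Cα–Cα distances (Å) over all peptide copies in one frame.

    Minimum-image in x,y; intra-copy entries masked NaN.
    """
    labels, idx = _ca_layout(traj)
    if not labels:
        raise ValueError("no peptide Cα atoms found")
    pos = frame.coordinates[idx]
    disp = pos[:, None, :] - pos[None, :, :]
    disp = minimum_image_xy(disp, frame.box)
    dmat = np.linalg.norm(disp, axis=-1)
    chains = np.array([c for c, _ in labels])
    dmat[chains[:, None] == chains[None, :]] = np.nan
    return labels, dmat


def time_average_heatmap(
    traj: TrajectorySet, frame_range: tuple[int, int] | None = None
) -> InterPeptideHeatmap:
    """Elementwise mean of the per-frame inter-copy distance matrices."""
    sl = slice(*frame_range) if frame_range is not None else slice(None)
    frames = traj.frames[sl]
    if not frames:
        raise ValueError("empty frame range")
    acc = None
    labels = None
    for fr in frames:
        labels, dmat = ca_distance_matrix(fr, traj)
        acc = dmat if acc is None else acc + dmat
    mat = acc / len(frames)
    return InterPeptideHeatmap(
        labels=labels,
        matrix=mat,
        metadata={"n_frames": len(frames), "frame_range": frame_range},
    )


def oligomer_partition(
    frame: Frame,
    traj: TrajectorySet,
    contact_cutoff: float = 7.0,
    min_contacts: int = 1,
) -> OligomerPartition:
    """Cluster peptide copies by inter-copy Cα contacts.

    Copies i, j are adjacent iff at least ``min_contacts`` inter-copy Cα–Cα
    distances fall at or below ``contact_cutoff`` Å; clusters are the
    connected components of the resulting graph.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    labels, dmat = ca_distance_matrix(frame, traj)
    chains = traj.peptide_chains
    n = len(chains)
    adj = np.zeros((n, n), dtype=int)
    chain_rows = {c: [k for k, (cc, _) in enumerate(labels) if cc == c] for c in chains}
    for (i, ca), (j, cb) in combinations(enumerate(chains), 2):
        block = dmat[np.ix_(chain_rows[ca], chain_rows[cb])]
        if np.count_nonzero(block <= contact_cutoff) >= min_contacts:
            adj[i, j] = adj[j, i] = 1
    _, comp = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, set[str]] = {}
    for ci, chain in zip(comp, chains):
        clusters.setdefault(int(ci), set()).add(chain)
    return OligomerPartition(
        time=frame.time,
        clusters=tuple(frozenset(c) for c in clusters.values()),
    )


def _size_class(size: int) -> str:
    return SIZE_CLASSES[min(size, 5) - 1]


def oligomer_populations(
    traj: TrajectorySet,
    contact_cutoff: float = 7.0,
    min_contacts: int = 1,
    persistence: int = 10,
    frame_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-frame cluster-size populations with a persistence filter.

    Raw columns count every cluster of each size class at each frame; the
    ``stable_*`` columns count only clusters whose exact membership has
    persisted for at least ``persistence`` consecutive frames up to and
    including the current one (monomers are exempt from the filter).
    """
    sl = slice(*frame_range) if frame_range is not None else slice(None)
    frames = traj.frames[sl]
    run_length: dict[frozenset, int] = {}
    rows = []
    for fr in frames:
        part = oligomer_partition(fr, traj, contact_cutoff, min_contacts)
        new_runs = {c: run_length.get(c, 0) + 1 for c in part.clusters}
        run_length = new_runs
        row = {"time": fr.time}
        for cls in SIZE_CLASSES:
            row[cls] = 0
            row[f"stable_{cls}"] = 0
        for c in part.clusters:
            cls = _size_class(len(c))
            row[cls] += 1
            if len(c) == 1 or run_length[c] >= persistence:
                row[f"stable_{cls}"] += 1
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["params"] = dict(
        contact_cutoff=contact_cutoff, min_contacts=min_contacts, persistence=persistence
    )
    return df


def mediating_residues(
    heatmap: InterPeptideHeatmap,
    partition: OligomerPartition,
    contact_cutoff: float = 7.0,
    top_k: int = 10,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Rank residue pairs by ascending time-averaged distance for every
    copy pair sharing a cluster; only pairs whose minimal entry is within
    ``contact_cutoff`` are reported (distant co-clustered pairs are bridged
    by intermediates, not direct contacts)."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for cluster in partition.clusters:
        for ca, cb in combinations(sorted(cluster), 2):
            block, res_a, res_b = heatmap.block(ca, cb)
            if block.size == 0 or np.nanmin(block) > contact_cutoff:
                continue
            ii, jj = np.unravel_index(np.argsort(block, axis=None), block.shape)
            rows = [
                dict(residue_a=res_a[i], residue_b=res_b[j], distance=float(block[i, j]))
                for i, j in zip(ii[:top_k], jj[:top_k])
            ]
            out[(ca, cb)] = pd.DataFrame(rows)
    return out
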