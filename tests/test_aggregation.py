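"""Inter-peptide distances, oligomer partitions, mediating residues."""

from itertools import combinations

import numpy as np
import pytest

import helipore as hp
from helipore.aggregation import (
    ca_distance_matrix,
    mediating_residues,
    oligomer_partition,
    oligomer_populations,
    time_average_heatmap,
)
from helipore.trajectory import AtomRecord, Frame, TrajectorySet


def _copies_traj(positions, box=(500.0, 500.0, 200.0), n_frames=1):
    """One CA per residue per copy at the given (copy -> list of xyz)."""
    topo, coords = [], []
    for ci, pos in enumerate(positions):
        chain = "ABCDEFGH"[ci]
        for ri, xyz in enumerate(pos, start=1):
            topo.append(AtomRecord("CA", ri, "ALA", chain, True))
            coords.append(xyz)
    topo.append(AtomRecord("P", 1, "LIP", "L", False))
    coords.append([1.0, 1.0, 100.0])
    topo.append(AtomRecord("P", 2, "LIP", "L", False))
    coords.append([1.0, 1.0, 60.0])
    coords = np.array(coords, float)
    frames = [Frame(float(t), np.array(box), coords.copy()) for t in range(n_frames)]
    return TrajectorySet(topo, frames)


def brute_force_components(adj):
    """Independent oracle: DFS connected components of an adjacency matrix."""
    n = len(adj)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(w for w in range(n) if adj[v][w] and w not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def test_hand_placed_distances():
    traj = _copies_traj([
        [[0.0, 0.0, 50.0]],
        [[3.0, 4.0, 50.0]],
        [[0.0, 0.0, 62.0]],
    ])
    labels, dmat = ca_distance_matrix(traj.frames[0], traj)
    idx = {lab: k for k, lab in enumerate(labels)}
    assert dmat[idx[("A", 1)], idx[("B", 1)]] == pytest.approx(5.0)
    assert dmat[idx[("A", 1)], idx[("C", 1)]] == pytest.approx(12.0)
    assert np.isnan(dmat[idx[("A", 1)], idx[("A", 1)]])  # intra-copy masked


def test_minimum_image_in_xy():
    traj = _copies_traj(
        [[[1.0, 10.0, 50.0]], [[99.0, 10.0, 50.0]]], box=(100.0, 100.0, 200.0)
    )
    _, dmat = ca_distance_matrix(traj.frames[0], traj)
    assert np.nanmin(dmat) == pytest.approx(2.0)  # wraps across the x edge


def test_separated_copies_distance_bound():
    rng = np.random.default_rng(1)
    helix_a = rng.normal(scale=3.0, size=(10, 3)) + [50, 50, 50]
    helix_b = helix_a + [100.0, 0.0, 0.0]
    traj = _copies_traj([helix_a.tolist(), helix_b.tolist()])
    _, dmat = ca_distance_matrix(traj.frames[0], traj)
    assert np.nanmin(dmat) >= 100.0 - 2 * (3.0 * 4)


def test_static_heatmap_equals_single_frame():
    traj = _copies_traj([[[0, 0, 50]], [[5, 0, 50]]], n_frames=7)
    hm = time_average_heatmap(traj)
    _, single = ca_distance_matrix(traj.frames[0], traj)
    assert np.allclose(hm.matrix, single, equal_nan=True)


def test_chain_contacts_cluster_transitively():
    traj = _copies_traj([
        [[0.0, 0.0, 50.0]],
        [[5.0, 0.0, 50.0]],
        [[10.0, 0.0, 50.0]],
        [[40.0, 0.0, 50.0]],
    ])
    part = oligomer_partition(traj.frames[0], traj, contact_cutoff=7.0)
    got = {tuple(sorted(c)) for c in part.clusters}
    assert got == {("A", "B", "C"), ("D",)}


def test_all_far_apart_all_monomers():
    traj = _copies_traj([[[60.0 * i, 0.0, 50.0]] for i in range(8)])
    part = oligomer_partition(traj.frames[0], traj)
    assert part.sizes == [1] * 8


def test_all_close_one_octamer():
    traj = _copies_traj([[[3.0 * i, 0.0, 50.0]] for i in range(8)])
    part = oligomer_partition(traj.frames[0], traj)
    assert part.sizes == [8]


def test_partition_matches_bruteforce_on_random_configs():
    """100 random <=8-copy configurations agree with a DFS oracle."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        pts = rng.uniform(20, 180, size=(n, 3))
        traj = _copies_traj([[p.tolist()] for p in pts])
        cutoff = float(rng.uniform(5, 120))
        part = oligomer_partition(traj.frames[0], traj, contact_cutoff=cutoff)
        adj = [[0] * n for _ in range(n)]
        for i, j in combinations(range(n), 2):
            if np.linalg.norm(pts[i] - pts[j]) <= cutoff:
                adj[i][j] = adj[j][i] = 1
        want = {
            frozenset("ABCDEFGH".index(c) for c in cl) for cl in part.clusters
        }
        assert want == brute_force_components(adj)


def test_increasing_cutoff_coarsens_monotonically():
    rng = np.random.default_rng(3)
    pts = rng.uniform(20, 120, size=(8, 3))
    traj = _copies_traj([[p.tolist()] for p in pts])
    previous = np.inf
    for cutoff in (2.0, 10.0, 30.0, 60.0, 120.0):
        k = len(oligomer_partition(traj.frames[0], traj, cutoff).clusters)
        assert k <= previous
        previous = k


def test_one_frame_brush_filtered_by_persistence():
    base = [[[0.0, 0.0, 50.0]], [[50.0, 0.0, 50.0]]]
    traj = _copies_traj(base, n_frames=30)
    # a single-frame approach below the cutoff at frame 15
    traj.frames[15].coordinates[1] = [5.0, 0.0, 50.0]
    pops = oligomer_populations(traj, contact_cutoff=7.0, persistence=10)
    assert pops.dimer.sum() == 1  # the raw brush is seen once
    assert pops.stable_dimer.sum() == 0  # but never called a stable aggregate


def test_persistent_tetramer_reported():
    spec = hp.TrajectorySpec(
        sequence=hp.TEMPORIN_L, n_copies=8, n_frames=60, seed=3,
        aggregation=[hp.AggregationSchedule(
            copies=[0, 1, 2, 3], contact_residues=[5, 6, 7, 8], onset_frame=5
        )],
    )
    traj, truth = hp.generate_helix_trajectory(spec)
    pops = hp.oligomer_populations(traj, persistence=10)
    assembled = pops[pops.time >= (5 + 10 + 10) * spec.frame_dt]
    assert (assembled.stable_tetramer >= 1).mean() >= 0.95
    part = oligomer_partition(traj.frames[-1], traj)
    assert frozenset("ABCD") in part.clusters


def test_programmed_contact_residues_rank_first():
    spec = hp.TrajectorySpec(
        sequence=hp.TEMPORIN_L, n_copies=4, n_frames=40, seed=8,
        aggregation=[hp.AggregationSchedule(
            copies=[0, 1], contact_residues=[5, 6, 7, 8], onset_frame=0
        )],
    )
    traj, _ = hp.generate_helix_trajectory(spec)
    hm = time_average_heatmap(traj, frame_range=(15, 40))
    part = oligomer_partition(traj.frames[-1], traj)
    ranks = mediating_residues(hm, part)
    top = ranks[("A", "B")].iloc[0]
    assert top.residue_a in (5, 6, 7, 8)
    assert top.residue_b in (5, 6, 7, 8)
    # ranking symmetric under copy swap
    sub, res_a, res_b = hm.block("A", "B")
    sub_t, res_b2, res_a2 = hm.block("B", "A")
    assert np.allclose(sub, sub_t.T, equal_nan=True)


def test_distant_pair_gives_empty_ranking():
    traj = _copies_traj([[[0.0, 0.0, 50.0]], [[200.0, 0.0, 50.0]]], n_frames=2)
    hm = time_average_heatmap(traj)
    part = oligomer_partition(traj.frames[0], traj, contact_cutoff=300.0)
    assert mediating_residues(hm, part, contact_cutoff=7.0) == {}


def test_rigid_rotation_invariance():
    rng = np.random.default_rng(9)
    pts = rng.uniform(-20, 20, size=(4, 3))
    center = np.array([250.0, 250.0, 100.0])
    traj = _copies_traj([[(p + center).tolist()] for p in pts])
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]
    ])
    rotated = _copies_traj([[(rot @ p + center).tolist()] for p in pts])
    _, d0 = ca_distance_matrix(traj.frames[0], traj)
    _, d1 = ca_distance_matrix(rotated.frames[0], rotated)
    assert np.allclose(d0, d1, equal_nan=True, atol=1e-9)
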