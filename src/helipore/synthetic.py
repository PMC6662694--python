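"""Synthetic trajectories and current traces with known ground truth.

Every downstream analysis (dihedral statistics, insertion depth,
aggregation, channel idealization) can be exercised against programmed
parameters instead of real simulation or recording data:

* ``generate_helix_trajectory`` builds multi-copy peptide backbones frame by
  frame from per-residue (φ, ψ) angles drawn from von Mises distributions,
  using sequential internal-coordinate placement with ideal bond geometry.
  Copies are rigid-body placed above a two-leaflet lattice of pseudo
  phosphate atoms, with optional programmed insertion (per-residue depth
  schedules) and aggregation (copy groups driven into lateral contact via
  chosen residues).
* ``generate_channel_trace`` samples a continuous-time Markov chain over
  {closed, open₁..open_K} exactly (exponential holding times), discretizes
  it at the sampling rate and adds Gaussian noise.

Both are deterministic given their seed; each copy and each subsystem draws
from an independently spawned random stream, so adding copies does not
perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .physchem import PeptideSequence
from .trajectory import AtomRecord, Frame, TrajectorySet

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Next-atom position from internal coordinates (NeRF placement).

    ``a, b, c`` are (..., 3) positions of the three preceding atoms; the new
    atom d bonds to c with the given bond length, b–c–d angle, and a–b–c–d
    torsion in the IUPAC sign convention. Broadcasts over leading axes.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg, dtype=float))[..., None]
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = (
        -np.cos(theta) * bc
        + np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n)
    )
    return c + bond * d_local


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone (N, CA, C per residue) from dihedral arrays.

    ``phi``/``psi`` have shape (n_frames, n_res); phi[:, 0] and psi[:, -1]
    are ignored (those torsions do not exist). Returns
    (n_frames, 3·n_res, 3) coordinates, vectorized over frames.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    n_frames, n_res = phi.shape
    coords = np.zeros((n_frames, 3 * n_res, 3))
    # first residue in a canonical pose
    theta = np.radians(ANGLE_N_CA_C)
    coords[:, 0] = [0.0, 0.0, 0.0]
    coords[:, 1] = [BOND_N_CA, 0.0, 0.0]
    coords[:, 2] = coords[:, 1] + BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(1, n_res):
        nprev, ca_prev, c_prev = coords[:, 3 * i - 3], coords[:, 3 * i - 2], coords[:, 3 * i - 1]
        n_i = place_atom(nprev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[:, i])
        coords[:, 3 * i] = n_i
        coords[:, 3 * i + 1] = ca_i
        coords[:, 3 * i + 2] = c_i
    return coords


@dataclass
class BilayerSpec:
    """Two lattices of pseudo-phosphate atoms about programmed planes."""

    upper_z: float = 19.0  # Å
    lower_z: float = -19.0
    grid: int = 16  # grid×grid phosphates per leaflet (16² ≈ 256 lipids/leaflet)
    jitter_sigma: float = 1.0  # Å, per-frame vertical jitter
    box_xy: float = 128.0  # lateral box edge, Å (≈512-lipid bilayer patch)
    box_z: float = 140.0


@dataclass
class InsertionSchedule:
    """Drive listed residues to signed target depths (Å, positive = below
    the upper phosphate plane) linearly between onset and end frames."""

    target_depths: dict[int, float]  # residue_index -> depth
    onset_frame: int = 0
    end_frame: int | None = None  # default: last frame
    copies: Sequence[int] | None = None  # copy indices; default all


@dataclass
class AggregationSchedule:
    """Drive a group of copies into lateral contact from an onset frame."""

    copies: Sequence[int]
    contact_residues: Sequence[int]
    onset_frame: int = 0
    spacing: float = 9.5  # Å between neighbouring helix axes
    contact_gap: float = 4.2  # Å clamped Cα-Cα across each interface
    tilt_deg: float = 12.0  # alternating pitch so helices splay off-contact
    transition_frames: int = 10


@dataclass
class TrajectorySpec:
    sequence: PeptideSequence
    n_copies: int = 8
    n_frames: int = 100
    frame_dt: float = 2.0  # ps
    phi_mean: float | Sequence[float] = -57.0
    psi_mean: float | Sequence[float] = -47.0
    kappa: float | Sequence[float] = 50.0  # von Mises concentration(s)
    bilayer: BilayerSpec = field(default_factory=BilayerSpec)
    start_height: float = 30.0  # Å of the CA centroid above the upper plane
    min_separation: float = 20.0  # Å between copy anchors at placement
    insertion: InsertionSchedule | None = None
    aggregation: Sequence[AggregationSchedule] = ()
    seed: int = 0


def _per_residue(value, n_res: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_res, float(arr))
    if arr.shape != (n_res,):
        raise ValueError(f"per-residue array must have length {n_res}")
    return arr


def _axis_align(coords: np.ndarray, ca_slice: np.ndarray) -> np.ndarray:
    """Rotate each frame so the helix axis (first principal CA direction)
    lies along +x and the CA centroid is at the origin."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        ca = coords[f, ca_slice]
        centroid = ca.mean(axis=0)
        shifted = coords[f] - centroid
        u, s, vt = np.linalg.svd(ca - centroid, full_matrices=False)
        axis = vt[0]
        if axis[0] < 0:
            axis = -axis
        # rotation taking axis -> x̂
        x = np.array([1.0, 0.0, 0.0])
        v = np.cross(axis, x)
        c = float(np.dot(axis, x))
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
        out[f] = shifted @ rot.T
    return out


def _segment_distance(
    a: np.ndarray, b: np.ndarray, seg_len: float, box_xy: float
) -> float:
    """Closest approach of two x-aligned segments of length seg_len centred
    at lateral points a, b, under the lateral minimum-image convention."""
    dx = abs(a[0] - b[0])
    dx = min(dx, box_xy - dx)
    dy = abs(a[1] - b[1])
    dy = min(dy, box_xy - dy)
    return float(np.hypot(max(dx - seg_len, 0.0), dy))


def _scatter_anchors(
    rng: np.random.Generator,
    n: int,
    box_xy: float,
    min_sep: float,
    seg_len: float,
    keep_clear: Sequence[np.ndarray] = (),
) -> np.ndarray:
    """Random lateral anchors whose x-aligned helix footprints stay at least
    min_sep apart (and clear of any reserved points)."""
    # crowded boxes: progressively relax the separation rather than fail
    for relax in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
        sep = min_sep * relax
        pts: list[np.ndarray] = []
        for _ in range(20000):
            cand = rng.uniform(0.0, box_xy, size=2)
            if all(
                _segment_distance(cand, p, seg_len, box_xy) >= sep
                for p in list(pts) + list(keep_clear)
            ):
                pts.append(cand)
                if len(pts) == n:
                    return np.array(pts)
    raise RuntimeError(
        "could not place copies with the requested separation; "
        "enlarge box_xy or reduce min_separation"
    )


def _rot_y(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array(
        [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
    )


def generate_helix_trajectory(spec: TrajectorySpec) -> tuple[TrajectorySet, dict]:
    """Build the trajectory and return it with its ground-truth record.

    Ground truth keys: ``phi``/``psi`` (n_copies, n_frames, n_res) sampled
    angles; ``depth`` (n_frames, n_copies, n_res) realized CA depths below
    the true upper plane; ``clusters`` per-frame membership tuples;
    ``upper_plane_z``/``lower_plane_z``.
    """
    seq = spec.sequence
    n_res = len(seq)
    n_copies, n_frames = spec.n_copies, spec.n_frames
    phi_mu = _per_residue(spec.phi_mean, n_res)
    psi_mu = _per_residue(spec.psi_mean, n_res)
    kappa = _per_residue(spec.kappa, n_res)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    bl = spec.bilayer
    if bl.upper_z <= bl.lower_z:
        raise ValueError("upper phosphate plane must lie above the lower one")

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(n_copies + 2)
    copy_seeds = children[:n_copies]
    layout_rng = np.random.default_rng(children[n_copies])
    lipid_rng = np.random.default_rng(children[n_copies + 1])

    # aggregation bookkeeping: per copy, (schedule, rank within its group)
    group_of: dict[int, AggregationSchedule] = {}
    rank_in_group: dict[int, int] = {}
    for sched in spec.aggregation:
        for r, c in enumerate(sched.copies):
            if c in group_of:
                raise ValueError(f"copy {c} appears in two aggregation schedules")
            group_of[c] = sched
            rank_in_group[c] = r

    seg_len = 1.5 * (n_res - 1) + 4.0  # x-footprint of an axis-aligned helix
    # reserve the post-onset stack sites of each contact group first, then
    # scatter initial anchors clear of them so bystanders never join a cluster
    group_targets: dict[int, np.ndarray] = {}
    reserved: list[np.ndarray] = []
    for sched in spec.aggregation:
        base = _scatter_anchors(
            layout_rng, 1, bl.box_xy, spec.min_separation, seg_len, reserved
        )[0]
        for r, c in enumerate(sched.copies):
            pos = base + np.array([0.0, r * sched.spacing])
            group_targets[c] = pos
            reserved.append(pos)
    anchors = _scatter_anchors(
        layout_rng, n_copies, bl.box_xy, spec.min_separation, seg_len, reserved
    )

    ca_slice = np.arange(1, 3 * n_res, 3)
    copy_coords = np.zeros((n_copies, n_frames, 3 * n_res, 3))
    gt_phi = np.zeros((n_copies, n_frames, n_res))
    gt_psi = np.zeros((n_copies, n_frames, n_res))

    for c in range(n_copies):
        rng = np.random.default_rng(copy_seeds[c])
        phi = np.stack([rng.vonmises(np.radians(phi_mu), kappa) for _ in range(n_frames)])
        psi = np.stack([rng.vonmises(np.radians(psi_mu), kappa) for _ in range(n_frames)])
        phi, psi = np.degrees(phi), np.degrees(psi)
        gt_phi[c], gt_psi[c] = phi, psi
        bb = _axis_align(build_backbone(phi, psi), ca_slice)

        sched = group_of.get(c)
        base_xy = anchors[c]
        z0 = bl.upper_z + spec.start_height
        for f in range(n_frames):
            fr = bb[f].copy()
            if sched is not None and f >= sched.onset_frame:
                cres = [r - 1 for r in sched.contact_residues]
                sign = 1.0 if rank_in_group[c] % 2 == 0 else -1.0
                # roll about the helix axis so the central contact residues
                # face the partner copy (even ranks face +y, odd face -y):
                # the helical phase would otherwise decide which residues
                # approach closest
                mid = cres[len(cres) // 2 :][:1] + cres[: (len(cres) + 1) // 2][-1:]
                ry, rz = fr[ca_slice][mid, 1].mean(), fr[ca_slice][mid, 2].mean()
                alpha = np.arctan2(rz, ry)
                target = 0.0 if sign > 0 else np.pi
                roll = target - alpha
                cr, sr = np.cos(roll), np.sin(roll)
                y, z = fr[:, 1].copy(), fr[:, 2].copy()
                fr[:, 1] = cr * y - sr * z
                fr[:, 2] = sr * y + cr * z
                # alternate pitch through the contact-region centroid:
                # neighbours splay apart in z away from the contact residues
                pivot = fr[ca_slice][cres].mean(axis=0)
                fr = (fr - pivot) @ _rot_y(sign * sched.tilt_deg).T + pivot
                target_xy = group_targets[c]
                prog = min(1.0, (f - sched.onset_frame) / max(sched.transition_frames, 1))
                xy = base_xy + prog * (target_xy - base_xy)
            else:
                xy = base_xy
            fr[:, 0] += xy[0]
            fr[:, 1] += xy[1]
            fr[:, 2] += z0
            copy_coords[c, f] = fr

    # clamp contact residues onto the predecessor in each contact group:
    # each member's contact-residue CAs are pulled to the predecessor's at
    # a fixed interface gap, so the programmed residues are the closest
    # pairs by construction (a rigid-body approach cannot guarantee this:
    # the helical phase recurs every ~3.6 residues)
    taper = 3.0
    for sched in spec.aggregation:
        cres = np.array(sorted(sched.contact_residues)) - 1
        for r in range(1, len(sched.copies)):
            c, p = sched.copies[r], sched.copies[r - 1]
            for f in range(sched.onset_frame, n_frames):
                prog = min(1.0, (f - sched.onset_frame) / max(sched.transition_frames, 1))
                raw = {}
                for j in cres:
                    target = copy_coords[p, f, 3 * j + 1] + np.array(
                        [0.0, sched.contact_gap, 0.0]
                    )
                    raw[j] = prog * (target - copy_coords[c, f, 3 * j + 1])
                for j in range(n_res):
                    nearest = cres[np.argmin(np.abs(cres - j))]
                    w = 1.0 if j in raw else max(0.0, 1.0 - abs(j - nearest) / taper)
                    copy_coords[c, f, 3 * j : 3 * j + 3] += raw[nearest] * w

    # insertion schedule: per-residue z offsets with a short taper
    gt_depth = np.zeros((n_frames, n_copies, n_res))
    if spec.insertion is not None:
        ins = spec.insertion
        end = ins.end_frame if ins.end_frame is not None else n_frames - 1
        if not (0 <= ins.onset_frame <= end < n_frames):
            raise ValueError("insertion schedule outside frame range")
        targets = ins.target_depths
        bad = [r for r in targets if not 1 <= r <= n_res]
        if bad:
            raise ValueError(f"insertion schedule names missing residues {bad}")
        copies = list(ins.copies) if ins.copies is not None else list(range(n_copies))
        taper = 3.0
        sched_res = np.array(sorted(targets)) - 1  # 0-based
        for c in copies:
            for f in range(n_frames):
                prog = np.clip((f - ins.onset_frame) / max(end - ins.onset_frame, 1), 0, 1)
                ca_z = copy_coords[c, f, ca_slice, 2]
                offsets = np.zeros(n_res)
                raw = {}
                for r0 in sched_res:
                    d_start = bl.upper_z - ca_z[r0]
                    d_target = targets[r0 + 1]
                    d_now = d_start + prog * (d_target - d_start)
                    raw[r0] = (bl.upper_z - d_now) - ca_z[r0]
                for j in range(n_res):
                    nearest = sched_res[np.argmin(np.abs(sched_res - j))]
                    w = max(0.0, 1.0 - abs(j - nearest) / taper) if j not in raw else 1.0
                    offsets[j] = raw.get(j, raw[nearest] * w)
                for j in range(n_res):
                    copy_coords[c, f, 3 * j : 3 * j + 3, 2] += offsets[j]

    for f in range(n_frames):
        for c in range(n_copies):
            gt_depth[f, c] = bl.upper_z - copy_coords[c, f, ca_slice, 2]

    # phosphate lattices
    g = bl.grid
    xs = (np.arange(g) + 0.5) * (bl.box_xy / g)
    gx, gy = np.meshgrid(xs, xs)
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    n_ph = 2 * g * g

    topology: list[AtomRecord] = []
    for c in range(n_copies):
        chain = CHAIN_IDS[c]
        for r, aa in enumerate(seq.residues, start=1):
            for name in ("N", "CA", "C"):
                topology.append(AtomRecord(name, r, AA1TO3[aa], chain, True))
    for leaflet, cid in (("upper", "1"), ("lower", "2")):
        for k in range(g * g):
            topology.append(AtomRecord("P", k + 1, "LIP", cid, False))

    z_off = 0.5 * bl.box_z  # keep all z positive inside the box
    frames: list[Frame] = []
    for f in range(n_frames):
        coords = np.vstack(
            [copy_coords[c, f] for c in range(n_copies)]
            + [
                np.column_stack(
                    [lattice, np.full(g * g, bl.upper_z) + bl.jitter_sigma * lipid_rng.standard_normal(g * g)]
                ),
                np.column_stack(
                    [lattice, np.full(g * g, bl.lower_z) + bl.jitter_sigma * lipid_rng.standard_normal(g * g)]
                ),
            ]
        )
        coords = coords.copy()
        coords[:, 2] += z_off
        frames.append(
            Frame(
                time=f * spec.frame_dt,
                box=np.array([bl.box_xy, bl.box_xy, bl.box_z]),
                coordinates=coords,
            )
        )

    traj = TrajectorySet(topology=topology, frames=frames)

    clusters = []
    for f in range(n_frames):
        grouped: set[int] = set()
        cl: list[tuple[str, ...]] = []
        for sched in spec.aggregation:
            if f >= sched.onset_frame + sched.transition_frames:
                cl.append(tuple(CHAIN_IDS[c] for c in sched.copies))
                grouped.update(sched.copies)
        for c in range(n_copies):
            if c not in grouped:
                cl.append((CHAIN_IDS[c],))
        clusters.append(tuple(sorted(cl)))

    ground_truth = {
        "phi": gt_phi,
        "psi": gt_psi,
        "depth": gt_depth,
        "clusters": clusters,
        "upper_plane_z": bl.upper_z + z_off,
        "lower_plane_z": bl.lower_z + z_off,
        "phi_mean": phi_mu,
        "psi_mean": psi_mu,
        "kappa": kappa,
    }
    return traj, ground_truth


def von_mises_circular_variance(kappa: float) -> float:
    """Closed-form circular variance 1 − I₁(κ)/I₀(κ) of a von Mises law."""
    from scipy.special import i0e, i1e

    return float(1.0 - i1e(kappa) / i0e(kappa))


# ---------------------------------------------------------------------------
# channel traces

@dataclass
class TraceSpec:
    """Multi-level stochastic channel current.

    ``rates`` is the (K+1)×(K+1) transition-rate matrix over states
    {closed, open₁..open_K} in s⁻¹ (off-diagonal entries; the diagonal is
    derived). ``quiet_until`` holds the chain closed until that time, giving
    a programmable first-opening latency.
    """

    amplitudes: Sequence[float]  # pA, ascending, one per open state
    rates: np.ndarray
    noise_sigma: float = 0.15  # pA
    sampling_rate: float = 50_000.0  # Hz
    duration: float = 1.0  # s
    holding_potential: float = 50.0  # mV
    baseline: float = 0.0  # pA
    quiet_until: float = 0.0  # s
    seed: int = 0


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary law π of the chain: π Q = 0, Σπ = 1."""
    q = np.asarray(rates, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise ValueError("rate matrix does not have a unique stationary law")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    return np.abs(pi)


def first_detectable_opening(
    state_per_sample: np.ndarray, sampling_rate: float, min_duration: int = 2
) -> float:
    """Time (s) of the first opening sustained for >= min_duration samples.

    Openings briefer than the idealization dead time are invisible to any
    analysis; this is the ground truth a latency estimate can be held to.
    NaN if no such opening exists.
    """
    open_ = (np.asarray(state_per_sample) > 0).astype(int)
    if len(open_) < min_duration:
        return float("nan")
    sustained = np.convolve(open_, np.ones(min_duration, dtype=int), mode="valid")
    idx = np.flatnonzero(sustained == min_duration)
    if idx.size == 0:
        return float("nan")
    return float(idx[0] / sampling_rate)


def generate_channel_trace(spec: TraceSpec) -> tuple["CurrentTrace", dict]:
    """Sample the chain exactly and return (trace, ground truth).

    Ground truth: ``segments`` [(state, start_s, end_s)], ``state_per_sample``,
    ``stationary``, ``first_opening_time`` (NaN and a ``quiet`` flag if the
    trace never opens).
    """
    from .ephys import CurrentTrace

    amps = np.asarray(spec.amplitudes, dtype=float)
    if np.any(np.diff(amps) <= 0):
        raise ValueError("amplitudes must be strictly increasing")
    k = len(amps)
    q = np.asarray(spec.rates, dtype=float).copy()
    if q.shape != (k + 1, k + 1):
        raise ValueError(f"rates must be {(k + 1, k + 1)} for {k} open levels")
    if np.any(q[~np.eye(k + 1, dtype=bool)] < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    np.fill_diagonal(q, 0.0)
    out_rate = q.sum(axis=1)

    rng_chain, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    t = spec.quiet_until
    state = 0
    segments: list[tuple[int, float, float]] = []
    if t > 0:
        segments.append((0, 0.0, min(t, spec.duration)))
    while t < spec.duration:
        if out_rate[state] <= 0:
            segments.append((state, t, spec.duration))
            break
        hold = rng_chain.exponential(1.0 / out_rate[state])
        end = min(t + hold, spec.duration)
        segments.append((state, t, end))
        t = end
        if t >= spec.duration:
            break
        state = rng_chain.choice(k + 1, p=q[state] / out_rate[state])

    n = int(round(spec.duration * spec.sampling_rate))
    times = np.arange(n) / spec.sampling_rate
    starts = np.array([s for _, s, _ in segments])
    states = np.array([st for st, _, _ in segments])
    state_per_sample = states[np.clip(np.searchsorted(starts, times, "right") - 1, 0, len(states) - 1)]

    level_current = np.concatenate([[0.0], amps])
    samples = (
        spec.baseline
        + level_current[state_per_sample]
        + spec.noise_sigma * rng_noise.standard_normal(n)
    )
    trace = CurrentTrace(samples, spec.sampling_rate, spec.holding_potential, "synthetic")

    opening = [s for st, s, _ in segments if st > 0]
    ground_truth = {
        "segments": segments,
        "state_per_sample": state_per_sample,
        "stationary": stationary_distribution(spec.rates),
        "first_opening_time": opening[0] if opening else float("nan"),
        "quiet": not opening,
    }
    return trace, ground_truth
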