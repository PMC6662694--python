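"""Single-channel current-trace analysis.

A patch-clamp trace of peptide-induced channel activity is summarized by its
all-points histogram (modes = closed and open conductance levels), a set of
detected opening levels (amplitudes above the closed baseline), a
half-amplitude idealization into discrete dwell events, conductances
G = I/V, and pore radii from a cylindrical-pore (Hille-type) conductance
model:

    cylinder                 G = κ·π·r² / l
    with access resistance   1/G = l/(κ·π·r²) + 1/(2·κ·r)

with κ the electrolyte conductivity (S/m) and l the pore length (nm).
Defaults κ = 3.5 S/m (≈250 mM KCl + 50 mM MgCl₂, room temperature) and
l = 4 nm (bilayer span).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.signal import find_peaks


@dataclass
class CurrentTrace:
    """Sampled current in pA at a fixed holding potential."""

    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    holding_potential: float  # mV
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class ConductanceLevel:
    """One detected opening level (amplitude above the closed baseline)."""

    level_index: int  # 1-based, ascending amplitude
    mean_amplitude: float  # pA
    amplitude_sd: float  # pA
    conductance: float = float("nan")  # pS
    pore_radius: float = float("nan")  # nm


# ---------------------------------------------------------------------------
# trace I/O

def read_trace_delimited(path: str | Path) -> CurrentTrace:
    """Two-column ``time,current`` text (or one current column) with
    ``# key=value`` header comments for rate_hz / potential_mv / label."""
    meta = {"rate_hz": None, "potential_mv": None, "label": ""}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        rows.append([float(v) for v in line.replace(",", " ").split()])
    arr = np.asarray(rows, dtype=float)
    current = arr[:, -1]
    if meta["rate_hz"] is not None:
        rate = float(meta["rate_hz"])
    elif arr.shape[1] >= 2:
        rate = 1.0 / float(np.median(np.diff(arr[:, 0])))
    else:
        raise ValueError("sampling rate neither in header nor derivable from times")
    if meta["potential_mv"] is None:
        raise ValueError("holding potential missing from header (# potential_mv=...)")
    return CurrentTrace(current, rate, float(meta["potential_mv"]), str(meta["label"]))


def write_trace_delimited(trace: CurrentTrace, path: str | Path) -> None:
    head = (
        f"# rate_hz={trace.sampling_rate}\n"
        f"# potential_mv={trace.holding_potential}\n"
        f"# label={trace.label}\n"
    )
    body = "\n".join(
        f"{t:.6f},{c:.5f}" for t, c in zip(trace.times, trace.samples)
    )
    Path(path).write_text(head + body + "\n")


def read_trace_raw(path: str | Path) -> CurrentTrace:
    """Little-endian float32 stream with a JSON sidecar ``<path>.json``
    holding rate_hz, potential_mv and optional label."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype="<f4").astype(float)
    return CurrentTrace(
        data, float(meta["rate_hz"]), float(meta["potential_mv"]), meta.get("label", "")
    )


# ---------------------------------------------------------------------------
# histogram and level detection

def all_points_histogram(
    trace: CurrentTrace, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of every sample. Returns (counts, bin_edges) on a uniform
    grid of ``bin_width`` pA covering the sample range."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(trace.samples.min() / bin_width) * bin_width
    hi = np.ceil(trace.samples.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(trace.samples, bins=edges)
    return counts, edges


def _histogram_levels(
    trace: CurrentTrace, max_levels: int, bin_width: float, min_separation: float
) -> list[ConductanceLevel]:
    counts, edges = all_points_histogram(trace, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
    peaks, props = find_peaks(
        smooth,
        prominence=max(smooth.max() * 1e-4, 1.0),
        distance=max(int(min_separation / bin_width), 1),
    )
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
        props = {"prominences": np.array([smooth.max()])}
    baseline = centers[peaks[np.argmax(smooth[peaks])]]
    open_centers = sorted(
        c for c in centers[peaks] if c > baseline + min_separation
    )
    # keep the max_levels most prominent, then re-sort ascending
    if len(open_centers) > max_levels:
        prom = {centers[p]: pr for p, pr in zip(peaks, props["prominences"])}
        open_centers = sorted(
            sorted(open_centers, key=lambda c: -prom[c])[:max_levels]
        )
    if not open_centers:
        return []
    # bin centers are quantized to the histogram grid; refine each mode by
    # iterating a symmetric truncated mean (unbiased for symmetric noise,
    # and unlike free EM it cannot drift off to absorb a neighbouring mode)
    means = np.array([baseline] + open_centers)
    sds = np.zeros_like(means)
    near_base = trace.samples[np.abs(trace.samples - baseline) <= 3 * bin_width]
    mad = np.median(np.abs(near_base - np.median(near_base))) if near_base.size else 0.0
    sigma0 = max(1.4826 * mad, bin_width)
    for i, m in enumerate(means):
        gaps = np.abs(np.delete(means, i) - m)
        w = min(2.5 * sigma0, 0.5 * gaps.min()) if gaps.size else 2.5 * sigma0
        for _ in range(3):
            sel = trace.samples[np.abs(trace.samples - m) <= w]
            if sel.size == 0:
                break
            m = float(sel.mean())
        means[i] = m
        sds[i] = float(sel.std(ddof=0)) if sel.size else 0.0
    baseline = means[0]
    order = np.argsort(means[1:])
    levels = []
    for k, j in enumerate(order, start=1):
        levels.append(
            ConductanceLevel(k, float(means[1 + j] - baseline), float(sds[1 + j]))
        )
    return levels


def _gmm_levels(
    trace: CurrentTrace, max_levels: int, random_state: int = 0
) -> list[ConductanceLevel]:
    from sklearn.mixture import GaussianMixture

    x = trace.samples.reshape(-1, 1)
    # subsample long traces: BIC selection does not need every point
    if len(x) > 200_000:
        rng = np.random.default_rng(random_state)
        x = x[rng.choice(len(x), 200_000, replace=False)]
    best, best_bic = None, np.inf
    for k in range(1, max_levels + 2):
        gm = GaussianMixture(n_components=k, random_state=random_state).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    means = best.means_.ravel()
    weights = best.weights_
    sds = np.sqrt(best.covariances_.ravel())
    baseline = means[np.argmax(weights)]
    order = np.argsort(means)
    levels = []
    for m, s in zip(means[order], sds[order]):
        if m > baseline + 1e-9:
            levels.append(ConductanceLevel(len(levels) + 1, float(m - baseline), float(s)))
    return levels[:max_levels]


def detect_levels(
    trace: CurrentTrace,
    max_levels: int = 5,
    method: str = "histogram",
    bin_width: float = 0.05,
    min_separation: float = 0.3,
) -> list[ConductanceLevel]:
    """Detect opening levels as amplitudes above the closed-state baseline.

    ``histogram`` (default) picks modes of the smoothed all-points histogram,
    with the most populated mode as baseline; ``gmm`` fits Gaussian mixtures
    with BIC selection of the component count. Levels separated by less than
    the histogram resolution merge into one. An empty list means a quiet
    trace.
    """
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    if method == "histogram":
        return _histogram_levels(trace, max_levels, bin_width, min_separation)
    if method == "gmm":
        return _gmm_levels(trace, max_levels)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# idealization

def idealize(
    trace: CurrentTrace,
    levels: list[ConductanceLevel],
    baseline: float | None = None,
    min_duration: int = 2,
) -> pd.DataFrame:
    """Half-amplitude idealization into non-overlapping dwell events.

    Each sample is assigned to the nearest of {baseline, level amplitudes}
    (equivalent to thresholds midway between adjacent levels); runs shorter
    than ``min_duration`` samples are absorbed into their predecessor.
    Returns events (level_index ≥ 1 only) with columns level_index,
    start (s), dwell (s).
    """
    if not levels:
        raise ValueError("need at least one detected level")
    if baseline is None:
        counts, edges = all_points_histogram(trace, 0.05)
        baseline = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    amps = np.array([0.0] + [lv.mean_amplitude for lv in levels])
    targets = baseline + amps
    assign = np.argmin(np.abs(trace.samples[:, None] - targets[None, :]), axis=1)

    # run-length encode, then apply the dead-time rule: openings shorter
    # than min_duration revert to baseline, baseline gaps shorter than
    # min_duration are absorbed into the surrounding opening
    change = np.flatnonzero(np.diff(assign)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(assign)]]))
    vals = assign[starts]
    runs: list[list[int]] = []  # [level, length]
    for v, ln in zip(vals, lengths):
        v, ln = int(v), int(ln)
        if ln < min_duration:
            v = 0 if v >= 1 else (runs[-1][0] if runs else 0)
        if runs and runs[-1][0] == v:
            runs[-1][1] += ln
        else:
            runs.append([v, ln])
    rows = []
    pos = 0
    for lvl, ln in runs:
        if lvl >= 1:
            rows.append(
                dict(
                    level_index=lvl,
                    start=pos / trace.sampling_rate,
                    dwell=ln / trace.sampling_rate,
                )
            )
        pos += ln
    return pd.DataFrame(rows, columns=["level_index", "start", "dwell"])


def latency(
    trace: CurrentTrace,
    detection_threshold: float | None = None,
    levels: list[ConductanceLevel] | None = None,
    min_duration: int = 2,
) -> float:
    """Time (s) of the first detected opening; NaN (with warning) if quiet.

    With ``levels`` given, the first idealized event; otherwise the first run
    of at least ``min_duration`` samples above ``detection_threshold``.
    """
    if levels:
        ev = idealize(trace, levels, min_duration=min_duration)
        if len(ev):
            return float(ev["start"].iloc[0])
    elif detection_threshold is not None:
        above = trace.samples >= detection_threshold
        run = 0
        for i, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= min_duration:
                return (i - min_duration + 1) / trace.sampling_rate
    else:
        raise ValueError("provide detection_threshold or levels")
    warnings.warn("no opening events detected: latency undefined", stacklevel=2)
    return float("nan")


# ---------------------------------------------------------------------------
# conductance and pore geometry

def conductance(amplitude_pa: float, potential_mv: float) -> float:
    """G in pS from amplitude (pA) and holding potential (mV): pA/mV = nS."""
    if potential_mv == 0:
        raise ValueError("holding potential must be nonzero")
    return amplitude_pa / potential_mv * 1000.0


def pore_radius(
    conductance_ps: float,
    conductivity: float = 3.5,  # S/m
    pore_length: float = 4.0,  # nm
    model: str = "cylinder",
) -> float:
    """Pore radius (nm) from conductance (pS).

    ``cylinder``: r = sqrt(G·l / (π·κ)). ``cylinder_with_access_resistance``
    adds the Hall access term 1/(2κr) on each conductance path and solves
    the monotone relation by bracketing. Non-positive G gives 0.
    """
    if conductivity <= 0 or pore_length <= 0:
        raise ValueError("conductivity and pore_length must be positive")
    if conductance_ps <= 0:
        return 0.0
    g = conductance_ps * 1e-12  # S
    l = pore_length * 1e-9  # m
    if model == "cylinder":
        return float(np.sqrt(g * l / (np.pi * conductivity)) * 1e9)
    if model == "cylinder_with_access_resistance":
        def f(r_m: float) -> float:
            return l / (conductivity * np.pi * r_m**2) + 1.0 / (
                2.0 * conductivity * r_m
            ) - 1.0 / g
        # radii are O(1e-10) m: default absolute xtol would be ~1% of r
        return float(brentq(f, 1e-15, 1e-5, xtol=1e-20, rtol=1e-14) * 1e9)
    raise ValueError(f"unknown model {model!r}")


def summarize_levels(
    levels: list[ConductanceLevel],
    potential_mv: float,
    conductivity: float = 3.5,
    pore_length: float = 4.0,
    model: str = "cylinder",
) -> pd.DataFrame:
    """Level table (amplitude ± sd, conductance pS, estimated radius nm).

    κ, l and the pore model are echoed in ``DataFrame.attrs['params']``:
    radius estimates are model-dependent and meaningless without them.
    """
    rows = []
    for lv in levels:
        g = conductance(lv.mean_amplitude, potential_mv)
        rows.append(
            dict(
                level_index=lv.level_index,
                mean_amplitude=lv.mean_amplitude,
                amplitude_sd=lv.amplitude_sd,
                conductance=g,
                pore_radius=pore_radius(g, conductivity, pore_length, model),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["level_index", "mean_amplitude", "amplitude_sd", "conductance", "pore_radius"],
    )
    df.attrs["params"] = dict(
        potential_mv=potential_mv, conductivity=conductivity,
        pore_length=pore_length, model=model,
    )
    return df
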