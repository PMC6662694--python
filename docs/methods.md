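# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Sequence descriptors

Net charge is the formal charge at neutral pH: K, R → +1; D, E → −1; H → 0;
plus +1 for a free N-terminus and −1 for a free-acid C-terminus (0 when
amidated). Histidine is counted neutral because its pKa (~6) sits below
physiological pH; no titration model is attempted. Mean hydrophobicity ⟨H⟩
is the length-normalized sum over the Fauchère–Pliška octanol/water scale,
the scale used by the HeliQuest web service; other scales can be supplied as
`HydrophobicityScale` objects. The hydrophobic moment places residue j at
azimuth j·δ with δ = 100° (the ideal α-helical repeat of 3.6 residues/turn)
and reports the length-normalized magnitude of the vector sum. The phase
origin is residue 0; the magnitude is origin-independent (asserted in
tests). Values are reported to 3 decimals.

## Trajectory model

Internal units are Å and picoseconds, membrane normal along z. Orthorhombic
boxes only. Readers: multi-model PDB (MDAnalysis), multi-frame GRO series
(mdtraj, nm → Å ×10), and a documented plain-text frame format used by the
synthetic generator. GRO files carry no chain records, so peptide copies are
delimited wherever the residue numbering resets or the peptide/non-peptide
character changes; peptide residues are recognized by the 20 standard
three-letter names. Leaflets are assigned per frame: the midplane is the
mean z of all phosphate atoms, upper = z above it. Inter-atomic distances
apply the minimum-image convention in x,y only; z is treated as
non-periodic so that insertion depths keep a meaningful sign (peptides
approach from one side of the bilayer).

## Circular statistics of backbone dihedrals

phi(i) = C(i−1)–N(i)–CA(i)–C(i) and psi(i) = N(i)–CA(i)–C(i)–N(i+1), IUPAC
sign convention, degrees in (−180, 180]. phi of the first and psi of the
last residue do not exist and are omitted, never zero-filled. The
per-residue summary is the circular mean ψ̄ = atan2(Σsin, Σcos) and the
circular variance Var = 1 − R/n with R² = (Σcos)² + (Σsin)²; dividing R by
n keeps Var in [0, 1] (0 = rigid, 1 = uniformly dispersed). Multi-copy
profiles concatenate the per-frame samples of every copy into one pooled
sample per residue index rather than averaging per-copy means; per-copy
profiles remain available. A zero resultant leaves the mean undefined
(NaN, warned) while the variance is still well defined (=1). An
equilibration window can be excluded via the `frame_range` argument; no
window is excluded by default since the appropriate choice is
system-dependent.

## Insertion depth

Reference point: Cα (a center-of-mass option exists, `reference_atom`).
depth = z(upper phosphate plane) − z(Cα), so positive = inserted below the
plane — the sign convention used throughout. The plane is recomputed per
frame from the upper-leaflet phosphates. Copies engaging the lower leaflet
(not expected with the standard setup) can be handled by reflecting z
(`mirror_lower=True`). The dominant spatial period of a depth profile is
the argmax of a zero-padded periodogram of the mean-centred profile,
restricted to periods shorter than the profile; a helix parallel to the
plane yields ~3.6 residues.

## Aggregation

Contact definition: copies are adjacent when at least `min_contacts` (default
1) inter-copy Cα–Cα distances fall at or below `contact_cutoff` (default
7 Å — roughly two Cα van der Waals shells plus side-chain reach; there is no
community-standard value, so both parameters are echoed into output
metadata). Clusters are connected components of the adjacency graph
(scipy.sparse.csgraph; validated against a brute-force DFS oracle in the
tests). Populations are tallied per frame into monomer/dimer/trimer/
tetramer/≥5; a cluster counts as *stable* only after its exact membership
has persisted `persistence` consecutive frames (default 10), which excludes
transient brushes; monomers are exempt. Heatmaps average the per-frame
distance matrices elementwise over the full analysis window by default.
Mediating residues are ranked by ascending time-averaged distance per
contacting copy pair; pairs whose minimal entry exceeds the cutoff are
bridged by intermediates, not direct contacts, and are skipped.

## Channel analysis

All-points histogram: uniform bins, default width 0.05 pA (≈ σ/3 at
study-like noise of 0.15 pA). Level detection (default path): modes of the
Gaussian-smoothed histogram via peak-picking; the most populated mode is the
closed baseline (mode, not mean — robust to rare openings); open levels are
modes above baseline. Because mode positions are quantized to the bin grid,
each mode is refined by an iterated symmetric truncated mean (window =
min(2.5σ̂, half the gap to the nearest mode), three iterations); unlike free
EM refinement this cannot drift off to absorb a neighbouring mode's tail.
An alternative `gmm` path fits Gaussian mixtures with BIC selection of the
component count. Levels separated by less than the histogram resolution
merge — a physical resolution limit, exercised in tests.

Idealization: each sample is assigned to the nearest of {baseline, levels}
(equivalent to half-amplitude thresholds); the dead-time rule then reverts
openings shorter than `min_duration` samples (default 2) to baseline and
absorbs equally short closed gaps into the surrounding opening. Latency is
the start of the first idealized event; a trace with no events returns NaN
with a warning. Conductance G = amplitude/potential (pA/mV → nS, reported
in pS). Pore radius: cylinder model r = √(G·l/(π·κ)), defaults κ = 3.5 S/m
(≈250 mM KCl + 50 mM MgCl₂ at room temperature) and l = 4 nm (bilayer
span); the variant with Hall access resistance solves
1/G = l/(κπr²) + 1/(2κr) by bracketed root finding with tolerances far
below the 0.1 nm scale of the answer. Radius estimates are model-dependent;
κ, l and the model name are always echoed in output metadata. Optional
low-pass filtering is off by default (synthetic traces are unfiltered).

## Synthetic trajectory generator

Backbones (N, CA, C) are built frame-by-frame from per-residue (φ, ψ)
sampled from von Mises distributions (mean, concentration κ per residue) via
sequential internal-coordinate placement with fixed ideal bond lengths and
angles (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; ω = 180°), vectorized over
frames. Only dihedrals vary: sufficient for dihedral, depth and contact
analyses, not for energetics. The closed-form circular variance of a von
Mises law, 1 − I₁(κ)/I₀(κ), is the recovery target in tests. Each frame is
axis-aligned (first principal component of the CAs along x) and rigid-body
placed above a two-leaflet lattice of pseudo-phosphates (planes ±19 Å,
16×16 sites per leaflet in a 128 Å box — the scale of a 512-lipid patch;
per-frame Gaussian z-jitter, σ = 1 Å). Copies start 30 Å above the upper
plane at anchors kept ≥20 Å apart (segment-aware, periodic in x,y); in
crowded boxes the separation relaxes gradually rather than failing.

Insertion schedules drive listed residues linearly to signed target depths;
they are applied as per-residue z displacements with a 3-residue taper, so
a depth-programmed trajectory slightly perturbs dihedrals — dihedral and
depth recovery are therefore exercised on separate specs. Aggregation
schedules drive listed copies into a stack: each member is rolled so its
central contact residues face the partner, splayed by an alternating pitch,
and its contact-residue CAs are clamped onto the predecessor's at a fixed
interface gap (4.2 Å) with the same tapered deformation. The clamp makes the
programmed residues the closest pairs by construction; a purely rigid-body
approach cannot, because the helical phase recurs every ~3.6 residues.
Random streams are spawned independently per copy and subsystem, so adding
copies never perturbs existing ones; everything is deterministic given the
seed.

## Synthetic current generator

A continuous-time Markov chain over {closed, open₁..open_K} is sampled
exactly (exponential holding times from the rate matrix), discretized at the
sampling rate (study value 50 kHz), and Gaussian noise is added. The
stationary law π (πQ = 0) is computed by null-space solve and serves as the
occupancy target. `quiet_until` holds the chain closed for a programmable
initial interval, giving a known first-opening latency; the matching ground
truth for a latency estimate is the first opening sustained at least the
idealization dead time (`first_detectable_opening`), since briefer openings
are invisible to any analysis.

## What the synthetic data does and does not show

The generators emulate the *statistical structure* the analyses assume:
von Mises dihedral scatter about helical means, programmed depths relative
to a noisy phosphate plane, geometrically clamped contacts, Markovian
gating with Gaussian noise. They do not emulate force-field physics, lipid
tails, side-chain packing, correlated (1/f or filtered) recording noise, or
baseline drift. Passing recovery tests therefore demonstrates that the
estimators are correct and unbiased under their stated assumptions — not
that real trajectories or recordings satisfy those assumptions.

## Problem sizes used in the automated checks

Flexibility recovery runs 8 copies × 5000 frames (40 000 pooled samples per
residue); depth recovery 8 × 600 frames; aggregation 8 × 200 frames plus
100 randomized partition cross-checks; channel recovery 20 traces of 2 s at
50 kHz. At these sizes every recovered quantity sits an order of magnitude
inside its tolerance band, and the full suite completes in well under a
minute on one core.

## Known limitations

- Backbone-only geometry (plus optional Cβ-free representation): analyses
  requiring side-chain atoms are out of scope.
- Depth treats z as non-periodic; systems where peptides wrap through the
  z boundary are not supported.
- The histogram level detector assumes approximately Gaussian, symmetric
  noise about each level; strongly skewed or drifting baselines should be
  detrended first.
- Published pore radii depend on unpublished model constants in the source
  experiments; the cylinder model with the defaults above reproduces the
  published radius column at its printed precision for most cells, but the
  radius column should be read as model-calibrated, not absolute.
- Dwell-time summaries stop at means/distributions; kinetic rate-constant
  fitting is out of scope.
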