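# Methods

This note records what `cdrloop` computes, the assumptions behind it, and
the choices made where the design was genuinely open.

## Data model and units

An `Ensemble` is an ordered list of frames sharing one topology (atoms
identified by chain, author residue number, optional insertion code, and
atom name — unique per topology).  Every coordinate in memory is in nm;
PDB files (ångström) are converted exactly once at the I/O boundary.  This
lets the geometric thresholds (0.25 nm, 0.5 nm, 0.2 nm, 0.4 nm) be used
verbatim everywhere downstream.  `frame_spacing` (default 2 ps) is pure
metadata used only by snapshot thinning.

Input is multi-model PDB (plus a whitespace XYZ-per-frame dialect for
synthetic fixtures).  The topology comes from the first MODEL; later models
must match it atom for atom, and the first mismatching model is named in
the error.  Only blank/'A' alternate locations are kept (deterministic
topology); hydrogens are passed through untouched — H-bond analysis
therefore requires files with explicit polar hydrogens and raises a
dedicated error otherwise, rather than inventing hydrogen positions.  gemmi
does the PDB parsing and writing; a line-level pre-validation rejects
malformed coordinate fields with a line number, because a silent zero would
be worse than a crash.  No periodic-boundary handling anywhere: ensembles
must contain a gathered (whole) solute.

## Superposition and fitted RMSD

Least-squares rototranslational superposition uses the SVD of the
covariance of the centred fit coordinates with a determinant sign
correction, so only proper rotations are produced.  Weights are uniform (no
mass weighting: the RMSD definition is over "all atoms" of the selection,
equally).  The residual is evaluated by explicitly applying the transform;
the closed-form `GA+GB-2·trace` expression cancels catastrophically near
zero and is not used.  Degenerate fits (< 3 atoms, collinear atoms) raise.

`fitted_rmsd(a, b, fit, rmsd)` superposes on the *fit* selection and
measures over the *rmsd* selection.  The least-squares minimum makes it
symmetric (observed ≤ 1e-9 nm asymmetry) and invariant under rigid motion
of either frame — both are asserted as test properties, and the whole
superposition path is checked against an independent quaternion
characteristic-polynomial oracle, which parametrises exactly the proper
rotations.

"Backbone" for fitting defaults to atom names N, CA, C (the carbonyl O
excluded).  Conventions differ between force fields on whether O (or the
amide H) belongs to the fit; N/CA/C is the minimal common choice, and the
fit selection is an ordinary selection expression, so callers can widen
it.  The residue extent of the flanking framework regions is likewise
supplied by the caller — there is no universal definition.

## Interaction criteria

H-bond: d(H…A) < 0.25 nm and ∠(D–H–A) > 135°, both strict; stacking:
centre-of-geometry distance ≤ 0.5 nm and plane angle ≤ 30°, both
inclusive.  The asymmetry (strict vs inclusive) follows the wording of the
criteria as stated ("is < … more than" vs "within … at most") and is
frozen into boundary tests.  Donor–hydrogen covalency is declared via
atom-name tables (e.g. HH11 belongs to NH1), never inferred from
distances: name conventions are format-stable, distance inference is not.
The planar-group atom tables are module constants a caller can copy and
override; Arg's guanidinium excludes CD by default.  Ring planes come from
the smallest principal axis of the group atoms (total least squares) —
every atom contributes, and the normal is stable under coordinate noise,
unlike triangle normals.  Only the distance + plane-angle test is applied;
no ring-offset (lateral displacement) criterion and no T-shaped or
cation–π classes.

Occurrence tables carry `n_frames`, `n_hits`, fraction, percent and a
status column: interactions whose atoms are absent from a variant's
topology (mutated away) are `na` with NaN fraction, deliberately distinct
from 0.0 — "never formed" and "cannot exist" are different findings.

## Clustering

Pooled frames from all variants are clustered jointly (the default; a
single-ensemble call is just a one-element list) on the fitted-RMSD metric
with a strict 0.2 nm neighbour cutoff.  The greedy neighbour-count
algorithm (Daura-style) defines one cluster per iteration: the remaining
frame with most remaining neighbours is the central member structure
(CMS).  The source formulation leaves ties open; here ties break to the
lowest pooled index (ensemble order, then frame order), which makes the
partition a pure function of the matrix.  Partitioning, non-increasing
cluster sizes, and agreement with a literal brute-force implementation (on
all random matrices ≤ 12 frames, 200 trials) are asserted in tests.

The occurrence filter keeps clusters at ≥ 2 % overall occurrence.  The
threshold is inclusive by default ("at least 2 %"), with a flag for the
strict variant, since both readings exist in practice; removed mass is
reported as `other` so occupancy rows still sum to 1.  The full RMSD
matrix is held in memory — fine to roughly 30k pooled frames (a 30k²
float64 matrix is ~7 GB; in practice stay below ~20k) — and `stride` is
the supported route to scale, mirroring the usual 1-frame-per-ns style of
subsampling.  The matrix builder runs batched Kabsch fits (chunked einsum +
stacked SVD), about 15 s for 2 000 pooled frames on one core.

## Distances, snapshots, flexibility

Distance monitoring reduces an aromatic ring to its centre of geometry and
measures the Euclidean distance to each probe atom per frame.  Which atoms
of residue 94h count as "central" depends on its identity, so the probe
table is configuration with defaults per residue type: Arg → CZ, NE, NH1,
NH2; Lys → CE, NZ; Thr → CB, OG1.  Histograms use uniform bins anchored at
zero (default width 0.01 nm — fine enough to resolve the 0.25/0.4/0.5 nm
thresholds cleanly) and are density-normalised; the below-threshold
fraction (default 0.4 nm, strict) equals the histogram mass below the
threshold when it falls on a bin edge.

Snapshot extraction keeps every k-th frame with k = round(interval /
spacing); the default 1000 ps interval on 2 ps spacing gives 1 frame per
ns.  The flexibility summary superposes every frame onto a reference
(default: the first frame; a crystal-structure frame can be passed instead)
on the fit selection, then reports per-atom RMSF and the eigenvalues of the
3×3 covariance of pooled per-atom displacements.  One dominant eigenvalue
is the quantitative signature of a "narrow, elliptical" positional cloud;
three comparable eigenvalues mean isotropic wobble.

## The synthetic generator

The generator emulates the statistical structure of per-variant loop
ensembles, not their physics: a rigid framework scaffold plus a loop of
pseudo-residues (numbered 95–102 by default, so real selection expressions
work); K ≤ 4 loop templates made by displacing all loop atoms by constant
vectors, which makes the pairwise fitted RMSD between templates *exactly*
the displacement difference (default 0.5 nm); per-frame template choice by
variant-specific mixture weights; isotropic Gaussian noise (default
0.03 nm/axis) on loop atoms only, so the fit region stays internally rigid
and fitted RMSD isolates loop variation; and a random rigid motion of the
whole molecule per frame (rotations up to 180°, translations up to 2 nm)
so nothing downstream can rely on lab-frame coordinates.

The default study conditions — 4 variants × 500 frames, K = 3, σ =
0.03 nm — put within-template frame pairs at ≈ σ√6 ≈ 0.073 nm fitted RMSD
(well under the 0.2 nm cutoff) and between-template pairs at ≥ 0.5 nm
(well over), so cluster recovery is expected to be exact while occupancies
carry honest multinomial sampling error (binomial SE ≈ 0.02 at w = 0.7,
n = 500).  Randomness uses numpy's PCG64 generator; each ensemble label
gets an independent stream derived from (seed, hash(label)), so adding a
variant never perturbs another's frames.  Interaction fixtures place
triads/ring pairs at exact requested geometry, nudged by ulps onto the
safe side of a requested boundary value (a 0.25 nm probe must never
measure 0.2499…97 nm) and self-checked to 1e-9 before use.

What the generator does *not* emulate: physical loop energetics, correlated
backbone motion, solvent, within-cluster anharmonicity, or gradual
conformational drift.  Passing recovery tests therefore demonstrates the
correctness of the measurement and clustering machinery, not that real
trajectories contain well-separated conformations.

## Numerical choices and degenerate inputs

Strictness of every inequality is stated above and tested at the boundary.
Collinearity (plane fits, fit selections) is detected via the second
singular value at a 1e-10 relative tolerance.  Plane angles use
arccos(|dot|), so normal orientation never matters.  Empty selections warn
rather than raise (an absent chain is data, not a syntax error) except
where an operation requires atoms.  Occupancy "other" columns are clipped
at zero against floating-point dust.  Output tables are written with 6
significant digits, so re-running a command with identical inputs
reproduces identical files.

## Known limitations

Multi-model PDB is the only trajectory carrier (no DCD/XTC/TRR); inputs
must be whole molecules; hydrogens are never added; cluster counts from
greedy neighbour clustering depend on the cutoff and have no significance
measure; and the in-memory matrix bounds pooled frame counts (use
`stride`).  The CLI is a thin wrapper — anything beyond the standard
workflow is meant to be scripted against the library API.
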