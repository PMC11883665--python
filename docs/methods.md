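# Methods

This note records the models, conventions and numerical choices behind
`slicefit`, and what its synthetic fixtures do and do not demonstrate.

## Confidence semantics and trimming

A predicted model's B-factor column holds one of four score types: pLDDT
(0–100), fractional pLDDT (0–1), an estimated positional error in Å, or an
already-converted pseudo-B factor (Å²). The score is per residue; where
atoms within a residue disagree, the Cα atom's value is taken (predictors
emit per-residue constants, and Cα is present in every usable residue).
Non-polymer entities are dropped on read with a logged count.

Trimming removes whole residues. Comparisons are strict and boundary-equal
residues are kept: pLDDT-type scores are removed when strictly *below* the
threshold, error-type scores when strictly *above* it. Defaults: pLDDT 70
(0.70 fractional), error 1.75 Å. For a model already carrying pseudo-B
factors the threshold is supplied in pLDDT units and converted first, and
residues strictly above the converted value are removed. Trimming is
monotone in the threshold and idempotent (both property-tested).

## Pseudo-B conversion

For a positional error estimate *d* (Å), *B* = (8π²/3)·*d*² — the
isotropic displacement parameter corresponding to a mean-square
displacement of *d*². pLDDT is first mapped to an error estimate with the
exponential fit *d*(p) = 1.5·exp(4·(0.7 − p/100)), a widely used mapping
for processing predicted models; the map is an ordinary function argument
(`error_map`) and any strictly decreasing callable can be substituted.
Both conversions are strictly monotone on their domains; conversion never
touches coordinates or residue counts.

## Slicing

Coordinate methods cluster the Cα coordinate table in 3-D:

* `birch` (default) — BIRCH with leaf threshold 2.5 Å (about one Cα
  step, so subcluster leaves stay sub-domain sized), global count `k`.
* `kmeans` — seeded, 10 restarts.
* `agglomerative` — Ward linkage.
* `auto_density` — DBSCAN (eps 8 Å, min 5 points); noise points join
  their nearest cluster centroid; the unit count emerges automatically.

PAE slicing never consults coordinates. The matrix is symmetrised by the
element-wise minimum of the two directions (a conservative affinity, since
the PAE need not be symmetric); pairs below the 5 Å cutoff get an edge of
weight 1/max(PAE, 0.2); greedy modularity maximisation (networkx, with a
resolution parameter, default 1) yields the communities. Communities
smaller than 10 residues — too small to be useful search models — are
absorbed into the community with the lowest mean symmetrised PAE to them,
keeping the partition a pure function of the PAE.

Slices are canonically numbered 1…k by descending residue count (ties by
earliest residue), matching the place-largest-first search convention.
Merging down to a maximum split count clusters the slice Cα centroids
agglomeratively with **single** linkage (nearest units merge first — the
minimal reading of "cluster the centroids") and unions each group.
Exported slices keep the parent's author residue numbering; slices with
two or more sequence-discontiguous segments are flagged as fragmented in
the colour key, since such slices can pack poorly.

## Density simulation and scores

A map is a voxel grid with origin, voxel size and nominal resolution
(MRC/CCP4 2014 via gemmi; float32 grids round-trip bit-faithfully). Model
density places an isotropic Gaussian of width σ = resolution/(π√2) at each
atom, normalised to unit total weight per atom (grid sum ≈ atom count);
kernels are rasterised to 4σ and normalised against the unclipped patch
sum, making interior density exactly covariant under whole-voxel shifts.

* **CC** — Pearson correlation over (optionally masked) voxels; errors on
  zero variance.
* **MI** — joint 20-bin equal-width histogram, natural log (nats);
  constant maps give 0 by convention.
* **FSCavg** — unweighted mean of per-shell Fourier correlations, shells
  one Fourier voxel wide, from the first non-DC shell to 1/resolution
  (else Nyquist); non-cubic grids are zero-padded to a cube.
* **SMOC** — the whole model is simulated once; each residue is scored by
  the Manders coefficient Σxy/√(Σx²·Σy²) between simulated and
  experimental map over the footprint (voxels within max(2.5 Å, 2σ) of
  any atom) of a 9-residue sliding sequence window, truncated at chain
  ends. Scoring a model against its own simulated map gives exactly 1
  per residue.
* **overlap_map / overlap_model** — each map is thresholded at 1× its own
  standard deviation; overlap_model is the fraction of model-footprint
  voxels inside the map footprint and overlap_map the converse. These are
  deliberately simple footprint-ratio statistics that tell the classifier
  how much of the map the model explains and vice versa.

For classification, CC/MI/FSCavg are evaluated over the placed model's
neighbourhood (bounding box + one kernel width): a correctly placed slice
of a larger assembly then scores near 1 regardless of how much of the map
it covers, while the overlap scores retain the global size signal. A
placement in a locally flat region gets CC 0 by convention.

## Placement classifier

An SGDClassifier (scikit-learn) with log loss — i.e. logistic regression
fitted by stochastic gradient descent — over the six scores. Default
hyperparameters are the selected values of a randomized accuracy-scored
search: α 0.001, L2 penalty, inverse-scaling learning rate (η₀ 100,
power_t 0.9), validation fraction 0.2, ε 0.1. An optional seeded random
search over the printed space is provided but off by default. Perceptron
loss is accepted for training experiments but refused at prediction time
(it yields no probabilities).

Features are standardized with train-set mean/SD; at η₀ = 100 this is a
numerical necessity, and the statistics are stored in the model JSON and
reused verbatim at prediction time. The map's nominal resolution is
carried in every score vector but excluded from the feature set by
default (including it was found to hurt generalisation). Training sets
are balanced by undersampling the majority class; train/test splits are
made at map granularity so evaluation is always against unseen maps —
many placements are scored per map, and row-level splits would leak map
identity. The acceptance cutoff is 0.5, strict: a probability of exactly
0.5 fails. Models persist as plain JSON (weights, standardization,
hyperparameters) — no binary artefacts.

## Fitting engine

Orientations come from a deterministic quasi-uniform SO(3) grid: viewing
directions on a Fibonacci sphere at the requested angular step (10–90°),
each combined with in-plane twists at the same step; the identity is
always included and no randomness is involved. For each orientation the
slice is rotated about its Cα centroid, simulated on the target grid, and
scanned over every integer-voxel cyclic translation at once via FFT; the
score is the Pearson correlation of the shifted slice map against the
target, identical (to ~1e-16) to a direct rolled-grid scan. The peak is
refined to sub-voxel precision by per-axis parabolic interpolation of the
correlation, and top candidates are re-scored by a local CC over the
slice footprint (voxels above 1e-4 of the simulated peak).

Clash checking uses a ball tree (scikit-learn) over atom coordinates: the
clash fraction is the fraction of atoms of the *smaller* (fewer atoms) set
with any atom of the other set within 3.8 Å — one Cα–Cα step, so atoms of
a non-overlapping neighbour should fall outside it. The radius query is
exact, so the ball-tree result equals the O(n²) scan on every instance. A
pair overlaps when the fraction strictly exceeds 5 %; pairs whose
axis-aligned bounding boxes (2 Å margin) are disjoint skip the check.
Resolution is greedy in descending classifier probability (ties: more
atoms, then slice id), so the kept set is pairwise non-clashing and the
highest-probability placement always survives.

The pipeline has two modes. *Parallel* fits every slice independently
against the full map, gates each top placement with the classifier, then
resolves clashes among survivors. *Sequential* fits slices in descending
size order and, after each acceptance, zeroes map voxels within 3 Å of
the accepted atoms before the next fit — the fixed-model contract — so
later slices cannot re-occupy claimed density; a post-hoc clash pass is
still run as a safety net. The combined solution is scored by local CC
over the union footprint and banded: for 4.5–6 Å maps, > 0.507 is a good
fit and < 0.408 a likely misfit; beyond 6 Å the bounds are 0.559 and
0.4345; below 4.5 Å no band is defined and the verdict is indeterminate
with a logged note. Comparisons are strict at the bounds.

## Synthetic fixtures

`make_planted_model` grows each domain as a self-avoiding Cα random walk
(step 3.8 Å, non-consecutive exclusion 3 Å, gradually relaxed if the walk
stalls) confined to a sphere of radius 2.5·n^{1/3} Å; domain centroids sit
40 Å apart by default (≈ 4 domain radii for 60-residue domains, so
clustering methods should succeed exactly at the true k). Dummy N/C/O/CB
atoms at fixed offsets give atom-count realism. Core residues draw pLDDT
from N(90, 4), the 8-residue linkers from N(40, 5) — the linker tail
probability above 70 is < 1e-8 per residue, so default trimming removes
linkers deterministically in practice. The PAE is block-structured:
N(3, 0.5) within domains, N(25, 3) between, N(12, 2) for linker rows,
clipped at 0.2 Å, asymmetric by construction.

`make_target_map` renders posed models onto a shared grid (2 Å voxels and
6 Å resolution by default, padding 8 Å) plus optional white voxel noise.
`make_classifier_fixture` draws, per map group, a latent placement
quality (N(1, 0.2) for correct rows, N(0, 0.2) for incorrect, plus a
N(0, 0.05) per-map offset) and sets each feature to its class baseline
plus the class gap times (latent + overlap·noise), clipped to the score's
valid range; the baselines (e.g. CC 0.35 → 0.85) are module constants.
The default overlap of 0.5 puts each single feature at roughly AUC 0.87–
0.90 while the joint set reaches ≈ 0.99 — separable jointly, not singly —
which is exactly the property the ablation study checks. As overlap → 0
every feature separates alone.

What passing these fixtures does **not** show: the generators have no
realistic backbone geometry, no conformational error between prediction
and target (domains are rendered from the very model being placed), no
map anisotropy, sharpening artefacts or local-resolution variation, and
the classifier fixture is a statistical emulation of score rows, not
scores measured on deposited maps. Results on real EMDB/PDB data will be
worse than these clean-room numbers; the fixtures establish correctness
of the machinery, not field performance.

## Problem sizes and determinism

Default test-scale sizes: 60-residue domains (300 atoms each), 2 Å
voxels, 6 Å maps of ~20–60 voxels per side, a 30° angular step
(553 rotations), and a 2000-row classifier fixture over 20 maps. The
end-to-end placement of four slices completes in about a minute on one
CPU at these sizes. Every stochastic step (k-means, undersampling,
splits, SGD, noise) takes an explicit seed; the rotation grid and FFT
search are deterministic by construction, so identical configurations
reproduce coordinate outputs byte for byte.

## Known limitations

* Pose recovery is exact only for poses on the search grid; between grid
  points, accuracy is bounded by the angular step and the parabolic
  translation refinement (no local rigid-body refinement is performed).
* One PAE community method is provided (greedy modularity); other graph
  clusterings may cut different boundaries.
* The overlap scores are a documented stand-in with footprint-ratio
  semantics; other definitions with the same intent exist.
* No map sharpening, masking by local resolution, half-map handling or
  symmetry expansion; maps with differing geometry are resampled by
  trilinear interpolation only.
* Crystallographic placement (maximum-likelihood MR, phased translation
  functions) and model rebuilding are out of scope; the package prepares
  models and places them in real-space density only.
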