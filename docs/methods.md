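# Methods

`emsynapse` detects chemical synapses in serial-section transmission EM
(ssTEM) stacks — data with fine lateral but coarse axial resolution
(reference grid 4.5 × 4.5 × 45 nm).  The visual signature of a synapse is
the postsynaptic density: a dark, slightly curved sheet a few tens of
nanometres thick, flanked by a cloud of 40–50 nm vesicles on the
presynaptic side.  The detector is a two-stage learner: a pixel stage tuned
for recall proposes candidates, an object stage restores precision.

## Pipeline

1. **Axial upsampling.** The stack is linearly interpolated by a factor of
   2 along z (edge-aligned: `(n−1)·f+1` slices, original sections preserved
   exactly).  This gives the 3D filters the intermediate-slice context that
   the 10:1 anisotropy otherwise denies them.  Linear interpolation is used
   because it is the cheapest kernel that creates that context; no data is
   invented past the terminal sections.
2. **Filter bank (26 channels).** Gaussian-smoothed intensity (σ = 0.7, 1.0,
   1.6, 3.5, 5.0, 10.0), Hessian eigenvalues (σ = 1.6, 3.5, 5.0, 10.0; 3
   channels each), Laplacian of Gaussian (σ = 3.5, 5.0, 10.0), difference
   of Gaussians (σ = 5.0, 10.0; second sigma 0.66·σ), structure-tensor
   eigenvalues (σ = 5.0; inner gradient scale σ/2).  All sigmas are
   isotropic in pixels of the upsampled grid; all filtering is 3D with
   reflective boundaries; eigenvalues are sorted descending.  The dark-plate
   signature of a synaptic density appears as one strongly positive Hessian
   eigenvalue against two near-zero ones.
3. **Pixel classification.** A Random Forest (default 50 trees, grown to
   purity, √26 features per split) is trained on sparse voxel scribbles of
   three classes — synapse, membrane, everything else — and produces a
   per-voxel probability map.  The out-of-bag error is recorded as the
   stopping signal an annotator would use.  Features are computed on the
   upsampled grid but the forest is evaluated only at the slices that
   survive downsampling back to native sections; this is identical to
   predicting everywhere and then downsampling, at half the cost.
4. **Candidate detection.** The synapse-class map is thresholded at 0.5
   (strict `>`), connected components are extracted (26-connectivity, the
   most forgiving of diagonal-only contact across the coarse z step), and
   components outside [100, 10⁶] native voxels are discarded (inclusive
   bounds).  Each surviving bounding box is enlarged by ⌈500 nm /
   voxel⌉ per side — 112 px laterally, 12 slices axially at the reference
   resolution — so it can be assumed to contain the synapse's full extent.
5. **Graph-cut segmentation.** Inside each enlarged box the binary labeling
   minimizing `E(L) = Σ_p D_p(L_p) + β·#{6-neighbor pairs with unequal
   labels}` is found exactly by max-flow/min-cut.  The unary is twice the
   synapse probability, charged to the background label (`D(bkg) = 2p`,
   `D(syn) = 2(1−p)`), so the β = 0 limit coincides with the 0.5 detection
   threshold; the opposite reading of the doubled-probability unary is
   available behind the `convention` switch.  The pairwise term is a
   constant Ising penalty, deliberately blind to image gradients: a true
   synapse contains two strong internal edges (the cleft) that a
   contrast-sensitive term would wrongly snap to.  β is never hard-coded:
   it is selected by grid search maximizing the mean Jaccard index against
   reference segmentations (on phantoms, the generator's truth masks), with
   ties resolved toward the smallest value.  The resulting mask is
   restricted to its connected components that overlap the seeding
   detection component; empty results drop the candidate.
6. **Object features (29).** Mean, unbiased variance, skewness
   (m₃/m₂^1.5) and kurtosis (m₄/m₂², non-excess) of the raw grayscale over
   the object and over its neighborhood — voxels within an anisotropic
   ellipsoidal radius of (30, 30, 1) voxels in (x, y, z), computed by a
   distance transform with per-axis normalization and excluding the object
   itself; 10-bin uniform LBP histograms (P = 8, R = 1, computed per
   z-slice — the descriptor is inherently 2D — and pooled over the region);
   and the ratio of largest to smallest principal standard deviation of the
   voxel coordinates scaled to nanometres, so shape anisotropy is physical
   rather than grid-dependent.
7. **Object classification.** A second Random Forest (100 trees, grown to
   purity) scores each candidate on its 29 features; candidates with score
   ≥ 0.5 are accepted.  Raising the threshold trades recall for precision
   monotonically.  Candidates touching a volume boundary plane are scored
   but flagged, since annotators avoid labeling such objects.
8. **Evaluation.** Accepted candidates are matched one-to-one to
   ground-truth points greedily by increasing anisotropic distance within a
   250 nm tolerance (half the 500 nm synapse-extent prior).  FN and FP
   fractions are both normalized by the ground-truth count.  Morphometrics:
   mean xy cross-section over the 5 slices centered on the z-extent
   midpoint; z continuity as the count of occupied slices (not the span);
   size as Σ over slices of (2D medial-axis pixel count × lateral nm) ×
   slice thickness, in nm² — known to underestimate synapses lying parallel
   to the cutting plane; perforation as the number of slices whose
   cross-section has exactly two 8-connected components (a `≥ 2` variant is
   available).

## Blockwise processing

Synapses are sparse and local, so the pipeline tiles the volume laterally
and processes each block with a 500 nm halo per side; a candidate is owned
by the block whose core contains its centroid, so every object is reported
exactly once.  Blocks span the full z extent: the lateral halo (112 px)
strictly contains the largest filter support (4σ = 40 px at σ = 10), making
core-region features bit-identical to a whole-volume run, whereas a 500 nm
z halo (24 upsampled slices) would not cover that support.  On phantoms
whose objects are smaller than the halo, the blockwise accepted-candidate
centroids equal the whole-volume result exactly (asserted by test).

## Numerical choices

* **Min-cut solver.** `scipy.sparse.csgraph.maximum_flow` on int64
  capacities, probabilities scaled by 2²⁰; the returned labeling is the
  canonical minimal source side of the residual graph, which breaks
  degenerate ties toward background (hence β = 0 reproduces the strict
  threshold).  Quantization is exact for dyadic inputs and bounded by
  ~10⁻⁶ per edge otherwise.
* **Exact domain reduction.** In any optimum a voxel with
  `p < 0.5 − 1.5β` is background (flipping it changes the energy by
  `4p − 2 + β·c` with `c ≥ −6`), so the cut is solved on the bounding box
  of the remaining voxels with a β charge per fixed-background neighbor
  outside the box.  This is an identity, not an approximation, and it makes
  per-candidate cuts cheap at calibrated β.
* **Symmetric 3×3 eigenvalues** use the closed-form trigonometric solution
  (order of magnitude faster than batched LAPACK on volume-sized fields;
  agreement asserted at 10⁻⁸).
* **Truncated derivative kernels** (scipy, 4σ support) leave a ~10⁻⁴
  relative residue on constants; tests of "derivative filters vanish on
  constants" use tolerances of that order.
* **Degenerate regions** (too few voxels, zero variance, empty
  neighborhood, < 3 voxels for the PC ratio) produce zero features with a
  logged warning instead of exceptions, so candidate lists stay aligned.
  The smallest principal standard deviation is floored at 10⁻³ nm.
* **Moment accumulation** uses a streaming central-moment accumulator with
  exact pairwise merging, so blockwise statistics agree with whole-volume
  statistics to ~10⁻⁹ relative.

## Phantom generator

Phantoms emulate the appearance statistics the pipeline keys on, not EM
physics: dark bowed discs (extent 200–800 nm, thickness 50 nm, curvature
sag 15% of the radius) with one-sided vesicle-sized speckle, placed at
random orientations including a 15% fraction lying at a low angle to the
cutting plane (the hard case); distractor membranes (thinner at 35 nm,
slightly lighter, no speckle) and mitochondrion-like striped ellipsoids
share the darkness but not the joint sheet-plus-speckle signature, and are
deliberately contrasty enough to leak through the pixel stage so the object
stage has real negatives to learn from.  Objects are placed largest-first
by rejection sampling against an occupancy grid with a small guard, keeping
truth masks pairwise disjoint; all randomness derives from one seed.

The default evaluation phantom is 30 × 512 × 512 voxels
(≈ 1.35 × 2.3 × 2.3 µm) with 20 synapses, 8 membranes and 6 blobs; training
uses a separate 24 × 448 × 448 phantom with 12 synapses.  These sizes are
the package's chosen study conditions: large enough that 20 synapses of the
stated extent range place without overlap, small enough that the full
train + evaluate + blockwise cycle runs in minutes on one CPU.

What passing on phantoms does and does not show: it validates the
pipeline's mechanics — feature discriminability of sheet + speckle versus
look-alikes, exactness of the segmentation stage, recall/precision
monotonicity, blockwise equivalence — but not performance on real tissue,
which adds registration error, staining variability, section defects
(rips, folds, contrast drift) and far richer distractor morphology.  The
phantom deliberately simulates none of those.

## Known limitations

* Synapses lying parallel to the cutting plane span 1–2 sections and are
  the dominant failure mode, on phantoms as in real data; the skeleton-size
  morphometric underestimates them by construction.
* The object stage needs both true and false candidates from its training
  volume; a training volume whose pixel stage leaks no distractors raises
  an error rather than silently training a one-class model.
* Probabilities are forest vote shares, not calibrated probabilities; the
  0.5 thresholds are operating points, not likelihood statements.
* Blockwise equality holds for objects smaller than the halo; objects
  larger than 500 nm past a block core are not guaranteed identical.
* The size filter bounds are voxel counts and therefore resolution
  dependent; they are config values, not constants.
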