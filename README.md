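# emsynapse

Automated detection of chemical synapses in serial-section transmission
electron microscopy (ssTEM) image stacks.

ssTEM delivers nanometre lateral resolution but coarse sections
(reference grid 4.5 × 4.5 × 45 nm), so a synapse — a dark, slightly curved
postsynaptic density a few tens of nm thick, with a vesicle cloud on the
presynaptic side — appears in only a handful of slices and changes
appearance with its orientation to the cutting plane.  `emsynapse`
implements a fully automated two-stage detector for such anisotropic data
that needs no prior segmentation of the tissue into cells and learns from
sparse annotations only:

1. **Pixel stage (high recall).** The stack is linearly upsampled ×2 along
   z and a 26-channel 3D filter bank (Gaussian smoothings, Hessian
   eigenvalues, Laplacian of Gaussian, difference of Gaussians,
   structure-tensor eigenvalues) feeds a Random Forest trained on sparse
   voxel labels (synapse / membrane / other), yielding a synapse
   probability map `p(x)`.
2. **Candidate segmentation.** The map is thresholded at 0.5, connected
   components outside [100, 10⁶] voxels are discarded, and each remaining
   component is segmented inside a 500 nm-enlarged bounding box by exact
   minimization of the Ising energy

       E(L) = Σ_p D_p(L_p) + β · #{6-neighbor pairs pq : L_p ≠ L_q},
       D_p(bkg) = 2·p_syn,  D_p(syn) = 2·(1 − p_syn),

   via max-flow/min-cut.  The constant pairwise term β (calibrated by
   Jaccard grid search against reference segmentations) gives the cut a
   useful *shrinking bias*: unlike hysteresis thresholding it does not
   attach long spurious protrusions to candidates.
3. **Object stage (precision).** Each candidate is summarized by 29
   features — grayscale moment statistics and uniform-LBP texture
   histograms of the object and of its anisotropic (30, 30, 1)-voxel
   neighborhood, plus a physical principal-component shape ratio — and a
   second Random Forest (100 trees grown to purity) accepts candidates
   scoring ≥ 0.5.

The package also provides synthetic phantom generators (so every stage is
testable without any microscope data), an evaluation module with the
error-analysis morphometrics (mean xy cross-section, z continuity,
per-slice skeleton size, perforation count), and blockwise processing with
500 nm halos for volumes too large to hold in memory.

## Worked example

`examples/03_graphcut_vs_hysteresis.py` segments a synthetic probability
map containing one object with a thin high-probability protrusion:

```
object body: 960 voxels, protrusion: 15 voxels
graph cut   keeps 0 protrusion voxels, Jaccard vs body 1.000
hysteresis  keeps 15 protrusion voxels, Jaccard vs body 0.985
calibrated beta on noisy phantoms: 0.2
```

The graph cut recovers the object exactly and trims the protrusion that
hysteresis keeps — the shrinking bias working as intended — and the Ising
constant comes from calibration, not from a guess.

`examples/04_full_pipeline.py` trains both stages on one small phantom and
evaluates on another (about two minutes on one CPU):

```
pixel-stage OOB error: 0.094
calibrated Ising beta: 0.2
candidates segmented: 7, accepted: 6
ground truth: 4 synapses; missed 0 (0% FN), false detections 2 (50% FP)
```

All four planted synapses are found; the two false detections reflect the
handful of object-level training labels a phantom this small can supply —
the object stage is the component that profits most from more labels.  At
the default phantom scale (20 synapses, ~2.3 µm field; see
`scripts/acceptance.py`) the same pipeline reaches recall 1.0 with ≤ 2
false positives.

The other examples cover the phantom generator (`01`), the filter bank
(`02`) and the morphometrics (`05`).  A thin CLI mirrors the stages for
shell use: `emsynapse phantom | train-pixel | predict | detect | segment |
train-object | classify | run | evaluate`.

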