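"""Generate a phantom ssTEM volume with ground truth and inspect it.

The phantom plants dark, curved synapse-like sheets (with one-sided
vesicle speckle) plus membrane- and mitochondrion-like distractors into a
textured background on an anisotropic 45 x 4.5 x 4.5 nm grid.
"""

import numpy as np

import emsynapse as es

spec = es.PhantomSpec(seed=1)
volume, truth = es.generate_phantom(spec)

sizes = [int(truth.synapse_mask(i).sum()) for i in range(truth.n_synapses)]
print(f"volume shape (z, y, x): {volume.shape}, voxel size {volume.voxel_size} nm")
print(f"planted synapses: {truth.n_synapses}")
print(f"synapse sizes (voxels): min {min(sizes)}, median {int(np.median(sizes))}, max {max(sizes)}")
print(f"distractor voxels: membranes {int(truth.membrane_mask.sum())}, "
      f"blobs {int(truth.blob_mask.sum())}, vesicles {int(truth.vesicle_mask.sum())}")
print(f"intensity: mean {volume.data.mean():.1f}, sd {volume.data.std():.1f} (8-bit-like scale)")

# Every planted synapse lies inside the detection size filter [100, 1e6],
# so a perfect pixel classifier would let all of them reach the graph-cut
# stage; the distractors share the darkness but not the sheet+speckle
# signature the classifiers key on.
assert all(100 <= s <= 1_000_000 for s in sizes)
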