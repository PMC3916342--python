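"""Error-analysis morphometrics of a segmented synapse mask.

What makes a synapse hard to detect in anisotropic stacks: a small xy
cross-section, few occupied slices (low z continuity), small physical
size.  Perforated synapses — those whose cross-section splits into two
components in some slices — are the easy ones.
"""

import numpy as np

import emsynapse as es

spec = es.PhantomSpec(shape=(16, 160, 160), n_synapses=1, n_membranes=0, n_blobs=0,
                      synapse_extent_nm=(300.0, 380.0), seed=21)
volume, truth = es.generate_phantom(spec)
mask = truth.synapse_mask(0)

area = es.mean_xy_area(mask)
zr = es.z_range(mask)
size = es.skeleton_size(mask, volume.voxel_size)
perf = es.perforation_count(mask)

print(f"synapse mask: {int(mask.sum())} voxels")
print(f"mean xy cross-section over the 5 central slices: {area:.1f} px")
print(f"z continuity: visible in {zr} slices")
print(f"skeleton-based size: {size:.0f} nm^2 "
      f"(per-slice medial-axis length x slice thickness)")
print(f"perforated (two components) in {perf} slices")
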