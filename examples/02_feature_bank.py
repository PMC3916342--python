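"""Compute the 26-channel 3D filter bank on an upsampled phantom crop.

Features are computed on the z-upsampled grid (factor 2) so the nonlinear
filters see interpolated axial context — the key trick that makes 3D
pixel classification work on 10:1 anisotropic data.
"""

import emsynapse as es

spec = es.PhantomSpec(shape=(16, 160, 160), n_synapses=1, n_membranes=0, n_blobs=0,
                      synapse_extent_nm=(250.0, 330.0), seed=4)
volume, truth = es.generate_phantom(spec)

upsampled = es.upsample_z(volume, 2)
print(f"native grid {volume.shape} at {volume.voxel_size} nm")
print(f"upsampled grid {upsampled.shape} at {upsampled.voxel_size} nm")

stack = es.compute_feature_stack(upsampled)
print(f"feature channels: {stack.n_channels}")
for name in stack.channel_names:
    print(f"  {name}")

# A synaptic density is a dark plate: at its scale the largest Hessian
# eigenvalue responds strongly (bright ridge across the sheet) while the
# other two stay near zero.
cz, cy, cx = truth.centroids[0].astype(int)
idx = stack.channel_names.index("hessian_eig@3.5:0")
print(f"\nlargest Hessian eigenvalue @ sigma 3.5 at the synapse center: "
      f"{stack.data[idx, cz * 2, cy, cx]:.2f}")
print(f"same channel in background: {stack.data[idx, 1, 5, 5]:.2f}")
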