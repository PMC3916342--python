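"""Train and run the full two-stage detector on small phantoms (~2 min).

Pipeline: sparse pixel labels -> Random-Forest probability map ->
threshold/components/size filter -> per-box graph cut -> 29 object
features -> object-level Random Forest -> accepted synapses, evaluated
against the phantom's ground-truth points.
"""

import emsynapse as es
from emsynapse.pipeline import PipelineConfig, run_pipeline, train_pipeline

cfg = PipelineConfig(seed=3)

train_spec = es.PhantomSpec(
    shape=(18, 256, 256), n_synapses=5, synapse_extent_nm=(200.0, 420.0),
    n_membranes=4, membrane_extent_nm=(250.0, 400.0),
    n_blobs=2, blob_axis_nm=(150.0, 250.0), seed=7,
)
train_vol, train_truth = es.generate_phantom(train_spec)
detector = train_pipeline(train_vol, train_truth, cfg)
print(f"pixel-stage OOB error: {detector.pixel_classifier.oob_error:.3f}")
print(f"calibrated Ising beta: {detector.beta}")

test_spec = es.PhantomSpec(
    shape=(18, 256, 256), n_synapses=4, synapse_extent_nm=(200.0, 420.0),
    n_membranes=3, membrane_extent_nm=(250.0, 400.0),
    n_blobs=2, blob_axis_nm=(150.0, 250.0), seed=11,
)
vol, truth = es.generate_phantom(test_spec)
result = run_pipeline(vol, detector, cfg)
print(f"candidates segmented: {len(result.candidates)}, accepted: {len(result.accepted)}")

masks = {c.candidate_id: c.mask for c in result.accepted}
origins = {c.candidate_id: c.origin for c in result.accepted}
report = es.match_detections(
    masks, es.phantom_gt_points(truth), vol.voxel_size, 250.0, origins
)
fn, fp = es.error_rates(report)
print(f"ground truth: {report.n_gt} synapses; missed {report.n_fn} "
      f"({fn:.0%} FN), false detections {report.n_fp} ({fp:.0%} FP)")
# FN counts synapses with no accepted candidate within 250 nm; FP counts
# accepted candidates that match no ground-truth point, normalized by the
# ground-truth count.
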