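"""Full supervised workflow on synthetic biopsy phantoms.

Trains the block classifier on annotated phantoms, then refines a rough
user-style contour around a glomerulus-like region three ways: with the
texture-classification force field (supervised), with the gradient
field only (unsupervised), and by the raw block-classification mask.
Prints the overlap of each result with the ground truth plus the label
and area the supervised pipeline assigns.
"""

from textsnake import measure, pipeline, synthetic
from textsnake.snake import contour_to_mask

config = pipeline.PipelineConfig.for_phantoms()

print("training block classifier on 6 annotated phantoms ...")
training = [
    synthetic.generate_phantom(synthetic.biopsy_phantom_spec(100 + k)) for k in range(6)
]
model = pipeline.train_model(training, config)
print("classes:", ", ".join(model.class_names))

image, records = synthetic.generate_phantom(synthetic.biopsy_phantom_spec(990))
truth = contour_to_mask(records[0].polygon_array(), image.shape)
initial = synthetic.rough_contour(truth, seed=7)

sup = pipeline.segment_supervised(image, initial, model, config)
unsup = pipeline.segment_unsupervised(image, initial, config)
blk = pipeline.block_segmentation_mask(image, model, config, records[0].label)

j = measure.jaccard
print(f"\ntarget region: {records[0].label}")
print(f"overlap vs truth — initial:      {j(contour_to_mask(initial, image.shape), truth):.3f}")
print(f"overlap vs truth — block-based:  {j(blk, truth):.3f}")
print(f"overlap vs truth — unsupervised: {j(unsup.mask, truth):.3f}")
print(f"overlap vs truth — supervised:   {j(sup.mask, truth):.3f}")
print(f"assigned label: {sup.label}   area: {sup.area_px} px")
print("\nThe supervised field (gradient + classifier edges + annotation")
print("anchoring) outlines the region more accurately than gradients alone;")
print("the bare block map shows the coarse boundary the snake refines.")
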