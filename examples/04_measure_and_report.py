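"""Calibrated area measurement and classifier evaluation.

Measures a segmented phantom region in physical units and summarizes a
block-classification experiment with a confusion matrix.
"""

import numpy as np

from textsnake import measure, pipeline, synthetic
from textsnake.io import Calibration
from textsnake.snake import contour_to_mask

# --- areas -----------------------------------------------------------
image, records = synthetic.generate_phantom(synthetic.biopsy_phantom_spec(42))
truth = contour_to_mask(records[0].polygon_array(), image.shape)

cal = Calibration(0.5)  # 0.5 um per pixel
px, um2 = measure.area(truth, cal)
print(f"{records[0].label}: {px} px = {um2:.0f} um^2 "
      f"(equivalent diameter {2 * np.sqrt(um2 / np.pi):.0f} um)")

other = contour_to_mask(records[1].polygon_array(), image.shape)
diff, ratio = measure.compare_areas(truth, other, cal)
print(f"vs second region: difference {diff:+.0f} um^2, ratio {ratio:.2f}")

# --- confusion matrix ------------------------------------------------
cm = measure.ConfusionMatrix.from_labels(
    predicted=["glom", "glom", "tub", "bg", "glom", "tub"],
    true=["glom", "tub", "tub", "bg", "glom", "tub"],
)
m = measure.confusion_metrics(cm)
print("\ntoy confusion matrix accuracy:", round(m["accuracy"], 1), "%")
for name in cm.class_names:
    print(f"  {name:5s} precision {m['precision'][name]:6.1f}%  recall {m['recall'][name]:6.1f}%")
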