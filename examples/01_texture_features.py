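"""Extract the 7 texture features from image blocks.

Builds two small textured patches — one smooth, one with an oriented
grating — and prints their feature vectors.  The first-order features
(mean, std) react to brightness and noise; the co-occurrence features
(contrast, IDM, correlation, entropy, ASM) react to spatial structure
that the mean and std cannot see.
"""

import numpy as np

from textsnake import texture

rng = np.random.default_rng(0)

smooth = np.clip(160 + rng.normal(0, 10, size=(37, 37)), 0, 255).astype(np.uint8)

rr, cc = np.mgrid[0:37, 0:37]
grating = np.clip(
    160 + 25 * np.sin(2 * np.pi * cc / 6) + rng.normal(0, 10, size=(37, 37)), 0, 255
).astype(np.uint8)

for name, block in [("smooth", smooth), ("grating", grating)]:
    fv = texture.extract_features(block)
    print(f"{name:8s} mean={fv.mean:6.1f} std={fv.std:5.1f} contrast={fv.contrast:6.2f} "
          f"idm={fv.idm:.3f} corr={fv.correlation:+.3f} entropy={fv.entropy:.3f} asm={fv.asm:.4f}")

print("\nBoth patches share the same mean; the grating raises the std and,")
print("more distinctively, GLCM contrast/entropy/correlation while lowering")
print("IDM/ASM — the signal the block classifier uses to tell tissue")
print("classes apart.")
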