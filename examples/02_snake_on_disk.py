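"""Refine a rough circle onto a disk with the greedy snake.

Builds a bright disk on a dark background, composes the classic
gradient force field, and evolves a deliberately-too-small overlap
(~0.7) initial circle.  Prints the overlap before and after.
"""

import numpy as np

from textsnake import forcefield as ff
from textsnake import measure
from textsnake.snake import Contour, SnakeParams, contour_to_mask, evolve

rr, cc = np.mgrid[0:100, 0:100]
disk = (rr - 50) ** 2 + (cc - 50) ** 2 <= 400  # radius 20
img = np.where(disk, 200, 30).astype(np.uint8)

field = ff.compose_external_energy([ff.edge_term_f1(img, sigma=3.0)], [1.0])

th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
init = Contour(np.column_stack([50 + 24 * np.cos(th), 50 + 24 * np.sin(th)]))

params = SnakeParams(alpha=1.44, beta=1.58, search_radius=8)
final = evolve(init, field, params)

omega_init = measure.jaccard(contour_to_mask(init, img.shape), disk)
omega_final = measure.jaccard(contour_to_mask(final, img.shape), disk)
print(f"overlap with the true disk: initial {omega_init:.3f} -> final {omega_final:.3f}")
print("The snake walks each vertex downhill in the composed energy until")
print("the contour locks onto the gradient ridge at the disk boundary.")
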