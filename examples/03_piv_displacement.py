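"""Measure a known displacement field from a rendered bead-image pair.

Renders beads before/after a uniform subpixel shift and runs the PIV
stage (windowed normalized cross-correlation, 3-point Gaussian subpixel
fit, normalized-median validation).
"""

import numpy as np

from tfmkit import (
    VectorField2D,
    estimate_displacement,
    random_bead_field,
    render_bead_images,
    validate_and_fill,
)

PIXEL = 0.2  # um/px
TRUE_SHIFT_PX = 0.30

beads = random_bead_field((256, 256), PIXEL, seed=3)
shift = VectorField2D(
    np.full((33, 33), TRUE_SHIFT_PX * PIXEL), np.zeros((33, 33)), spacing=8 * PIXEL
)
reference, deformed = render_bead_images(beads, shift, (256, 256), PIXEL)

field = estimate_displacement(reference, deformed)
field = validate_and_fill(field)

err_x = field.u_x / PIXEL - TRUE_SHIFT_PX
err_y = field.u_y / PIXEL
rms = np.sqrt(np.mean(err_x**2 + err_y**2))
print(f"grid: {field.shape[0]} x {field.shape[1]} nodes, "
      f"spacing {field.spacing:.2f} um")
print(f"true shift: {TRUE_SHIFT_PX} px; "
      f"mean recovered: {field.u_x.mean() / PIXEL:.4f} px")
print(f"RMS error: {rms:.4f} px")
print()
print("Subpixel RMS error a small fraction of a pixel means bead-scale gel")
print("deformations (a few hundred nm) are measurable at this magnification.")
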