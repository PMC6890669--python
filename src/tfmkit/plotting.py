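"""Rendering of stress- and deformation-magnitude maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fields import VectorField2D

__all__ = ["save_magnitude_map"]


def save_magnitude_map(
    field: VectorField2D,
    path: str | Path,
    title: str = "traction stress",
    unit: str = "Pa",
    cmap: str = "inferno",
    scale_bar_um: float = 20.0,
) -> None:
    """Save a color-coded vector-magnitude map with a physical scale bar."""
    mag = field.magnitude()
    ny, nx = mag.shape
    extent = (0.0, nx * field.spacing, ny * field.spacing, 0.0)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(mag, cmap=cmap, extent=extent, origin="upper")
    fig.colorbar(im, ax=ax, label=f"|{title}| ({unit})")
    # scale bar, bottom-left
    x0 = 0.05 * nx * field.spacing
    y0 = 0.93 * ny * field.spacing
    ax.plot([x0, x0 + scale_bar_um], [y0, y0], color="white", lw=3)
    ax.text(
        x0 + scale_bar_um / 2,
        y0 - 0.03 * ny * field.spacing,
        f"{scale_bar_um:g} μm",
        color="white",
        ha="center",
        fontsize=9,
    )
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
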