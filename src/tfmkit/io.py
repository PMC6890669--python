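"""Readers and writers: TIFF movies, field tables, configs.

Movies are multi-page TIFFs with a JSON payload in the ImageDescription
tag carrying pixel size (um/px), per-frame timestamps (min) and which
page is the stress-free reference frame.  Vector fields travel as CSV
(one node per row, unit-annotated header) for interoperability and as
NumPy ``.npz`` archives (keys u_x, u_y, spacing, origin, valid_mask)
when exact binary round trips matter.  Configs are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fields import ImageFrame, ImageSequence, VectorField2D
from .piv import PIVSettings, ReferencePolicy, SubpixelMethod
from .substrate import ElasticSubstrate
from .traction import InversionMethod, InversionSettings, LambdaPolicy, PadMode, Taper

__all__ = [
    "write_movie",
    "read_movie",
    "write_field_csv",
    "read_field_csv",
    "write_field_npz",
    "read_field_npz",
    "PipelineConfig",
    "load_config",
    "save_config",
]


# --------------------------------------------------------------------------
# movies

def write_movie(
    seq: ImageSequence, path: str | Path, reference_index: int | None = None
) -> None:
    """Write a sequence as a multi-page TIFF with JSON metadata."""
    meta = {
        "pixel_size_um": seq.pixel_size,
        "timestamps_min": [float(t) for t in seq.timestamps],
        "reference_index": reference_index,
    }
    stack = np.stack([f.pixels for f in seq.frames]).astype(np.float32)
    tifffile.imwrite(
        str(path), stack, photometric="minisblack", description=json.dumps(meta)
    )


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    cadence: float | None = None,
) -> tuple[ImageSequence, int | None]:
    """Read a multi-page TIFF movie.

    Pixel size comes from the embedded metadata or, failing that, the
    ``pixel_size`` argument; timestamps from metadata or a uniform
    ``cadence`` (min/frame, default 0 spacing).  Returns the sequence
    and the metadata's reference-frame index (None if absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise IOError(f"expected a (frames, y, x) TIFF stack, got shape {stack.shape}")
    meta: dict[str, Any] = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    ps = meta.get("pixel_size_um", pixel_size)
    if ps is None:
        raise ValueError(
            "pixel size not found in TIFF metadata; pass pixel_size=<um/px> explicitly"
        )
    ts = meta.get("timestamps_min")
    if ts is None:
        dt = cadence if cadence is not None else 0.0
        ts = [i * dt for i in range(stack.shape[0])]
    frames = [
        ImageFrame(np.clip(img.astype(float), 0, None), float(ps), timestamp=float(t))
        for img, t in zip(stack, ts)
    ]
    return ImageSequence(frames), meta.get("reference_index")


# --------------------------------------------------------------------------
# vector fields

def write_field_csv(field: VectorField2D, path: str | Path, unit: str = "um") -> None:
    """One node per row: x_um, y_um, components (named by ``unit``), valid."""
    xg, yg = field.node_positions()
    df = pd.DataFrame(
        {
            "x_um": xg.ravel(),
            "y_um": yg.ravel(),
            f"u_x_{unit}": field.u_x.ravel(),
            f"u_y_{unit}": field.u_y.ravel(),
            "valid": field.valid_mask.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_field_csv(path: str | Path) -> VectorField2D:
    df = pd.read_csv(path)
    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    nx, ny = xs.size, ys.size
    if nx * ny != len(df):
        raise IOError("field CSV does not describe a complete regular grid")
    dxs = np.diff(xs)
    if nx > 1 and not np.allclose(dxs, dxs[0]):
        raise IOError("field CSV grid is not uniformly spaced")
    spacing = float(dxs[0]) if nx > 1 else (float(np.diff(ys)[0]) if ny > 1 else 1.0)
    ucols = [c for c in df.columns if c.startswith("u_x")]
    vcols = [c for c in df.columns if c.startswith("u_y")]
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    return VectorField2D(
        u_x=df[ucols[0]].to_numpy()[order].reshape(ny, nx),
        u_y=df[vcols[0]].to_numpy()[order].reshape(ny, nx),
        spacing=spacing,
        origin=(float(xs[0]), float(ys[0])),
        valid_mask=df["valid"].to_numpy()[order].reshape(ny, nx).astype(bool),
    )


def write_field_npz(field: VectorField2D, path: str | Path) -> None:
    np.savez(
        path,
        u_x=field.u_x,
        u_y=field.u_y,
        spacing=field.spacing,
        origin=np.asarray(field.origin),
        valid_mask=field.valid_mask,
    )


def read_field_npz(path: str | Path) -> VectorField2D:
    with np.load(path) as z:
        return VectorField2D(
            u_x=z["u_x"],
            u_y=z["u_y"],
            spacing=float(z["spacing"]),
            origin=tuple(z["origin"]),
            valid_mask=z["valid_mask"],
        )


# --------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serializable).

    ``output_units`` selects between SI-ish internal units (pN/um, Pa)
    and display units (nN/um, nN/um^2) in the metrics CSV.
    """

    movie: str = ""
    out_dir: str = "tfm_out"
    young_modulus: float = 3000.0
    poisson_ratio: float = 0.45
    pixel_size: float | None = None
    cadence: float | None = None
    reference_policy: str = "last_frame"
    reference_index: int | None = None
    drift_correction: bool = False
    piv: PIVSettings = dataclasses.field(default_factory=PIVSettings)
    inversion: InversionSettings = dataclasses.field(default_factory=InversionSettings)
    seed: int = 0
    output_units: str = "paper"  # "paper" (nN-based) or "si" (pN/um, Pa)

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.output_units not in ("paper", "si"):
            raise ValueError("output_units must be 'paper' or 'si'")
        ReferencePolicy(self.reference_policy)

    @property
    def substrate(self) -> ElasticSubstrate:
        return ElasticSubstrate(self.young_modulus, self.poisson_ratio)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["piv"]["subpixel_method"] = self.piv.subpixel_method.value
        d["inversion"]["lambda_policy"] = self.inversion.lambda_policy.value
        d["inversion"]["taper"] = self.inversion.taper.value
        d["inversion"]["pad_mode"] = self.inversion.pad_mode.value
        d["inversion"]["method"] = self.inversion.method.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        piv_d = dict(d.pop("piv", {}))
        if "subpixel_method" in piv_d:
            piv_d["subpixel_method"] = SubpixelMethod(piv_d["subpixel_method"])
        inv_d = dict(d.pop("inversion", {}))
        if "lambda_policy" in inv_d:
            inv_d["lambda_policy"] = LambdaPolicy(inv_d["lambda_policy"])
        if "taper" in inv_d:
            inv_d["taper"] = Taper(inv_d["taper"])
        if "pad_mode" in inv_d:
            inv_d["pad_mode"] = PadMode(inv_d["pad_mode"])
        if "method" in inv_d:
            inv_d["method"] = InversionMethod(inv_d["method"])
        return cls(piv=PIVSettings(**piv_d), inversion=InversionSettings(**inv_d), **d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
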