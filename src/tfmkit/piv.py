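"""Displacement estimation by windowed normalized cross-correlation.

The deformed bead image is compared with a stress-free reference frame
(recorded after detaching the cells) window by window: each
interrogation window of the reference is matched against a search
region of the deformed frame by zero-normalized cross-correlation, the
integer peak is refined to subpixel precision with a three-point
Gaussian fit, and the resulting vector grid is screened with the
normalized median test before gaps are filled.

Defaults follow common monolayer TFM practice: 32 px windows on an
8 px step (75% overlap) — a dense output grid — with correlation
computed on mean-subtracted, unit-normalized windows so that
illumination differences between frames do not bias the match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation
from scipy import ndimage

from .fields import ImageFrame, ImageSequence, VectorField2D

__all__ = [
    "PIVSettings",
    "SubpixelMethod",
    "ReferencePolicy",
    "estimate_displacement",
    "validate_and_fill",
    "reference_from_sequence",
    "register_sequence",
]

logger = logging.getLogger(__name__)


class SubpixelMethod(str, Enum):
    GAUSSIAN3PT = "gaussian3pt"
    PARABOLIC = "parabolic"


class ReferencePolicy(str, Enum):
    LAST_FRAME = "last_frame"
    EXPLICIT_INDEX = "explicit_index"


@dataclass(frozen=True)
class PIVSettings:
    """Interrogation and validation settings.

    window_size, step and search_margin are in pixels.  The output grid
    has ``floor((image_size - window_size) / step) + 1`` nodes per axis
    and spacing ``step * pixel_size``; only windows fully inside the
    frame are used.  ``median_test_threshold`` is the normalized-median
    residual above which a vector is invalidated (2-3 is the standard
    operating range); ``median_test_eps_px`` the noise floor of that
    test, in px.  ``min_snr`` is the smallest acceptable ratio of the
    primary correlation peak to the secondary peak.
    """

    window_size: int = 32
    step: int = 8
    subpixel_method: SubpixelMethod = SubpixelMethod.GAUSSIAN3PT
    search_margin: int = 12  # must exceed the largest expected displacement (px)
    median_test_threshold: float = 2.5
    median_test_eps_px: float = 0.1
    min_snr: float = 1.15
    min_peak_correlation: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 8:
            raise ValueError("window_size must be >= 8 px")
        if not (1 <= self.step <= self.window_size):
            raise ValueError("step must satisfy 1 <= step <= window_size")
        if self.search_margin < 1:
            raise ValueError("search_margin must be >= 1 px")


def _subpixel_offset_1d(cm: float, c0: float, cp: float, method: SubpixelMethod) -> float:
    """Peak offset in (-0.5, 0.5) from three correlation samples."""
    if method is SubpixelMethod.GAUSSIAN3PT and min(cm, c0, cp) > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))
    # parabolic fallback (also used when a correlation sample is <= 0)
    denom = cm - 2.0 * c0 + cp
    if denom < 0:
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    return 0.0


def estimate_displacement(
    reference: ImageFrame,
    deformed: ImageFrame,
    settings: PIVSettings = PIVSettings(),
) -> VectorField2D:
    """Per-window displacement of ``deformed`` relative to ``reference``.

    Returns a vector field in micrometres on the interrogation grid.
    Windows without texture (constant intensity) and windows whose
    correlation peak fails the signal-to-noise screen are flagged
    invalid in ``valid_mask`` — they raise no exception; downstream
    gap filling is explicit (:func:`validate_and_fill`).
    """
    if reference.shape != deformed.shape:
        raise ValueError(
            f"frame shape mismatch: {reference.shape} vs {deformed.shape}"
        )
    if not np.isclose(reference.pixel_size, deformed.pixel_size):
        raise ValueError("frames must share one pixel size")
    w = settings.window_size
    step = settings.step
    m = settings.search_margin
    ny_px, nx_px = reference.shape
    n_rows = (ny_px - w) // step + 1
    n_cols = (nx_px - w) // step + 1
    if n_rows < 1 or n_cols < 1:
        raise ValueError("image smaller than one interrogation window")

    ref = reference.pixels
    mov = deformed.pixels
    u_x = np.zeros((n_rows, n_cols))
    u_y = np.zeros((n_rows, n_cols))
    valid = np.ones((n_rows, n_cols), dtype=bool)

    for i in range(n_rows):
        r0 = i * step
        for j in range(n_cols):
            c0 = j * step
            win = ref[r0 : r0 + w, c0 : c0 + w]
            if win.std() == 0:
                valid[i, j] = False
                continue
            # search region, clipped at the frame border; a vector whose
            # correlation peak lands on the (possibly clipped) border of
            # the search surface is flagged invalid further down
            pr0, pr1 = max(r0 - m, 0), min(r0 + w + m, ny_px)
            pc0, pc1 = max(c0 - m, 0), min(c0 + w + m, nx_px)
            patch = mov[pr0:pr1, pc0:pc1]
            if patch.std() == 0:
                valid[i, j] = False
                continue
            ncc = match_template(patch, win)
            pk = np.unravel_index(np.argmax(ncc), ncc.shape)
            peak_val = ncc[pk]
            if peak_val < settings.min_peak_correlation:
                valid[i, j] = False
                continue
            if (
                pk[0] == 0
                or pk[1] == 0
                or pk[0] == ncc.shape[0] - 1
                or pk[1] == ncc.shape[1] - 1
            ):
                # peak on the search border: the true displacement likely
                # exceeds search_margin — unreliable, flag it
                valid[i, j] = False
                continue
            # secondary peak outside a 3x3 exclusion zone around the primary
            masked = ncc.copy()
            masked[
                max(pk[0] - 1, 0) : pk[0] + 2, max(pk[1] - 1, 0) : pk[1] + 2
            ] = -np.inf
            second = masked.max()
            if np.isfinite(second) and second > 0 and peak_val / second < settings.min_snr:
                valid[i, j] = False
                continue
            dy = float(pk[0] + pr0 - r0)
            dx = float(pk[1] + pc0 - c0)
            if peak_val >= 1.0 - 1e-9:
                # exact registration (ZNCC cannot exceed 1): the match is
                # the integer lag itself; a 3-point fit would only add a
                # spurious apex offset
                u_x[i, j] = dx
                u_y[i, j] = dy
                continue
            if 0 < pk[0] < ncc.shape[0] - 1:
                dy += _subpixel_offset_1d(
                    ncc[pk[0] - 1, pk[1]], peak_val, ncc[pk[0] + 1, pk[1]],
                    settings.subpixel_method,
                )
            if 0 < pk[1] < ncc.shape[1] - 1:
                dx += _subpixel_offset_1d(
                    ncc[pk[0], pk[1] - 1], peak_val, ncc[pk[0], pk[1] + 1],
                    settings.subpixel_method,
                )
            u_x[i, j] = dx
            u_y[i, j] = dy

    ps = reference.pixel_size
    # node position = window center; pixel centers are the length datum
    origin = ((w - 1) / 2.0 * ps, (w - 1) / 2.0 * ps)
    return VectorField2D(
        u_x=u_x * ps,
        u_y=u_y * ps,
        spacing=step * ps,
        origin=origin,
        valid_mask=valid,
    )


def _neighbor_stack(arr: np.ndarray, radius: int = 1) -> np.ndarray:
    """(k, ny, nx) stack of neighbor values within ``radius`` (excluding
    the center), NaN where out of grid."""
    r = radius
    padded = np.full((arr.shape[0] + 2 * r, arr.shape[1] + 2 * r), np.nan)
    padded[r:-r, r:-r] = arr
    stacks = []
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj == 0:
                continue
            stacks.append(padded[r + di : padded.shape[0] - r + di,
                                 r + dj : padded.shape[1] - r + dj])
    return np.stack(stacks)


def validate_and_fill(
    field_in: VectorField2D,
    settings: PIVSettings = PIVSettings(),
) -> VectorField2D:
    """Outlier screening (normalized median test) plus gap filling.

    A vector is an outlier when its residual against the median of its
    valid neighbors (5x5 neighborhood), normalized by the median
    neighbor residual plus a noise floor, exceeds
    ``median_test_threshold`` in either component.  Outliers and
    previously invalid nodes are replaced by the component median of
    their valid 8-neighbors (iterated until the grid is complete); the
    replacement count is logged.  More than 50% invalid nodes is a
    hard failure.
    """
    if field_in.shape[0] < 3 or field_in.shape[1] < 3:
        raise ValueError("validation requires at least a 3x3 grid")
    # the noise floor is specified in px of the source image; the field
    # spacing is step * pixel_size, so pixel_size = spacing / step
    eps = settings.median_test_eps_px * (field_in.spacing / settings.step)

    ux = field_in.u_x.copy()
    uy = field_in.u_y.copy()
    valid = field_in.valid_mask.copy()

    ux_masked = np.where(valid, ux, np.nan)
    uy_masked = np.where(valid, uy, np.nan)
    outlier = np.zeros_like(valid)
    # 5x5 neighborhoods for the screen: one-sided 3x3 neighborhoods at
    # grid corners produce spurious flags on strong gradients, and pairs
    # of adjacent bad vectors can shield each other in a 3x3 median
    for comp in (ux_masked, uy_masked):
        nb = _neighbor_stack(comp, radius=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
            med = np.nanmedian(nb, axis=0)
            resid_nb = np.nanmedian(np.abs(nb - med), axis=0)
        with np.errstate(invalid="ignore"):
            r = np.abs(comp - med) / (resid_nb + eps)
        outlier |= np.nan_to_num(r, nan=0.0) > settings.median_test_threshold
    outlier &= valid
    valid &= ~outlier

    n_invalid = int((~valid).sum())
    if n_invalid > 0.5 * valid.size:
        raise RuntimeError(
            f"{n_invalid}/{valid.size} nodes invalid — displacement field unusable"
        )

    filled = valid.copy()
    ux_f = np.where(filled, ux, np.nan)
    uy_f = np.where(filled, uy, np.nan)
    n_replaced = n_invalid
    while not filled.all():
        nb_x = _neighbor_stack(ux_f)
        nb_y = _neighbor_stack(uy_f)
        have_nb = (~np.isnan(nb_x)).sum(axis=0) > 0
        fixable = ~filled & have_nb
        if not fixable.any():
            # isolated pocket with no valid neighbors: fall back to grid median
            ux_f[~filled] = np.nanmedian(ux_f)
            uy_f[~filled] = np.nanmedian(uy_f)
            filled[:] = True
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            ux_f[fixable] = np.nanmedian(nb_x, axis=0)[fixable]
            uy_f[fixable] = np.nanmedian(nb_y, axis=0)[fixable]
        filled |= fixable
    if n_replaced:
        logger.info(
            "validate_and_fill: %d/%d vectors replaced (outliers + gaps)",
            n_replaced,
            valid.size,
        )
    return replace(
        field_in,
        u_x=ux_f,
        u_y=uy_f,
        valid_mask=np.ones_like(valid),
    )


def reference_from_sequence(
    seq: ImageSequence,
    policy: ReferencePolicy | str = ReferencePolicy.LAST_FRAME,
    index: int | None = None,
) -> ImageFrame:
    """Select the stress-free reference frame of a recording.

    ``last_frame`` mirrors the detachment protocol: the cells are
    released (10% SDS) at the end of the movie, so the final frame shows
    the relaxed gel.  ``explicit_index`` selects ``index``.
    """
    policy = ReferencePolicy(policy)
    if policy is ReferencePolicy.LAST_FRAME:
        return seq[len(seq) - 1]
    if index is None or not (0 <= index < len(seq)):
        raise ValueError(f"reference index {index} out of range for {len(seq)} frames")
    return seq[index]


def register_sequence(
    seq: ImageSequence,
    reference: ImageFrame,
    upsample_factor: int = 20,
) -> tuple[ImageSequence, np.ndarray]:
    """Rigid drift correction of every frame against the reference.

    Whole-frame phase correlation estimates each frame's (dy, dx) shift
    relative to the reference; frames are resampled (cubic spline) to
    undo it.  Returns the corrected sequence and the (n_frames, 2)
    array of detected shifts in px; shifts are also logged.
    """
    corrected = []
    shifts = []
    for frame in seq:
        shift, _, _ = phase_cross_correlation(
            reference.pixels, frame.pixels, upsample_factor=upsample_factor
        )
        shifts.append(shift)
        if np.allclose(shift, 0):
            corrected.append(frame)
        else:
            moved = ndimage.shift(frame.pixels, shift, order=3, mode="nearest")
            corrected.append(
                ImageFrame(np.clip(moved, 0, None), frame.pixel_size, frame.timestamp)
            )
    shifts_arr = np.array(shifts)
    logger.info(
        "register_sequence: max |drift| = %.2f px over %d frames",
        np.abs(shifts_arr).max() if len(shifts_arr) else 0.0,
        len(seq),
    )
    return ImageSequence(corrected), shifts_arr
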