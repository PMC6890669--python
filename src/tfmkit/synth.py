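"""Forward simulation: traction patterns, elastic displacements, bead images.

The study conditions this module emulates: a flat polyacrylamide gel
(E of 3, 35 or 70 kPa) whose surface carries the smooth, spatially
heterogeneous traction field of a confluent endothelial monolayer;
sub-resolution (0.1 um) fluorescent beads embedded near the surface,
imaged through a diffraction-limited objective (Gaussian point-spread
function) with shot and read noise; frames every 10 minutes over hours,
with a stress-free reference frame recorded after the cells are
detached at the end of the movie.

Because the FFT-based elastic solver is periodic while real fields of
view are not, scenes are simulated on a domain twice the analysis field
of view and cropped centrally, which keeps wrap-around artifacts out of
the analyzed region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import ImageFrame, ImageSequence, VectorField2D
from .greens import apply_forward
from .substrate import ElasticSubstrate

__all__ = [
    "TractionPattern",
    "BeadField",
    "NoiseModel",
    "SimulatedMovie",
    "generate_traction_pattern",
    "ar1_traction_schedule",
    "forward_displacement",
    "random_bead_field",
    "render_bead_images",
    "simulate_movie",
    "default_scene_movie",
]

logger = logging.getLogger(__name__)

# Default synthetic scene: 512x512 px field of view at 0.2 um/px with a
# 40x-objective-like PSF; peak monolayer stress 200 Pa so that soft-gel
# (3 kPa) deformations reach the micrometre scale.
DEFAULT_FOV_PX = 512
DEFAULT_PIXEL_SIZE = 0.2  # um/px
DEFAULT_BEAD_DENSITY = 0.02  # beads per px^2
DEFAULT_PSF_SIGMA_PX = 1.0
DEFAULT_PEAK_STRESS = 200.0  # Pa
DEFAULT_CORRELATION_LENGTH = 8.0  # um
DEFAULT_NODE_SPACING_PX = 8  # traction/displacement grid spacing, px


@dataclass
class TractionPattern:
    """A prescribed monolayer traction field with provenance.

    ``ground_truth_strain_energy`` (pN um) is filled in by
    :func:`simulate_movie` once the paired displacement field is known.
    """

    field: VectorField2D  # components in Pa
    seed: int | None = None
    ground_truth_strain_energy: float | None = None


@dataclass
class BeadField:
    """Sub-resolution fluorescent fiducial markers.

    positions : (N, 2) array of (x, y) in um; amplitudes : peak
    intensity of each bead's Gaussian image (a.u.); psf_sigma : Gaussian
    point-spread-function width in um.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    psf_sigma: float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        if self.amplitudes.shape != (self.positions.shape[0],):
            raise ValueError("amplitudes must be length N")
        if self.positions.shape[0] == 0:
            raise ValueError("bead field must contain at least one bead")
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: additive Gaussian read noise (a.u.) plus Poisson
    shot noise (``poisson_scale`` photoelectrons per intensity unit;
    0 disables shot noise)."""

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0


def _divergence_of_random_stress(
    rng: np.random.Generator, shape: tuple[int, int], sigma_nodes: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled smooth traction field tau_i = d_j sigma_ij from a random
    smooth symmetric stress tensor.

    A confluent monolayer transmits force through an intercellular
    stress tensor; its substrate traction is that tensor's divergence.
    Building tractions this way enforces *local* force balance: any
    region much larger than the correlation length exerts (almost) no
    net force, so the field's spectral power vanishes at k -> 0 instead
    of peaking there, as it would for plainly low-pass-filtered noise.
    The spatial mean is exactly zero (periodic derivative).
    """
    # differentiating tightens the correlation scale by about sqrt(2);
    # filter the stress components wider so that sigma_nodes describes
    # the *traction* field's correlation length
    stress = [
        ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=np.sqrt(2.0) * sigma_nodes, mode="wrap"
        )
        for _ in range(3)  # sigma_xx, sigma_xy, sigma_yy
    ]
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny)
    KX, KY = np.meshgrid(kx, ky)
    sxx, sxy, syy = (np.fft.fft2(s) for s in stress)
    tx = np.fft.ifft2(1j * (KX * sxx + KY * sxy)).real
    ty = np.fft.ifft2(1j * (KX * sxy + KY * syy)).real
    return tx, ty


def generate_traction_pattern(
    shape: tuple[int, int],
    spacing: float,
    peak_stress: float,
    correlation_length: float,
    seed: int,
) -> TractionPattern:
    """Smooth random zero-mean traction field, deterministic in ``seed``.

    The field is the divergence of a random smooth intercellular stress
    tensor whose components are low-pass-filtered white noise (periodic
    Gaussian filter of width ``correlation_length``); see
    :func:`_divergence_of_random_stress` for why this construction, and
    not plain filtered noise, is the right model of a monolayer.  The
    result has exactly zero spatial mean per component and is jointly
    rescaled so the maximum vector magnitude equals ``peak_stress`` (Pa).
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    if not peak_stress > 0:
        raise ValueError("peak_stress must be positive")
    if correlation_length < 2 * spacing:
        raise ValueError("correlation_length must be >= 2 * spacing")
    rng = np.random.default_rng(seed)
    tx, ty = _divergence_of_random_stress(rng, shape, correlation_length / spacing)
    peak = np.sqrt(tx**2 + ty**2).max()
    scale = peak_stress / peak
    fld = VectorField2D(u_x=tx * scale, u_y=ty * scale, spacing=spacing)
    return TractionPattern(field=fld, seed=seed)


def ar1_traction_schedule(
    n_frames: int,
    rho: float,
    shape: tuple[int, int],
    spacing: float,
    peak_stress: float,
    correlation_length: float,
    seed: int,
) -> list[TractionPattern]:
    """First-order autoregressive sequence of traction patterns.

    s_t = rho s_{t-1} + sqrt(1 - rho^2) e_t with independent smooth
    innovations e_t, so the stationary marginal scale is constant and
    the lag-l field correlation is rho^l in expectation.  All frames are
    scaled by one common factor (max magnitude over the whole movie =
    ``peak_stress``); per-frame rescaling would distort the temporal
    correlation structure.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sigma_nodes = correlation_length / spacing

    def innovation() -> tuple[np.ndarray, np.ndarray]:
        return _divergence_of_random_stress(rng, shape, sigma_nodes)

    sx, sy = innovation()
    states = [(sx, sy)]
    w = np.sqrt(1.0 - rho**2)
    for _ in range(1, n_frames):
        ex, ey = innovation()
        sx = rho * sx + w * ex
        sy = rho * sy + w * ey
        states.append((sx, sy))
    peak = max(np.sqrt(sx**2 + sy**2).max() for sx, sy in states)
    scale = peak_stress / peak
    return [
        TractionPattern(
            field=VectorField2D(u_x=sx * scale, u_y=sy * scale, spacing=spacing),
            seed=seed,
        )
        for sx, sy in states
    ]


def forward_displacement(
    traction: TractionPattern | VectorField2D, substrate: ElasticSubstrate
) -> VectorField2D:
    """Surface displacement field (um) of the gel under a traction field (Pa).

    Periodic half-space solution u(k) = G(k) tau(k) per nonzero
    wavevector; the zero-frequency (rigid-motion) mode is set to zero.
    Exactly linear in the traction and in 1/E.
    """
    fld = traction.field if isinstance(traction, TractionPattern) else traction
    ny, nx = fld.shape
    if ny != nx:
        # non-square grids are fine as long as spacing is isotropic,
        # which VectorField2D guarantees; nothing to do
        pass
    ux, uy = apply_forward(fld.u_x, fld.u_y, fld.spacing, substrate)
    return VectorField2D(u_x=ux, u_y=uy, spacing=fld.spacing, origin=fld.origin)


def random_bead_field(
    fov_shape_px: tuple[int, int],
    pixel_size: float,
    density: float = DEFAULT_BEAD_DENSITY,
    psf_sigma_px: float = DEFAULT_PSF_SIGMA_PX,
    amplitude: float = 300.0,
    amplitude_cv: float = 0.2,
    seed: int = 0,
) -> BeadField:
    """Uniformly scattered beads with log-normal brightness variation.

    ``density`` is beads per px^2 (0.02 by default, matching a dense but
    non-overlapping preparation of 0.1 um beads).
    """
    if not density > 0:
        raise ValueError("bead density must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = fov_shape_px
    n = rng.poisson(density * ny * nx)
    n = max(n, 1)
    xs = rng.uniform(0, nx * pixel_size, size=n)
    ys = rng.uniform(0, ny * pixel_size, size=n)
    sigma_ln = np.sqrt(np.log(1.0 + amplitude_cv**2))
    amps = amplitude * rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=n)
    return BeadField(
        positions=np.column_stack([xs, ys]),
        amplitudes=amps,
        psf_sigma=psf_sigma_px * pixel_size,
    )


def _stamp_gaussians(
    canvas: np.ndarray,
    positions_px: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> None:
    """Accumulate bead Gaussians onto ``canvas`` in place.

    Each bead contributes amp * exp(-r^2 / (2 sigma^2)) evaluated at
    pixel centers over a +/- 4 sigma patch; patches are clipped at the
    frame border (beads are clipped, never wrapped).
    """
    ny, nx = canvas.shape
    r = int(np.ceil(4.0 * sigma_px))
    n_outside = 0
    n_partial = 0
    for (x, y), amp in zip(positions_px, amplitudes):
        cx, cy = int(np.floor(x)), int(np.floor(y))
        x0, x1 = cx - r, cx + r + 1
        y0, y1 = cy - r, cy + r + 1
        if x1 <= 0 or y1 <= 0 or x0 >= nx or y0 >= ny:
            n_outside += 1
            continue
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
            n_partial += 1
        xs = np.arange(max(x0, 0), min(x1, nx))
        ys = np.arange(max(y0, 0), min(y1, ny))
        gx = np.exp(-((xs - x) ** 2) / (2.0 * sigma_px**2))
        gy = np.exp(-((ys - y) ** 2) / (2.0 * sigma_px**2))
        canvas[np.ix_(ys, xs)] += amp * np.outer(gy, gx)
    if n_outside:
        logger.warning("%d beads moved outside the frame and were clipped", n_outside)
    if n_partial:
        logger.debug("%d beads at the frame border were partially clipped", n_partial)


def _interpolate_displacement(
    displacement: VectorField2D, positions: np.ndarray
) -> np.ndarray:
    """Bilinear displacement (um) at arbitrary (x, y) positions (um)."""
    cols = (positions[:, 0] - displacement.origin[0]) / displacement.spacing
    rows = (positions[:, 1] - displacement.origin[1]) / displacement.spacing
    coords = np.vstack([rows, cols])
    ux = ndimage.map_coordinates(displacement.u_x, coords, order=1, mode="nearest")
    uy = ndimage.map_coordinates(displacement.u_y, coords, order=1, mode="nearest")
    return np.column_stack([ux, uy])


def render_bead_images(
    beads: BeadField,
    displacement: VectorField2D | None,
    shape_px: tuple[int, int],
    pixel_size: float,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    timestamps: tuple[float, float] = (0.0, 0.0),
) -> tuple[ImageFrame, ImageFrame]:
    """Render a (reference, deformed) bead-image pair.

    The reference frame shows beads at rest; the deformed frame shows
    each bead advected by the displacement field interpolated
    (bilinearly) at its rest position.  Noise is applied after
    rendering, with independent draws per frame, seeded.
    """
    sigma_px = beads.psf_sigma / pixel_size
    ref = np.zeros(shape_px)
    _stamp_gaussians(ref, beads.positions / pixel_size, beads.amplitudes, sigma_px)
    if displacement is None:
        moved = beads.positions
    else:
        moved = beads.positions + _interpolate_displacement(displacement, beads.positions)
    def_ = np.zeros(shape_px)
    _stamp_gaussians(def_, moved / pixel_size, beads.amplitudes, sigma_px)

    rng = np.random.default_rng(seed)
    out = []
    for img in (ref, def_):
        noisy = img
        if noise.poisson_scale > 0:
            noisy = rng.poisson(np.clip(noisy, 0, None) * noise.poisson_scale) / noise.poisson_scale
        if noise.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
        out.append(np.clip(noisy, 0.0, None))
    t_ref, t_def = timestamps
    return (
        ImageFrame(out[0], pixel_size, timestamp=t_ref),
        ImageFrame(out[1], pixel_size, timestamp=t_def),
    )


@dataclass
class SimulatedMovie:
    """A synthetic recording plus its ground truth.

    ``sequence`` holds the deformed frames in time order followed by the
    stress-free reference frame as the **last** frame, mirroring the
    experimental protocol of detaching the cells (SDS) at the end of the
    recording; ``reference_index`` points at it.  Ground-truth fields
    are cropped to the analysis field of view, with origins in the
    cropped image's coordinate frame.
    """

    sequence: ImageSequence
    reference_index: int
    ground_truth: pd.DataFrame
    displacement_fields: list[VectorField2D] = field(default_factory=list)
    traction_fields: list[VectorField2D] = field(default_factory=list)


def _strain_energy_density(tau: VectorField2D, u: VectorField2D) -> tuple[float, float]:
    """(U_s in pN um, U_s per area in pN/um) via the node-sum surface integral."""
    dot = tau.u_x * u.u_x + tau.u_y * u.u_y
    us = 0.5 * float(dot.sum()) * tau.spacing**2
    return us, us / tau.fov_area


def simulate_movie(
    pattern_schedule: list[TractionPattern],
    substrate: ElasticSubstrate,
    beads: BeadField,
    cadence: float = 10.0,
    fov_shape_px: tuple[int, int] = (DEFAULT_FOV_PX, DEFAULT_FOV_PX),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> SimulatedMovie:
    """Simulate a time-lapse TFM recording with known ground truth.

    Patterns are defined on the full simulation grid (conventionally 2x
    the field of view); images are rendered on the simulation domain and
    cropped centrally to ``fov_shape_px``.  The bead field must cover
    the simulation domain and is reused across frames.  One stress-free
    reference frame is appended after the deformed frames.

    ``cadence`` is the frame interval in minutes (10 min in the
    monolayer recordings this emulates).
    """
    if not pattern_schedule:
        raise ValueError("pattern_schedule must be non-empty")
    shapes = {p.field.shape for p in pattern_schedule}
    if len(shapes) != 1:
        raise ValueError(f"all patterns must share one grid, got shapes {shapes}")
    spacings = {p.field.spacing for p in pattern_schedule}
    if len(spacings) != 1:
        raise ValueError("all patterns must share one grid spacing")

    grid_shape = shapes.pop()
    spacing = spacings.pop()
    sim_ny_px = int(round(grid_shape[0] * spacing / pixel_size))
    sim_nx_px = int(round(grid_shape[1] * spacing / pixel_size))
    fov_ny, fov_nx = fov_shape_px
    if sim_ny_px < fov_ny or sim_nx_px < fov_nx:
        raise ValueError("simulation grid smaller than the requested field of view")
    r0_px = (sim_ny_px - fov_ny) // 2
    c0_px = (sim_nx_px - fov_nx) // 2

    # node crop: nodes whose position falls inside the pixel crop window
    node_r0 = int(np.ceil(r0_px * pixel_size / spacing))
    node_c0 = int(np.ceil(c0_px * pixel_size / spacing))
    node_r1 = int(np.floor((r0_px + fov_ny) * pixel_size / spacing))
    node_c1 = int(np.floor((c0_px + fov_nx) * pixel_size / spacing))

    crop_origin = (c0_px * pixel_size, r0_px * pixel_size)

    rng = np.random.default_rng(seed)
    frames: list[ImageFrame] = []
    disp_fields: list[VectorField2D] = []
    trac_fields: list[VectorField2D] = []
    rows = []
    for i, pattern in enumerate(pattern_schedule):
        u_full = forward_displacement(pattern, substrate)
        _, deformed = render_bead_images(
            beads,
            u_full,
            (sim_ny_px, sim_nx_px),
            pixel_size,
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
            timestamps=(0.0, i * cadence),
        )
        frames.append(
            ImageFrame(
                deformed.pixels[r0_px : r0_px + fov_ny, c0_px : c0_px + fov_nx],
                pixel_size,
                timestamp=i * cadence,
            )
        )
        u_crop = u_full.crop(node_r0, node_r1, node_c0, node_c1)
        tau_crop = pattern.field.crop(node_r0, node_r1, node_c0, node_c1)
        for f in (u_crop, tau_crop):
            f.origin = (f.origin[0] - crop_origin[0], f.origin[1] - crop_origin[1])
        us, us_per_area = _strain_energy_density(tau_crop, u_crop)
        pattern.ground_truth_strain_energy = us
        disp_fields.append(u_crop)
        trac_fields.append(tau_crop)
        rows.append(
            {
                "frame": i,
                "timestamp_min": i * cadence,
                "strain_energy_pN_um": us,
                "strain_energy_per_area_pN_per_um": us_per_area,
                "mean_traction_Pa": float(tau_crop.magnitude().mean()),
                "rms_displacement_um": u_crop.rms(),
            }
        )

    ref_full, _ = render_bead_images(
        beads,
        None,
        (sim_ny_px, sim_nx_px),
        pixel_size,
        noise=noise,
        seed=int(rng.integers(0, 2**31 - 1)),
        timestamps=(len(pattern_schedule) * cadence, 0.0),
    )
    frames.append(
        ImageFrame(
            ref_full.pixels[r0_px : r0_px + fov_ny, c0_px : c0_px + fov_nx],
            pixel_size,
            timestamp=len(pattern_schedule) * cadence,
        )
    )

    return SimulatedMovie(
        sequence=ImageSequence(frames),
        reference_index=len(frames) - 1,
        ground_truth=pd.DataFrame(rows),
        displacement_fields=disp_fields,
        traction_fields=trac_fields,
    )


def default_scene_movie(
    n_frames: int = 8,
    young_modulus: float = 3000.0,
    poisson_ratio: float = 0.45,
    peak_stress: float = DEFAULT_PEAK_STRESS,
    rho: float = 0.9,
    noise: NoiseModel = NoiseModel(gaussian_sd=4.0, poisson_scale=1.0),
    seed: int = 0,
    fov_px: int = DEFAULT_FOV_PX,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> SimulatedMovie:
    """The package's reference benchmark scene.

    A ``fov_px`` x ``fov_px`` field of view at 0.2 um/px, simulated on a
    doubled domain; AR(1)-evolving monolayer traction pattern; bead
    density 0.02 /px^2 with a 1 px Gaussian PSF; shot + read noise at
    roughly 20 dB signal-to-noise.  E = 3 kPa by default (the soft-gel
    condition); pass 35000 for the stiff condition.
    """
    sim_px = 2 * fov_px
    spacing = DEFAULT_NODE_SPACING_PX * pixel_size
    grid_n = sim_px // DEFAULT_NODE_SPACING_PX
    schedule = ar1_traction_schedule(
        n_frames,
        rho,
        (grid_n, grid_n),
        spacing,
        peak_stress,
        DEFAULT_CORRELATION_LENGTH,
        seed=seed,
    )
    beads = random_bead_field(
        (sim_px, sim_px), pixel_size, seed=seed + 1
    )
    substrate = ElasticSubstrate(young_modulus, poisson_ratio)
    return simulate_movie(
        schedule,
        substrate,
        beads,
        cadence=10.0,
        fov_shape_px=(fov_px, fov_px),
        pixel_size=pixel_size,
        noise=noise,
        seed=seed + 2,
    )
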