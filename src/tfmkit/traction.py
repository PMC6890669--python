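"""Traction reconstruction by regularized Fourier-transform traction cytometry.

Given the measured surface displacement field of the gel and its
elastic constants, the monolayer's traction stress field is recovered
by inverting the half-space Green's operator per spatial frequency,

    tau(k) = (G*G + lambda^2 I)^(-1) G* u(k),

with Tikhonov weight lambda stabilizing the high-frequency content that
measurement noise dominates.  lambda = 0 reduces to the direct inverse
tau = G^(-1) u, which is exact on noise-free periodic data.

Real fields of view are not periodic, and the displacements inside one
also carry the long-range elastic signature of tractions outside it; by
default the inversion is solved as a partially observed problem on a
doubled domain (see InversionSettings).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal.windows import tukey

from .fields import VectorField2D
from .greens import (
    apply_forward,
    apply_inverse,
    greens_tensor,
    median_greens_singular_value,
    wavevectors,
)
from .substrate import ElasticSubstrate

__all__ = [
    "InversionSettings",
    "InversionMethod",
    "LambdaPolicy",
    "PadMode",
    "Taper",
    "reconstruct_traction",
    "choose_lambda",
]

logger = logging.getLogger(__name__)


class LambdaPolicy(str, Enum):
    FIXED = "fixed"
    L_CURVE = "l_curve"


class InversionMethod(str, Enum):
    FFT = "fft"
    MASKED_CG = "masked_cg"


class Taper(str, Enum):
    NONE = "none"
    COSINE = "cosine"


class PadMode(str, Enum):
    ZERO = "zero"
    MIRROR = "mirror"


@dataclass(frozen=True)
class InversionSettings:
    """Settings of the displacement -> traction inversion.

    regularization_lambda is dimensionless: the absolute Tikhonov
    weight is ``regularization_lambda`` times the median singular value
    of the Green's operator on the analysis grid, which makes one value
    transferable across grid sizes, stiffnesses and units.  The default
    1e-2 barely perturbs clean data while damping the high-frequency
    content that camera noise dominates.

    A measured field of view is not periodic, and the displacements
    inside it also carry the long-range elastic signature of tractions
    *outside* it.  The default method (``masked_cg``) therefore solves
    the inversion as a partially observed problem: tractions live on a
    domain ``pad_factor`` times the field of view, the forward map is
    constrained only where displacements were measured, and the
    Tikhonov normal equations are solved by conjugate gradients
    (FFT-applied operator, a fraction of a second per frame).  The
    ``fft`` method is the classical one-shot spectral inversion with
    mirror/zero padding and optional cosine taper; with ``pad_factor=1``
    (periodic data, exact round trips) both methods reduce to the same
    direct per-wavevector solve.
    """

    regularization_lambda: float = 1e-2
    lambda_policy: LambdaPolicy = LambdaPolicy.FIXED
    method: InversionMethod = InversionMethod.MASKED_CG
    pad_factor: int = 2
    pad_mode: PadMode = PadMode.MIRROR
    taper: Taper = Taper.NONE
    taper_alpha: float = 0.2
    cg_max_iterations: int = 120
    cg_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.regularization_lambda < 0:
            raise ValueError("regularization_lambda must be >= 0")
        if self.pad_factor not in (1, 2):
            raise ValueError("pad_factor must be 1 or 2")
        if not (0.0 <= self.taper_alpha <= 1.0):
            raise ValueError("taper_alpha must lie in [0, 1]")
        if self.cg_max_iterations < 1:
            raise ValueError("cg_max_iterations must be >= 1")


def _prepare(u: VectorField2D, settings: InversionSettings) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Mean-subtract, taper and pad the displacement components."""
    ny, nx = u.shape
    ux = u.u_x - u.u_x.mean()
    uy = u.u_y - u.u_y.mean()
    if settings.taper is Taper.COSINE:
        win = np.outer(tukey(ny, settings.taper_alpha), tukey(nx, settings.taper_alpha))
        ux = ux * win
        uy = uy * win
    if settings.pad_factor > 1:
        if settings.pad_mode is PadMode.MIRROR:
            ux = np.pad(ux, ((0, ny), (0, nx)), mode="symmetric")
            uy = np.pad(uy, ((0, ny), (0, nx)), mode="symmetric")
            return ux, uy, (0, 0, ny, nx)
        pny, pnx = settings.pad_factor * ny, settings.pad_factor * nx
        r0, c0 = (pny - ny) // 2, (pnx - nx) // 2
        px = np.zeros((pny, pnx))
        py = np.zeros((pny, pnx))
        px[r0 : r0 + ny, c0 : c0 + nx] = ux
        py[r0 : r0 + ny, c0 : c0 + nx] = uy
        return px, py, (r0, c0, ny, nx)
    return ux, uy, (0, 0, ny, nx)


def _masked_cg_inverse(
    displacement: VectorField2D,
    substrate: ElasticSubstrate,
    settings: InversionSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Tikhonov inversion with the forward map observed only on the FOV.

    Solves (A^T A + lam^2 I) tau = A^T u by conjugate gradients, where
    A = (restrict to FOV) o G on a domain ``pad_factor`` times the
    field of view.  G is symmetric, so A^T embeds the residual (zeros
    outside the FOV) and applies G again.  Returns the traction
    components cropped to the FOV.
    """
    ny, nx = displacement.shape
    N_y, N_x = settings.pad_factor * ny, settings.pad_factor * nx
    r0, c0 = (N_y - ny) // 2, (N_x - nx) // 2
    kxg, kyg = wavevectors((N_y, N_x), displacement.spacing)
    gxx, gxy, gyy = greens_tensor(kxg, kyg, substrate)
    lam = 0.0
    if settings.regularization_lambda > 0:
        sv = median_greens_singular_value(
            (N_y, N_x), displacement.spacing, substrate
        )
        lam = settings.regularization_lambda * sv

    mask = np.zeros((N_y, N_x))
    mask[r0 : r0 + ny, c0 : c0 + nx] = 1.0
    uobs_x = np.zeros((N_y, N_x))
    uobs_y = np.zeros((N_y, N_x))
    uobs_x[r0 : r0 + ny, c0 : c0 + nx] = displacement.u_x - displacement.u_x.mean()
    uobs_y[r0 : r0 + ny, c0 : c0 + nx] = displacement.u_y - displacement.u_y.mean()

    def apply_g(tx: np.ndarray, ty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        TX, TY = np.fft.fft2(tx), np.fft.fft2(ty)
        return (
            np.fft.ifft2(gxx * TX + gxy * TY).real,
            np.fft.ifft2(gxy * TX + gyy * TY).real,
        )

    def normal_op(tx: np.ndarray, ty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fx, fy = apply_g(tx, ty)
        gx, gy = apply_g(fx * mask, fy * mask)
        return gx + lam * lam * tx, gy + lam * lam * ty

    bx, by = apply_g(uobs_x, uobs_y)  # A^T u (uobs already zero outside FOV)
    xx = np.zeros((N_y, N_x))
    xy = np.zeros((N_y, N_x))
    rx, ry = bx.copy(), by.copy()
    px, py = rx.copy(), ry.copy()
    rs = float(np.sum(rx**2 + ry**2))
    rs0 = rs
    for _ in range(settings.cg_max_iterations):
        if rs <= settings.cg_tolerance * rs0:
            break
        qx, qy = normal_op(px, py)
        alpha = rs / float(np.sum(px * qx + py * qy))
        xx += alpha * px
        xy += alpha * py
        rx -= alpha * qx
        ry -= alpha * qy
        rs_new = float(np.sum(rx**2 + ry**2))
        beta = rs_new / rs
        px = rx + beta * px
        py = ry + beta * py
        rs = rs_new
    return (
        xx[r0 : r0 + ny, c0 : c0 + nx],
        xy[r0 : r0 + ny, c0 : c0 + nx],
    )


def reconstruct_traction(
    displacement: VectorField2D,
    substrate: ElasticSubstrate,
    settings: InversionSettings = InversionSettings(),
) -> VectorField2D:
    """Recover the traction field (Pa) from a displacement field (um).

    The displacement grid must be complete (all nodes valid — fill gaps
    with :func:`tfmkit.piv.validate_and_fill` first) and the substrate
    must have nu < 0.5.  The traction map is returned on the input
    grid; its spatial mean per component is zero by construction.
    """
    if not displacement.valid_mask.all():
        raise ValueError(
            "displacement field has invalid nodes; run validate_and_fill before inversion"
        )
    if (
        settings.method is InversionMethod.MASKED_CG
        and settings.pad_factor > 1
    ):
        if not (
            np.all(np.isfinite(displacement.u_x))
            and np.all(np.isfinite(displacement.u_y))
        ):
            raise ValueError("displacement field contains non-finite values")
        if substrate.poisson_ratio >= 0.5:
            raise ValueError(
                "traction inversion requires poisson_ratio < 0.5 — use nu <= 0.49"
            )
        tx, ty = _masked_cg_inverse(displacement, substrate, settings)
    else:
        ux, uy, (r0, c0, ny, nx) = _prepare(displacement, settings)
        lam_abs = 0.0
        if settings.regularization_lambda > 0:
            sv = median_greens_singular_value(ux.shape, displacement.spacing, substrate)
            lam_abs = settings.regularization_lambda * sv
        tx, ty = apply_inverse(ux, uy, displacement.spacing, substrate, lam=lam_abs)
        tx = tx[r0 : r0 + ny, c0 : c0 + nx]
        ty = ty[r0 : r0 + ny, c0 : c0 + nx]
    tx = tx - tx.mean()
    ty = ty - ty.mean()
    return VectorField2D(
        u_x=tx,
        u_y=ty,
        spacing=displacement.spacing,
        origin=displacement.origin,
    )


def choose_lambda(
    displacement: VectorField2D,
    substrate: ElasticSubstrate,
    candidate_lambdas: list[float],
    settings: InversionSettings = InversionSettings(),
) -> float:
    """L-curve selection of the (dimensionless) Tikhonov weight.

    For each candidate the residual norm ||G tau - u|| and solution
    norm ||tau|| are computed; the candidate at the corner of the
    log-log curve (maximum discrete curvature) is returned.  If the
    curvature is degenerate (monotone, no interior maximum), the
    smallest candidate is returned with a warning.
    """
    if len(candidate_lambdas) < 3:
        raise ValueError("need at least 3 candidate lambdas")
    cands = sorted(float(c) for c in candidate_lambdas)
    if cands[0] < 0:
        raise ValueError("candidate lambdas must be >= 0")

    res_norms = []
    sol_norms = []
    for lam in cands:
        s = dataclasses.replace(
            settings, regularization_lambda=lam, lambda_policy=LambdaPolicy.FIXED
        )
        tau = reconstruct_traction(displacement, substrate, s)
        pred_x, pred_y = apply_forward(tau.u_x, tau.u_y, tau.spacing, substrate)
        du = displacement.mean_subtracted()
        res = np.sqrt(np.sum((pred_x - du.u_x) ** 2 + (pred_y - du.u_y) ** 2))
        res_norms.append(res)
        sol_norms.append(tau.norm())
    logger.info(
        "choose_lambda L-curve: lambdas=%s residuals=%s solutions=%s",
        cands, res_norms, sol_norms,
    )

    eps = 1e-300
    x = np.log10(np.asarray(res_norms) + eps)
    y = np.log10(np.asarray(sol_norms) + eps)
    # discrete curvature via the circumscribed-circle formula per interior triple
    curv = np.full(len(cands), -np.inf)
    for i in range(1, len(cands) - 1):
        a = np.hypot(x[i] - x[i - 1], y[i] - y[i - 1])
        b = np.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
        c = np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1])
        cross = (x[i] - x[i - 1]) * (y[i + 1] - y[i]) - (y[i] - y[i - 1]) * (x[i + 1] - x[i])
        if a * b * c > 0:
            curv[i] = 2.0 * cross / (a * b * c)
    best = int(np.argmax(curv))
    if not np.isfinite(curv[best]) or curv[best] <= 0:
        logger.warning("choose_lambda: degenerate L-curve, returning smallest candidate")
        return cands[0]
    return cands[best]
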