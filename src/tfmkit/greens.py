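"""Fourier-space surface Green's tensor of the elastic half-space.

The Boussinesq/Cerruti problem — tangential traction applied to the free
surface of a semi-infinite, isotropic, linear-elastic body — has the
surface response, per spatial wavevector k = (k_x, k_y), k = |k|:

    u(k) = G(k) tau(k)

    G(k) = 2 (1 + nu) / (E k^3) *
           [ (1 - nu) k^2 + nu k_y^2     - nu k_x k_y        ]
           [ - nu k_x k_y                (1 - nu) k^2 + nu k_x^2 ]

with E the Young's modulus and nu the Poisson ratio.  This is the kernel
of Fourier-transform traction cytometry (FTTC): the forward map takes a
traction field (Pa) to the surface displacement field (um, with k in
1/um), and the inverse map recovers tractions from measured
displacements.  G is real, symmetric and positive definite for every
k != 0 (det G proportional to (1 - nu) > 0), so the Tikhonov-regularized
inverse

    tau(k) = (G^2 + lambda^2 I)^(-1) G u(k)

is well posed.  The k = 0 (spatial-mean) mode is unobservable — a
uniform traction on a periodic domain produces no relative deformation —
and is set to zero by convention in both directions.

Units: with tractions in Pa, lengths in um and k in rad/um, G has units
um/Pa and displacements come out in um directly (1 Pa um^2 = 1 pN).
"""

from __future__ import annotations

import numpy as np

from .substrate import ElasticSubstrate

__all__ = [
    "greens_tensor",
    "wavevectors",
    "apply_forward",
    "apply_inverse",
    "median_greens_singular_value",
]


def wavevectors(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Angular wavevector grids (KX, KY) in rad/um for an FFT of `shape`."""
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    return np.meshgrid(kx, ky)


def greens_tensor(
    kx: np.ndarray, ky: np.ndarray, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Components (Gxx, Gxy, Gyy) of G(k); entries at k = 0 are set to 0.

    G is symmetric, so three components determine it.
    """
    E = substrate.young_modulus
    nu = substrate.poisson_ratio
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        gxy = pref * (-nu * kx * ky)
    zero = k2 == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    # On even-sized grids the Nyquist frequency aliases +k and -k into one
    # sample; the off-diagonal coupling (odd in each k component) has no
    # consistent value there, and keeping it breaks the Hermitian symmetry
    # that makes real fields map to real fields.  Convention: drop it.
    ny, nx = kx.shape
    nyq = np.zeros_like(gxy, dtype=bool)
    if nx % 2 == 0:
        nyq |= kx == kx.min()  # unpaired column Nyquist
    if ny % 2 == 0:
        nyq |= ky == ky.min()  # unpaired row Nyquist
    gxy[nyq] = 0.0
    return gxx, gxy, gyy


def apply_forward(
    tau_x: np.ndarray,
    tau_y: np.ndarray,
    spacing: float,
    substrate: ElasticSubstrate,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (um) produced by a traction field (Pa).

    Periodic (FFT) evaluation: u(k) = G(k) tau(k), zero mode zeroed.
    Exactly linear in tau and in 1/E.
    """
    kxg, kyg = wavevectors(tau_x.shape, spacing)
    gxx, gxy, gyy = greens_tensor(kxg, kyg, substrate)
    tx = np.fft.fft2(tau_x)
    ty = np.fft.fft2(tau_y)
    ux = np.fft.ifft2(gxx * tx + gxy * ty).real
    uy = np.fft.ifft2(gxy * tx + gyy * ty).real
    return ux, uy


def apply_inverse(
    u_x: np.ndarray,
    u_y: np.ndarray,
    spacing: float,
    substrate: ElasticSubstrate,
    lam: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Traction field (Pa) recovered from a displacement field (um).

    Solves, per nonzero wavevector, the 2x2 system
    (G^2 + lam^2 I) tau = G u; for lam = 0 this is the direct inverse
    tau = G^-1 u.  `lam` is an absolute Tikhonov weight in the units of
    G (um/Pa); see :func:`median_greens_singular_value` for the scale
    the higher-level API normalizes against.
    """
    if substrate.poisson_ratio >= 0.5:
        raise ValueError(
            "traction inversion requires poisson_ratio < 0.5; "
            "nu = 0.5 makes the normal-tangential coupling assumptions "
            "of the half-space inversion degenerate — use nu <= 0.49"
        )
    if not (np.all(np.isfinite(u_x)) and np.all(np.isfinite(u_y))):
        raise ValueError("displacement field contains non-finite values")
    kxg, kyg = wavevectors(u_x.shape, spacing)
    gxx, gxy, gyy = greens_tensor(kxg, kyg, substrate)
    Ux = np.fft.fft2(u_x)
    Uy = np.fft.fft2(u_y)

    zero = (kxg**2 + kyg**2) == 0
    if lam == 0.0:
        # direct inverse tau = G^-1 u — numerically preferable to the
        # normal-equations form, whose condition number is squared
        det = gxx * gyy - gxy**2
        det[zero] = 1.0  # k=0 mode forced to zero below
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = (gyy * Ux - gxy * Uy) / det
            ty = (-gxy * Ux + gxx * Uy) / det
    else:
        # right-hand side G u (G symmetric)
        rx = gxx * Ux + gxy * Uy
        ry = gxy * Ux + gyy * Uy
        # M = G^2 + lam^2 I, symmetric 2x2 per k
        mxx = gxx**2 + gxy**2 + lam**2
        mxy = gxy * (gxx + gyy)
        myy = gyy**2 + gxy**2 + lam**2
        det = mxx * myy - mxy**2
        det[zero] = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            tx = (myy * rx - mxy * ry) / det
            ty = (-mxy * rx + mxx * ry) / det
    tx[zero] = 0.0
    ty[zero] = 0.0
    bad = ~np.isfinite(det) | (det == 0)
    if np.any(bad & ~zero):
        raise FloatingPointError("singular Green's operator at a nonzero wavevector")
    tau_x = np.fft.ifft2(tx).real
    tau_y = np.fft.ifft2(ty).real
    return tau_x, tau_y


def median_greens_singular_value(
    shape: tuple[int, int], spacing: float, substrate: ElasticSubstrate
) -> float:
    """Median singular value of G over the nonzero wavevectors of a grid.

    Used as the natural scale for a dimensionless Tikhonov weight:
    lambda_abs = lambda_rel * median_sv.  For the symmetric positive
    definite 2x2 blocks the singular values are the eigenvalues.
    """
    kxg, kyg = wavevectors(shape, spacing)
    gxx, gxy, gyy = greens_tensor(kxg, kyg, substrate)
    nz = (kxg**2 + kyg**2) > 0
    tr = gxx[nz] + gyy[nz]
    disc = np.sqrt((gxx[nz] - gyy[nz]) ** 2 + 4.0 * gxy[nz] ** 2)
    eigs = np.concatenate([(tr + disc) / 2.0, (tr - disc) / 2.0])
    return float(np.median(eigs))
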