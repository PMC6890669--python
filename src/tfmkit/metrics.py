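"""Per-frame monolayer mechanics readouts.

Three quantities summarize what a confluent monolayer does to its
substrate in each frame:

* strain energy — the mechanical work stored in the gel,
  U_s = 1/2 * integral over the surface of tau . u, reported per area
  of the field of view (pN/um internally, nN/um in display units);
* mean traction magnitude — the integral of |tau| over the field of
  view divided by its area, i.e. the spatial mean stress (Pa
  internally, nN/um^2 = kPa in display units);
* temporal correlation of deformation maps — how similar the
  displacement field stays across frames, a readout of how dynamic the
  monolayer is.

Unit identity used throughout: 1 Pa * um * um^2 = 1 pN um exactly, so
energy bookkeeping needs no physical constants, only powers of 10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import ImageSequence, VectorField2D
from .piv import (
    PIVSettings,
    ReferencePolicy,
    estimate_displacement,
    reference_from_sequence,
    validate_and_fill,
)
from .substrate import ElasticSubstrate
from .traction import InversionSettings, reconstruct_traction

__all__ = [
    "MonolayerMetrics",
    "strain_energy",
    "traction_force_per_area",
    "deformation_correlation",
    "movie_metrics",
    "PN_PER_UM_TO_NN_PER_UM",
    "PA_TO_NN_PER_UM2",
]

logger = logging.getLogger(__name__)

# exact decimal conversions to display units
PN_PER_UM_TO_NN_PER_UM = 1e-3   # energy per area
PA_TO_NN_PER_UM2 = 1e-3         # stress (1 nN/um^2 = 1 kPa)


@dataclass(frozen=True)
class MonolayerMetrics:
    """One frame's mechanics summary.

    strain_energy_per_area is in pN/um (multiply by 1e-3 for nN/um);
    mean_traction_magnitude in Pa (multiply by 1e-3 for nN/um^2);
    rms_displacement in um; fov_area in um^2.
    """

    timestamp: float
    strain_energy: float
    strain_energy_per_area: float
    mean_traction_magnitude: float
    rms_displacement: float
    fov_area: float


def strain_energy(
    traction: VectorField2D, displacement: VectorField2D
) -> tuple[float, float]:
    """Strain energy U_s = 1/2 sum(tau . u) * spacing^2 and U_s / area.

    ``traction`` in Pa, ``displacement`` in um, both on the identical
    grid; returns (U_s in pN um, U_s per field-of-view area in pN/um).
    A negative value is physically inconsistent with an elastic origin
    of the displacements and triggers a warning.
    """
    if traction.shape != displacement.shape:
        raise ValueError(
            f"grid mismatch: traction {traction.shape} vs displacement {displacement.shape}"
        )
    if not np.isclose(traction.spacing, displacement.spacing):
        raise ValueError("traction and displacement grids have different spacing")
    dot = traction.u_x * displacement.u_x + traction.u_y * displacement.u_y
    us = 0.5 * float(dot.sum()) * traction.spacing**2
    if us < 0:
        warnings.warn(
            "negative strain energy: traction and displacement are anti-aligned, "
            "which is inconsistent with an elastic response",
            stacklevel=2,
        )
    return us, us / traction.fov_area


def traction_force_per_area(traction: VectorField2D) -> float:
    """Integral of |tau| over the field of view divided by its area (Pa).

    Equals the spatial mean traction magnitude; multiply by 1e-3 for
    the display unit nN/um^2.
    """
    if traction.u_x.size == 0:
        raise ValueError("empty traction field")
    return float(traction.magnitude().mean())


def deformation_correlation(
    fields: list[VectorField2D], max_lag: int | None = None
) -> pd.DataFrame:
    """Mean normalized inner product of deformation maps vs frame lag.

    For lag l, averages over frame pairs (t, t+l) the quantity
    sum(u_t . u_{t+l}) / (||u_t|| ||u_{t+l}||), which lies in [-1, 1]
    and equals 1 at lag 0.  Pairs involving a zero-norm field are
    skipped (and logged).  Returns a table with columns lag, correlation
    and n_pairs.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 frames")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid")
    if max_lag is None:
        max_lag = len(fields) - 1
    max_lag = min(max_lag, len(fields) - 1)
    norms = np.array([f.norm() for f in fields])
    n_zero = int((norms == 0).sum())
    if n_zero:
        logger.warning("deformation_correlation: skipping %d zero-norm frames", n_zero)
    rows = []
    for lag in range(max_lag + 1):
        vals = []
        for t in range(len(fields) - lag):
            if norms[t] == 0 or norms[t + lag] == 0:
                continue
            a, b = fields[t], fields[t + lag]
            inner = float(np.sum(a.u_x * b.u_x + a.u_y * b.u_y))
            vals.append(inner / (norms[t] * norms[t + lag]))
        rows.append(
            {
                "lag": lag,
                "correlation": float(np.mean(vals)) if vals else np.nan,
                "n_pairs": len(vals),
            }
        )
    return pd.DataFrame(rows)


def movie_metrics(
    seq: ImageSequence,
    substrate: ElasticSubstrate,
    piv_settings: PIVSettings = PIVSettings(),
    inversion_settings: InversionSettings = InversionSettings(),
    reference_policy: ReferencePolicy | str = ReferencePolicy.LAST_FRAME,
    reference_index: int | None = None,
    return_fields: bool = False,
):
    """Run the full per-frame pipeline PIV -> fill -> FTTC -> metrics.

    The reference frame (selected by ``reference_policy``) is excluded
    from the output rows.  A frame whose PIV field is unusable is
    logged and reported as a row of NaNs rather than aborting the
    movie.  Returns a DataFrame (one row per analyzed frame); with
    ``return_fields=True`` also returns the per-frame filled
    displacement and traction fields.
    """
    reference = reference_from_sequence(seq, reference_policy, reference_index)
    ref_pos = (
        len(seq) - 1
        if ReferencePolicy(reference_policy) is ReferencePolicy.LAST_FRAME
        else reference_index
    )
    rows = []
    disp_fields: list[VectorField2D] = []
    trac_fields: list[VectorField2D] = []
    for i, frame in enumerate(seq):
        if i == ref_pos:
            continue
        try:
            raw = estimate_displacement(reference, frame, piv_settings)
            u = validate_and_fill(raw, piv_settings)
            tau = reconstruct_traction(u, substrate, inversion_settings)
            us, us_per_area = strain_energy(tau, u)
            rows.append(
                {
                    "frame": i,
                    "timestamp_min": frame.timestamp,
                    "strain_energy_pN_um": us,
                    "strain_energy_per_area_pN_per_um": us_per_area,
                    "mean_traction_Pa": traction_force_per_area(tau),
                    "rms_displacement_um": u.rms(),
                    "fov_area_um2": u.fov_area,
                }
            )
            disp_fields.append(u)
            trac_fields.append(tau)
        except (RuntimeError, ValueError) as exc:  # frame-level failure, movie continues
            logger.error("frame %d failed: %s", i, exc)
            rows.append(
                {
                    "frame": i,
                    "timestamp_min": frame.timestamp,
                    "strain_energy_pN_um": np.nan,
                    "strain_energy_per_area_pN_per_um": np.nan,
                    "mean_traction_Pa": np.nan,
                    "rms_displacement_um": np.nan,
                    "fov_area_um2": np.nan,
                }
            )
    table = pd.DataFrame(rows)
    if return_fields:
        return table, disp_fields, trac_fields
    return table
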