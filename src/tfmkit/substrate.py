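"""Elastic substrate material model shared by forward simulation and inversion."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ElasticSubstrate"]


@dataclass(frozen=True)
class ElasticSubstrate:
    """Linear-elastic, isotropic, semi-infinite substrate (a hydrogel slab
    thick enough that the glass coverslip below is mechanically invisible).

    Parameters
    ----------
    young_modulus
        Young's modulus E in pascals.  Polyacrylamide gels used for
        endothelial-monolayer traction assays span roughly 3--70 kPa.
    poisson_ratio
        Poisson ratio nu, dimensionless.  Polyacrylamide is nearly
        incompressible; 0.45 is the package default.  Values must lie in
        [0, 0.5]; nu = 0.5 is accepted for forward simulation but the
        traction inversion requires nu < 0.5.
    model
        Only ``"semi_infinite"`` is supported; finite-thickness
        corrections are out of scope.
    """

    young_modulus: float
    poisson_ratio: float = 0.45
    model: str = "semi_infinite"

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive (Pa)")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.model != "semi_infinite":
            raise ValueError(f"unsupported substrate model: {self.model!r}")

    def scaled(self, factor: float) -> "ElasticSubstrate":
        """Return the same material with Young's modulus multiplied by factor."""
        return ElasticSubstrate(self.young_modulus * factor, self.poisson_ratio, self.model)
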