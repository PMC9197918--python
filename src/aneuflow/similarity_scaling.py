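"""Dynamic-similarity bookkeeping.

Reynolds numbers, in-vivo / in-vitro flow matching, and the ratio bundle
used to rescale vorticity and wall shear stress between a scaled phantom
and the patient-scale flow.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FluidSpec",
    "SimilaritySpec",
    "reynolds",
    "percent_deviation",
    "build_similarity",
]


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid properties: density (kg/m^3) and dynamic viscosity (Pa·s)."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class SimilaritySpec:
    """Ratio bundle for cross-system scaling of vorticity and WSS.

    mu_ratio = mu_vivo / mu_vitro, u_ratio = u_vivo / u_vitro,
    d_ratio = d_vitro / d_vivo.  All dimensionless and positive.
    """

    mu_ratio: float = 1.0
    u_ratio: float = 1.0
    d_ratio: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_ratio, self.u_ratio, self.d_ratio) <= 0:
            raise ValueError("all similarity ratios must be > 0")

    def inverse(self) -> "SimilaritySpec":
        return SimilaritySpec(1.0 / self.mu_ratio, 1.0 / self.u_ratio, 1.0 / self.d_ratio)


def reynolds(fluid: FluidSpec, mean_velocity: float, diameter: float) -> float:
    """Reynolds number rho·V·D/mu for the given fluid and inlet scales.

    The characteristic velocity convention (mean vs peak) is the
    caller's choice; this module documents mean inlet velocity as the
    default convention.
    """
    if mean_velocity <= 0 or diameter <= 0:
        raise ValueError("velocity and diameter must be > 0")
    return fluid.density * mean_velocity * diameter / fluid.viscosity


def percent_deviation(measured: float, reference: float) -> float:
    """Absolute percent deviation 100·|measured - reference| / reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * abs(measured - reference) / abs(reference)


def build_similarity(
    fluid_vivo: FluidSpec,
    fluid_vitro: FluidSpec,
    d_ratio: float,
    re_match: bool = True,
    u_ratio_override: float | None = None,
) -> SimilaritySpec:
    """Assemble the scaling-ratio bundle for a scaled-phantom experiment.

    With ``re_match`` the velocity ratio follows from equating
    rho·V·D/mu across the two systems:

        u_vivo/u_vitro = (mu_vivo/mu_vitro) · (rho_vitro/rho_vivo) · d_ratio

    where ``d_ratio = d_vitro/d_vivo`` is the geometric scale-up factor.
    Otherwise ``u_ratio_override`` is used verbatim.
    """
    if d_ratio <= 0:
        raise ValueError("d_ratio must be > 0")
    mu_ratio = fluid_vivo.viscosity / fluid_vitro.viscosity
    if re_match:
        u_ratio = mu_ratio * (fluid_vitro.density / fluid_vivo.density) * d_ratio
    elif u_ratio_override is not None:
        u_ratio = u_ratio_override
    else:
        raise ValueError("need re_match=True or an explicit u_ratio_override")
    return SimilaritySpec(mu_ratio=mu_ratio, u_ratio=u_ratio, d_ratio=d_ratio)
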