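"""Continuum fluid media.

A :class:`FluidMedium` bundles the three continuum properties that enter every
bubble model here: mass density, dynamic viscosity and surface tension.  The
two presets correspond to the TIP3P-water and 10.4 % (w/w) gelatin-like gel
systems whose measured properties drive the worked examples (water:
σ = 0.0557 N/m, η = 0.321 mPa·s, ρ = 1.02 g/cm³; gel: σ = 0.0976 N/m,
η = 0.684 mPa·s, ρ = 1.05 g/cm³), together with the initial bubble radii of
the two systems (≈95 Å).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluidMedium", "WATER", "GEL", "MEDIA", "INITIAL_RADIUS_M"]


@dataclass(frozen=True)
class FluidMedium:
    """Continuum properties of a liquid or gel, in SI units.

    Parameters
    ----------
    name : str
        Label ("water", "gel", ...).
    density : float
        Mass density ρ in kg/m³. Must be positive.
    viscosity : float
        Dynamic viscosity η in Pa·s. Must be non-negative.
    surface_tension : float
        Surface tension σ (S) in N/m. Must be non-negative.
    """

    name: str
    density: float
    viscosity: float
    surface_tension: float

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.viscosity < 0:
            raise ValueError(f"viscosity must be >= 0, got {self.viscosity}")
        if self.surface_tension < 0:
            raise ValueError(
                f"surface_tension must be >= 0, got {self.surface_tension}"
            )


#: Pure (TIP3P-like) water preset.
WATER = FluidMedium("water", density=1020.0, viscosity=0.321e-3, surface_tension=0.0557)

#: Gelatin-like hydrogel preset (10.4 % w/w collagen).
GEL = FluidMedium("gel", density=1050.0, viscosity=0.684e-3, surface_tension=0.0976)

MEDIA = {"water": WATER, "gel": GEL}

#: Initial (pre-carved) bubble radius of each preset system, in metres.
INITIAL_RADIUS_M = {"water": 95.16e-10, "gel": 95.35e-10}
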