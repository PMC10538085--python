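"""Core value types shared across the package.

Unit conventions (documented on every field):

* lengths in micrometres (um)
* stresses, moduli and pressures in pascal (Pa)
* with these choices, force comes out in piconewton (Pa * um^2 = pN)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidGeometryError, InvalidInputError

__all__ = [
    "CellSpec",
    "TrapGeometry",
    "PowerLawModel",
    "FitResult",
    "SweepRecord",
]


@dataclass(frozen=True)
class CellSpec:
    """One spherical cell: diameter a (um), Young's modulus E (Pa),
    Poisson ratio nu (dimensionless, default 0.3)."""

    diameter: float
    youngs_modulus: float
    poisson_ratio: float = 0.3

    def __post_init__(self):
        if not self.diameter > 0:
            raise InvalidInputError(f"diameter must be > 0, got {self.diameter}")
        if not self.youngs_modulus > 0:
            raise InvalidInputError(
                f"youngs_modulus must be > 0, got {self.youngs_modulus}"
            )
        if not 0 < self.poisson_ratio < 0.5:
            raise InvalidInputError(
                f"poisson_ratio must lie in (0, 0.5), got {self.poisson_ratio}"
            )

    @property
    def radius(self) -> float:
        """Cell radius in um."""
        return 0.5 * self.diameter


@dataclass(frozen=True)
class TrapGeometry:
    """One trapping unit: two diamond pillars facing across a gap.

    gap            -- minimum clearance between the pillars, um
    diagonal_major -- pillar diagonal along the flow axis (x), um
    diagonal_minor -- pillar diagonal across the flow (y), um
    height         -- pillar/channel height (z), um
    fillet_radius  -- rounding radius of the pillar vertices, um
    """

    gap: float
    diagonal_major: float = 70.0
    diagonal_minor: float = 70.0
    height: float = 50.0
    fillet_radius: float = 2.0

    def __post_init__(self):
        if not self.gap > 0:
            raise InvalidInputError(f"gap must be > 0, got {self.gap}")
        if not self.gap < self.diagonal_minor:
            raise InvalidGeometryError(
                f"gap ({self.gap}) must be smaller than the minor diagonal "
                f"({self.diagonal_minor})"
            )
        if self.fillet_radius < 0:
            raise InvalidInputError(
                f"fillet_radius must be >= 0, got {self.fillet_radius}"
            )
        for name in ("diagonal_major", "diagonal_minor", "height"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class PowerLawModel:
    """Critical-pressure relation  Pc = coefficient * E * (a/g)**exponent.

    The literature-calibrated default is coefficient 0.027, exponent 2.
    """

    coefficient: float = 0.027
    exponent: float = 2.0

    def __post_init__(self):
        if not self.coefficient > 0:
            raise InvalidInputError(
                f"coefficient must be > 0, got {self.coefficient}"
            )
        if not self.exponent > 0:
            raise InvalidInputError(f"exponent must be > 0, got {self.exponent}")


@dataclass(frozen=True)
class FitResult:
    """Diagnostics of one power-law fit.

    r_squared is computed on the untransformed pressure scale
    (1 - SS_res/SS_tot); values < 0 are possible for models worse than the
    mean and are flagged degenerate rather than clipped.
    standard_error     -- residual standard error on the pressure scale, Pa
    log_standard_error -- residual standard error on the log scale
                          (dimensionless), reported because published fit
                          statistics often quote it without units
    """

    model: PowerLawModel
    r_squared: float
    standard_error: float
    log_standard_error: float
    n_points: int
    residuals: tuple = field(repr=False, default=())
    exponent_mode: str = "free"

    def __post_init__(self):
        n_params = 2 if self.exponent_mode == "free" else 1
        if self.n_points < n_params + 1:
            raise InsufficientDataError(
                f"{self.n_points} points cannot support {n_params} parameters"
            )

    @property
    def degenerate(self) -> bool:
        return self.r_squared < 0


@dataclass(frozen=True)
class SweepRecord:
    """One (cell, geometry) -> critical pressure observation, Pa."""

    cell: CellSpec
    geometry: TrapGeometry
    critical_pressure: float
    converged: bool = True
    seed: int | None = None
    settings: str | None = None

    def __post_init__(self):
        if self.critical_pressure < 0:
            raise InvalidInputError(
                f"critical_pressure must be >= 0, got {self.critical_pressure}"
            )

    @property
    def size_ratio(self) -> float:
        """a/g, the diameter-to-gap ratio."""
        return self.cell.diameter / self.geometry.gap


def as_float_array(x, name: str) -> np.ndarray:
    """Coerce to a 1-D float array, rejecting NaN/inf."""
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr
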