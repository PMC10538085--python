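"""Neo-Hookean hyperelastic material on linear tetrahedra.

Strain energy density (the conventional two-parameter compressible form)

    W = C10 * (I1_bar - 3) + (1/D1) * (J - 1)^2

with F the deformation gradient, J = det F, I1_bar = J^(-2/3) tr(F^T F),
and the parameters obtained from the engineering constants by

    C10 = E / (4 (1 + nu)),    D1 = 6 (1 - 2 nu) / E.

On linear tets F is constant per element, so energy and internal nodal
forces are exact one-point quadrature, fully vectorized over elements.
States approaching element inversion (J below a floor) are handled with a
stiff quadratic energy extension so the line search backs away instead of
producing NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidInputError

__all__ = ["MaterialNH", "ElementKernel"]

_J_FLOOR = 0.05  # below this, switch to the quadratic inversion barrier


@dataclass(frozen=True)
class MaterialNH:
    """Neo-Hookean parameters C10 (Pa) and D1 (1/Pa), retaining the source
    engineering constants for reporting."""

    c10: float
    d1: float
    source_modulus: float
    source_poisson: float

    def __post_init__(self):
        if not (self.c10 > 0 and self.d1 > 0):
            raise InvalidInputError("c10 and d1 must be > 0")

    @classmethod
    def from_engineering(cls, youngs_modulus: float, poisson_ratio: float) -> "MaterialNH":
        if not youngs_modulus > 0 or not 0 < poisson_ratio < 0.5:
            raise InvalidInputError("need E > 0 and 0 < nu < 0.5")
        return cls(
            c10=youngs_modulus / (4.0 * (1.0 + poisson_ratio)),
            d1=6.0 * (1.0 - 2.0 * poisson_ratio) / youngs_modulus,
            source_modulus=youngs_modulus,
            source_poisson=poisson_ratio,
        )


class ElementKernel:
    """Precomputed reference-configuration data for fast energy/force
    evaluation of one mesh + material pair.

    All quantities may be in any consistent unit system; the solver feeds it
    dimensionless data (lengths / R, stresses / E).
    """

    def __init__(self, ref_nodes: np.ndarray, elements: np.ndarray, c10: float, kappa_d1: float):
        self.elements = elements
        self.c10 = c10
        self.inv_d1 = kappa_d1  # the 1/D1 factor, same stress units as c10
        x = ref_nodes[elements]
        dm = np.stack(
            [x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=2
        )  # (m, 3, 3) columns = edge vectors
        det = np.linalg.det(dm)
        if np.any(det <= 0):
            raise InvalidInputError("reference mesh contains non-positive tets")
        self.dm_inv = np.linalg.inv(dm)
        self.vol0 = det / 6.0

    def deformation_gradients(self, nodes: np.ndarray) -> np.ndarray:
        x = nodes[self.elements]
        ds = np.stack(
            [x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=2
        )
        return ds @ self.dm_inv

    def energy_and_forces(self, nodes: np.ndarray):
        """Total strain energy and the internal nodal force array dW/dx."""
        F = self.deformation_gradients(nodes)
        J = np.linalg.det(F)
        I1 = np.einsum("mij,mij->m", F, F)

        safe = J > _J_FLOOR
        Js = np.where(safe, J, _J_FLOOR)
        Finv = np.linalg.inv(
            np.where(safe[:, None, None], F, np.eye(3)[None])
        )
        FinvT = np.transpose(Finv, (0, 2, 1))

        Jm23 = Js ** (-2.0 / 3.0)
        W = self.c10 * (Jm23 * I1 - 3.0) + self.inv_d1 * (Js - 1.0) ** 2
        # dW/dF for the safe branch
        P = (
            self.c10
            * (2.0 * Jm23[:, None, None] * F
               - (2.0 / 3.0) * (Jm23 * I1)[:, None, None] * FinvT)
            + (2.0 * self.inv_d1 * (Js - 1.0) * Js)[:, None, None] * FinvT
        )
        if not np.all(safe):
            # near inversion: freeze J at the floor in W (so the clamped branch
            # is exactly differentiated) and add a stiff quadratic barrier in J
            barrier_k = 1e3 * (self.c10 + self.inv_d1)
            dJdF = _cofactor(F)  # d(det F)/dF, defined for any F
            W = np.where(safe, W, W + barrier_k * (_J_FLOOR - J) ** 2)
            P_unsafe = (
                2.0 * self.c10 * Jm23[:, None, None] * F
                - (2.0 * barrier_k * (_J_FLOOR - J))[:, None, None] * dJdF
            )
            P = np.where(safe[:, None, None], P, P_unsafe)

        energy = float(np.sum(self.vol0 * W))
        # nodal forces: H = V0 * P * Dm_inv^T gives forces on nodes 1..3
        H = self.vol0[:, None, None] * (P @ np.transpose(self.dm_inv, (0, 2, 1)))
        forces = np.zeros_like(nodes)
        np.add.at(forces, self.elements[:, 1], H[:, :, 0])
        np.add.at(forces, self.elements[:, 2], H[:, :, 1])
        np.add.at(forces, self.elements[:, 3], H[:, :, 2])
        np.add.at(forces, self.elements[:, 0], -H.sum(axis=2))
        return energy, forces

    def jacobians(self, nodes: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.deformation_gradients(nodes))

    def max_principal_stretch(self, nodes: np.ndarray) -> float:
        F = self.deformation_gradients(nodes)
        s = np.linalg.svd(F, compute_uv=False)
        return float(s.max())


def _cofactor(F: np.ndarray) -> np.ndarray:
    """Cofactor matrix of each 3x3 in a batch: d(det F)/dF."""
    c = np.empty_like(F)
    c[:, :, 0] = np.cross(F[:, :, 1], F[:, :, 2], axis=1)
    c[:, :, 1] = np.cross(F[:, :, 2], F[:, :, 0], axis=1)
    c[:, :, 2] = np.cross(F[:, :, 0], F[:, :, 1], axis=1)
    return c
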