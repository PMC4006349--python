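"""Observer system estimating the user's ideal boundary.

The auxiliary field psi_hat mediates between the evolving segmentation phi
and the accumulated input U.  Its error terms are

    xi_hat = H_eps(phi) - H_eps(psi_hat)     (observer vs. visualized state)
    e_U    = H_eps(psi_hat) - H_eps(U)       (observer vs. user input)

and the observer PDE

    psi_hat_t = delta_eps(psi_hat) * [ xi_hat - e_U * (alpha U)^2 ]

makes psi_hat follow phi where the user is silent ((alpha U)^2 ~ 0) and be
driven toward the sign of U where input has accumulated past U_M (with
alpha = 1/U_M the input term then outweighs a saturated xi_hat).  The
Lyapunov functionals F, D_hat and V = F + D_hat certify stability of the
coupled loop once input stops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LevelSetField, ScalarField
from .inputs import InputField
from .levelset import delta_eps, evolve_step, heaviside_eps

__all__ = [
    "ObserverState",
    "observer_errors",
    "observer_step",
    "lyapunov_functionals",
]


@dataclass
class ObserverState:
    """psi_hat plus its current error fields (both in [-1, 1] pointwise)."""

    psi_hat: LevelSetField
    xi_hat: ScalarField
    e_U: ScalarField

    @classmethod
    def from_phi(cls, phi: LevelSetField, U: InputField) -> "ObserverState":
        """Initial observer state psi_hat(x, 0) = phi(x, 0)."""
        psi_hat = phi.copy()
        xi_hat, e_U = observer_errors(phi, psi_hat, U)
        return cls(psi_hat, xi_hat, e_U)


def observer_errors(phi: LevelSetField, psi_hat: LevelSetField,
                    U: InputField) -> tuple[ScalarField, ScalarField]:
    """Error fields xi_hat and e_U on the shared grid.

    H_eps is applied to the raw U values with the level-set half-width, so
    an un-clicked cell (U = 0) sits at the half-label 0.5.
    """
    if phi.grid != psi_hat.grid:
        raise ValueError("phi and psi_hat live on different grids")
    H_phi = heaviside_eps(phi.values, phi.eps_phys)
    H_psi = heaviside_eps(psi_hat.values, psi_hat.eps_phys)
    H_U = heaviside_eps(U.values, phi.eps_phys)
    xi_hat = ScalarField(H_phi - H_psi, phi.grid)
    e_U = ScalarField(H_psi - H_U, phi.grid)
    return xi_hat, e_U


def observer_step(state: ObserverState, phi: LevelSetField, U: InputField,
                  alpha: float, dt: float) -> ObserverState:
    """One explicit step of the psi_hat PDE with refreshed error fields.

    The delta_eps(psi_hat) prefactor confines the update to psi_hat's own
    narrowband; cells outside it are untouched.
    """
    xi_hat, e_U = observer_errors(phi, state.psi_hat, U)
    drive = xi_hat.values - e_U.values * (alpha * U.values) ** 2
    psi_hat = evolve_step(state.psi_hat, drive, dt)
    xi_hat, e_U = observer_errors(phi, psi_hat, U)
    return ObserverState(psi_hat, xi_hat, e_U)


def lyapunov_functionals(state: ObserverState, U: InputField,
                         alpha: float) -> tuple[float, float, float]:
    """(F, D_hat, V): input-agreement and state-agreement error functionals.

    F = int 1/2 (alpha U)^2 e_U^2 dx,  D_hat = int 1/2 xi_hat^2 dx,
    V = F + D_hat.
    """
    vol = state.psi_hat.grid.cell_volume
    aU2 = (alpha * U.values) ** 2
    F = 0.5 * float((aU2 * state.e_U.values**2).sum()) * vol
    D_hat = 0.5 * float((state.xi_hat.values**2).sum()) * vol
    return F, D_hat, F + D_hat
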