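"""Dynamic heart-valve model: Bernoulli resistance, blood inertance and
first-order opening/closing dynamics.

The transvalvular pressure gradient relates to flow through

    dP = B Q|Q| + L dQ/dt,     B = rho / (2 A_eff^2),  L = rho l_eff / A_eff

with the effective orifice area interpolating linearly between a closed
(A_min) and open (A_max) area through the opening fraction xi in [0, 1],
which itself obeys a pressure-driven first-order rate law.

Units: pressures in mmHg, flows in mL/s, areas in cm^2, lengths in cm and
blood density in g/cm^3.  The CGS-to-mmHg conversion (1 mmHg =
1333.22 dyn/cm^2) is applied once, here, so that B comes out in
mmHg.s^2/mL^2 and L in mmHg.s^2/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMHG_DYN_CM2",
    "ValveParams",
    "ValveState",
    "effective_area",
    "bernoulli_coefficients",
    "valve_derivatives",
]

#: dyn/cm^2 per mmHg
MMHG_DYN_CM2 = 1333.22


@dataclass
class ValveParams:
    """Geometry and rate constants of one valve.

    A_max/A_min  maximum and minimum effective orifice areas (cm^2); A_min
                 defaults to 0.1% of A_max — a negligible leak that keeps
                 the Bernoulli resistance finite when closed.
    l_eff        effective length (cm), sets the inertance.
    rho          blood density (g/cm^3).
    K_vo/K_vc    opening/closing rate coefficients (1/(mmHg.s)).
    """

    A_max: float = 2.5
    A_min: float | None = None
    l_eff: float = 1.5
    rho: float = 1.06
    K_vo: float = 12.0
    K_vc: float = 12.0

    def __post_init__(self) -> None:
        if self.A_min is None:
            self.A_min = 0.001 * self.A_max
        if not (self.A_max > self.A_min >= 0):
            raise ValueError("need A_max > A_min >= 0")
        if self.A_min == 0:
            raise ValueError("A_min must be > 0 to keep B finite")
        if self.K_vo <= 0 or self.K_vc <= 0:
            raise ValueError("rate coefficients must be > 0")
        if self.rho <= 0 or self.l_eff <= 0:
            raise ValueError("rho and l_eff must be > 0")

    @property
    def b_coef(self) -> float:
        """rho/2 in mmHg units: B = b_coef / A_eff^2 (mmHg.s^2/mL^2)."""
        return self.rho / 2.0 / MMHG_DYN_CM2

    @property
    def l_coef(self) -> float:
        """rho*l_eff in mmHg units: L = l_coef / A_eff (mmHg.s^2/mL)."""
        return self.rho * self.l_eff / MMHG_DYN_CM2


@dataclass
class ValveState:
    """Flow through the valve (mL/s) and opening fraction xi in [0, 1]."""

    Q: float = 0.0
    xi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0):
            raise ValueError("xi must lie in [0, 1]")


def effective_area(xi: float, params: ValveParams) -> float:
    """Effective orifice area A_eff = (A_max - A_min) xi + A_min (cm^2)."""
    if not (0.0 <= xi <= 1.0):
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    return (params.A_max - params.A_min) * xi + params.A_min


def bernoulli_coefficients(A_eff: float,
                           params: ValveParams) -> tuple[float, float]:
    """Bernoulli resistance B (mmHg.s^2/mL^2) and inertance L (mmHg.s^2/mL).

    B = rho / (2 A_eff^2), L = rho l_eff / A_eff, converted from CGS to the
    internal mmHg/mL/s unit system via ``MMHG_DYN_CM2``.
    """
    if A_eff <= 0:
        raise ValueError("A_eff must be > 0")
    B = params.b_coef / A_eff**2
    L = params.l_coef / A_eff
    return B, L


def valve_derivatives(dP: float, state: ValveState,
                      params: ValveParams) -> tuple[float, float]:
    """Time derivatives (dQ/dt, dxi/dt) for pressure gradient ``dP`` (mmHg).

    dQ/dt = (dP - B Q|Q|) / L with B, L evaluated at the current opening;
    the opening fraction relaxes toward 1 at rate K_vo*dP when the gradient
    is favourable and toward 0 at rate K_vc*|dP| otherwise.  Both xi = 0 and
    xi = 1 are invariant boundaries.
    """
    A_eff = effective_area(state.xi, params)
    B, L = bernoulli_coefficients(A_eff, params)
    dQ = (dP - B * state.Q * abs(state.Q)) / L
    if dP > 0:
        dxi = (1.0 - state.xi) * params.K_vo * dP
    else:
        dxi = state.xi * params.K_vc * dP
    return dQ, dxi


def steady_flow(dP: float, xi: float, params: ValveParams) -> float:
    """Steady-state flow at fixed opening: dP = B Q|Q| inverted.

    Convenience for the constant-pressure-head test rig; returns the signed
    flow sqrt(|dP|/B) * sign(dP).
    """
    A_eff = effective_area(xi, params)
    B, _ = bernoulli_coefficients(A_eff, params)
    return float(np.sign(dP) * np.sqrt(abs(dP) / B))
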