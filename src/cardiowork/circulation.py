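"""Systemic and pulmonary vascular chambers.

Each vessel chamber (aorta ao, systemic artery sa, systemic vein sv, vena
cava vc, pulmonary artery pa, pulmonary vein pv) is a linear elastance
reservoir P = E (V - V_d); inter-chamber flows are Ohmic, Q = dP/R; volume
bookkeeping is pure conservation, dV/dt = Q_in - Q_out, so the closed loop
conserves total blood volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VESSELS",
    "CirculationParams",
    "vessel_pressure",
    "resistive_flow",
    "volume_derivatives",
    "TopologyError",
]

VESSELS = ("ao", "sa", "sv", "vc", "pa", "pv")


class TopologyError(ValueError):
    """Raised when a flow references a chamber outside the loop."""


@dataclass
class CirculationParams:
    """Vessel elastances E (mmHg/mL), unstressed volumes V_d (mL),
    inter-chamber resistances R (mmHg.s/mL) and total blood volume (mL).

    The resistive chain follows the closed loop
    ao -R_ao- sa -R_sys- sv -R_vc- vc -R_ra- RA and
    pa -R_pul- pv -R_pv- LA; valves connect the cardiac chambers.
    """

    E_ao: float = 3.7
    E_sa: float = 2.5
    E_sv: float = 0.008
    E_vc: float = 0.05
    E_pa: float = 0.45
    E_pv: float = 0.035
    Vd_ao: float = 70.0
    Vd_sa: float = 220.0
    Vd_sv: float = 1200.0
    Vd_vc: float = 300.0
    Vd_pa: float = 50.0
    Vd_pv: float = 250.0
    R_ao: float = 0.03
    R_sys: float = 0.92
    R_vc: float = 0.04
    R_ra: float = 0.01
    R_pul: float = 0.08
    R_pv: float = 0.01
    total_volume: float = 3950.0

    def __post_init__(self) -> None:
        for name in VESSELS:
            if getattr(self, f"E_{name}") <= 0:
                raise ValueError(f"E_{name} must be > 0")
            if getattr(self, f"Vd_{name}") < 0:
                raise ValueError(f"Vd_{name} must be >= 0")
        for r in ("R_ao", "R_sys", "R_vc", "R_ra", "R_pul", "R_pv"):
            if getattr(self, r) <= 0:
                raise ValueError(f"{r} must be > 0")
        if self.total_volume <= sum(getattr(self, f"Vd_{n}") for n in VESSELS):
            raise ValueError("total blood volume must exceed the summed "
                             "vessel unstressed volumes")


def vessel_pressure(V, E: float, V_d: float):
    """Linear elastance reservoir pressure P = E (V - V_d) (mmHg)."""
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("volume must be >= 0")
    p = E * (V - V_d)
    return p if p.ndim else float(p)


def resistive_flow(P_up: float, P_down: float, R: float) -> float:
    """Ohmic flow Q = (P_up - P_down)/R (mL/s), signed, no diode behaviour."""
    if R <= 0:
        raise ValueError(f"resistance must be > 0, got {R}")
    return (P_up - P_down) / R


def volume_derivatives(
    flows: list[tuple[str, str, float]],
    chambers: tuple[str, ...],
) -> dict[str, float]:
    """Net volume rate per chamber from directed flows (source, sink, Q).

    Returns dV/dt per chamber; by construction the rates sum to zero
    (conservation on the closed loop).
    """
    dv = {name: 0.0 for name in chambers}
    for src, dst, q in flows:
        if src not in dv or dst not in dv:
            raise TopologyError(f"flow {src}->{dst} references an unknown "
                                "chamber")
        dv[src] -= q
        dv[dst] += q
    return dv
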