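"""Morris elementary-effects screening.

One-at-a-time random trajectories through a rescaled unit hypercube; each
trajectory yields one elementary effect per parameter.  A parameter's
influence is summarised by the mean of absolute effects (mu*), the standard
deviation of effects (sigma, flagging nonlinearity/interactions) and the
Euclidean distance D = sqrt(mu*^2 + sigma^2) from the origin of the
mu*-sigma plane, which provides the global ranking.

The screening target for the cardiovascular model is the transvalvular
pressure gradient dP = max(P_LV) - Pao_sys, with each parameter ranged
+/-30% around its nominal value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .parameters import (X_ART_NAMES, X_LV_NAMES, ParameterSet, get_param,
                         nominal_parameters)
from .simulator import SolverConfig, simulate

__all__ = [
    "MorrisConfig",
    "MorrisResult",
    "generate_trajectories",
    "elementary_effect",
    "elementary_effects",
    "morris_stats",
    "rank_cvs_parameters",
    "DEFAULT_SCREEN_NAMES",
]

#: parameters screened on the full model: the ventricular and circulatory
#: identified sets plus the aortic effective area
DEFAULT_SCREEN_NAMES = (("valves.aortic.A_max",) + X_LV_NAMES + X_ART_NAMES)


@dataclass
class MorrisConfig:
    """Trajectory-design settings.

    names / nominal  parameter labels and centre values; the sampled range
                     is nominal * (1 +/- range_fraction).
    r                number of trajectories (elementary effects per
                     parameter).
    levels           grid levels in the unit hypercube.
    delta            step in rescaled [0, 1] coordinates; the classic
                     choice is levels/(2(levels-1)).
    """

    names: tuple[str, ...]
    nominal: np.ndarray
    range_fraction: float = 0.30
    r: int = 10
    levels: int = 4
    delta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.nominal = np.asarray(self.nominal, dtype=float)
        if len(self.names) != self.nominal.size:
            raise ValueError("names and nominal values differ in length")
        if self.r < 2:
            raise ValueError("need r >= 2 trajectories")
        if self.levels < 2:
            raise ValueError("need >= 2 levels")
        if self.delta is None:
            self.delta = self.levels / (2.0 * (self.levels - 1))
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.range_fraction <= 0:
            raise ValueError("range_fraction must be > 0")

    @property
    def p(self) -> int:
        return len(self.names)

    def to_physical(self, x: np.ndarray) -> np.ndarray:
        """Map unit-cube coordinates to physical parameter values."""
        return self.nominal * (1.0 + (2.0 * np.asarray(x) - 1.0)
                               * self.range_fraction)


@dataclass
class MorrisResult:
    """Per-parameter mu*, sigma and distance, plus the global ranking."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    ee: np.ndarray               # (r, p) signed elementary effects
    distance: np.ndarray = field(init=False)
    ranking: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.distance = np.sqrt(self.mu_star**2 + self.sigma**2)
        order = np.argsort(-self.distance)
        self.ranking = [self.names[i] for i in order]

    def as_dict(self) -> dict:
        return {
            name: {
                "mu_star": float(self.mu_star[i]),
                "sigma": float(self.sigma[i]),
                "D": float(self.distance[i]),
                "rank": int(self.ranking.index(name) + 1),
            }
            for i, name in enumerate(self.names)
        }


def generate_trajectories(cfg: MorrisConfig,
                          rng: np.random.Generator | None = None
                          ) -> list[np.ndarray]:
    """r one-at-a-time trajectories of p+1 points in the unit hypercube.

    Each consecutive pair differs in exactly one coordinate by +/-delta and
    every point lies on the level grid inside [0, 1].  Deterministic under
    the configured seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    p, delta = cfg.p, cfg.delta
    grid = np.arange(cfg.levels) / (cfg.levels - 1)
    base_grid = grid[grid + delta <= 1.0 + 1e-12]
    if base_grid.size == 0:
        raise ValueError("delta/levels combination leaves no feasible "
                         "base points")
    trajectories = []
    lower = np.tri(p + 1, p, -1)             # strictly lower triangular ones
    ones = np.ones((p + 1, p))
    for _ in range(cfg.r):
        x_base = rng.choice(base_grid, size=p)
        d_signs = rng.choice([-1.0, 1.0], size=p)
        # a -delta step starting from x_base would exit [0,1]; start those
        # coordinates from x_base + delta instead (standard construction)
        perm = rng.permutation(p)
        b_star = (x_base + (delta / 2.0)
                  * ((2.0 * lower[:, perm] - ones) * d_signs[perm] + 1.0))
        trajectories.append(b_star)
    return trajectories


def elementary_effect(y_pair: tuple[float, float], delta: float) -> float:
    """Absolute elementary effect |Y(X) - Y(X + delta e_j)| / delta."""
    if delta == 0:
        raise ValueError("delta must be nonzero")
    y0, y1 = y_pair
    return abs(y1 - y0) / abs(delta)


def elementary_effects(trajectory: np.ndarray,
                       y: np.ndarray) -> dict[int, float]:
    """Signed elementary effects of one trajectory.

    Returns {parameter index: (Y_after - Y_before) / (x_after - x_before)}
    for each of the p one-coordinate moves.
    """
    ee: dict[int, float] = {}
    for a, b, ya, yb in zip(trajectory[:-1], trajectory[1:], y[:-1], y[1:]):
        dx = b - a
        j = int(np.argmax(np.abs(dx)))
        step = dx[j]
        if step == 0:
            raise ValueError("degenerate trajectory step")
        ee[j] = (yb - ya) / step
    return ee


def morris_stats(ee: np.ndarray, names: tuple[str, ...],
                 sigma_on: str = "signed") -> MorrisResult:
    """mu* (mean |EE|), sigma and distances from an (r, p) effect matrix.

    ``sigma_on="signed"`` computes sigma over the signed effects (the
    revised-Morris convention); ``"abs"`` computes it over |EE|.
    """
    ee = np.asarray(ee, dtype=float)
    if ee.ndim != 2 or ee.shape[0] < 2:
        raise ValueError("need an (r, p) matrix with r >= 2")
    mu_star = np.abs(ee).mean(axis=0)
    if sigma_on == "signed":
        sigma = ee.std(axis=0, ddof=1)
    elif sigma_on == "abs":
        sigma = np.abs(ee).std(axis=0, ddof=1)
    else:
        raise ValueError("sigma_on must be 'signed' or 'abs'")
    return MorrisResult(names=names, mu_star=mu_star, sigma=sigma, ee=ee)


def screen_function(cfg: MorrisConfig, func,
                    sigma_on: str = "signed") -> MorrisResult:
    """Morris screening of an arbitrary callable Y = func(physical vector).

    Trajectories whose evaluation fails (func raises or returns NaN) are
    discarded with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    trajectories = generate_trajectories(cfg, rng)
    rows = []
    for k, traj in enumerate(trajectories):
        try:
            ys = np.array([func(cfg.to_physical(x)) for x in traj])
        except Exception as err:           # noqa: BLE001 - flag and move on
            warnings.warn(f"trajectory {k} discarded: {err}",
                          RuntimeWarning, stacklevel=2)
            continue
        if not np.all(np.isfinite(ys)):
            warnings.warn(f"trajectory {k} discarded: non-finite output",
                          RuntimeWarning, stacklevel=2)
            continue
        ee = elementary_effects(traj, ys)
        rows.append([ee[j] for j in range(cfg.p)])
    if len(rows) < 2:
        raise RuntimeError("fewer than two usable trajectories")
    return morris_stats(np.asarray(rows), cfg.names, sigma_on=sigma_on)


def rank_cvs_parameters(
    names: tuple[str, ...] = DEFAULT_SCREEN_NAMES,
    r: int = 10,
    range_fraction: float = 0.30,
    seed: int = 0,
    base: ParameterSet | None = None,
    operating_ava: float = 1.0,
    n_beats: int = 10,
    solver: SolverConfig | None = None,
) -> MorrisResult:
    """Morris screening of the closed-loop model on dP = max(P_LV) - Pao_sys.

    Requires r (p+1) simulations.  The aortic minimum area tracks A_max
    (0.1% leak) whenever A_max is screened.

    By default the screening is centred on an aortic-stenosis operating
    point (``operating_ava`` = 1.0 cm^2, the severe-AS boundary): around a
    healthy valve the transvalvular gradient is ~1 mmHg and carries almost
    no parameter sensitivity, whereas the question the screening answers is
    which parameters shape the gradient in the stenotic regime.
    """
    if base is None:
        base = nominal_parameters()
        base.valves["aortic"].A_max = operating_ava
        base.valves["aortic"].A_min = 0.001 * operating_ava
    nominal = np.array([get_param(base, n) for n in names])
    cfg = MorrisConfig(names=tuple(names), nominal=nominal,
                       range_fraction=range_fraction, r=r, seed=seed)

    def run(values: np.ndarray) -> float:
        ps = base.with_values(names, values)
        if "valves.aortic.A_max" in names:
            a = values[list(names).index("valves.aortic.A_max")]
            ps.valves["aortic"].A_min = 0.001 * a
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = simulate(ps, n_beats=n_beats, solver=solver)
        return res.delta_p

    return screen_function(cfg, run)
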