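"""Cardiac conduction as a network of coupled finite-state automata.

Each automaton represents the activation state of a myocardial tissue and
cycles through four electrophysiological phases: slow diastolic
depolarisation (SDD), upstroke depolarisation (UDP), absolute refractory
period (ARP) and relative refractory period (RRP).  An automaton emits an
activation event at the end of its UDP phase and stimulates its downstream
neighbours after a conduction delay.  A pacemaker automaton (the sinoatrial
node, NSA) self-cycles with period SDD+UDP+ARP+RRP; non-pacemaker automata
idle in SDD until stimulated.

The standard network has seven automata: NSA, right/left atria (RA, LA),
atrioventricular node (NAV), upper bundle of His (UH) and both ventricles
(RV, LV).  Ventricular activation instants serve as QRS fiducial markers
that synchronise the mechanical drivers and the cost functions.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PHASES",
    "AutomatonSpec",
    "AutomatonState",
    "Network",
    "ActivationSchedule",
    "ConfigurationError",
    "step_automaton",
    "run_conduction",
    "qrs_times",
    "standard_network",
]

PHASES = ("SDD", "UDP", "ARP", "RRP")
_NEXT_PHASE = {"SDD": "UDP", "UDP": "ARP", "ARP": "RRP", "RRP": "SDD"}
STANDARD_NAMES = ("NSA", "RA", "LA", "NAV", "UH", "RV", "LV")


class ConfigurationError(ValueError):
    """Raised for ill-formed conduction networks."""


@dataclass
class AutomatonSpec:
    """Phase durations (s), downstream neighbours and pacemaker flag."""

    name: str
    sdd: float
    udp: float
    arp: float
    rrp: float
    neighbors: tuple[tuple[str, float], ...] = ()
    pacemaker: bool = False

    def __post_init__(self) -> None:
        for label, d in (("sdd", self.sdd), ("udp", self.udp),
                         ("arp", self.arp), ("rrp", self.rrp)):
            if d < 0:
                raise ValueError(f"{self.name}: {label} must be >= 0, got {d}")
        for target, delay in self.neighbors:
            if delay < 0:
                raise ValueError(f"{self.name}->{target}: negative delay")

    @property
    def period(self) -> float:
        return self.sdd + self.udp + self.arp + self.rrp

    def duration(self, phase: str) -> float:
        return {"SDD": self.sdd, "UDP": self.udp,
                "ARP": self.arp, "RRP": self.rrp}[phase]


@dataclass
class AutomatonState:
    """Instantaneous state of one automaton: current phase and time in it."""

    spec: AutomatonSpec
    phase: str = "SDD"
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


def step_automaton(
    state: AutomatonState, stimulated: bool, dt: float
) -> tuple[AutomatonState, list[float]]:
    """Advance one automaton by ``dt`` seconds.

    ``stimulated`` marks an incoming stimulation at the start of the step:
    during SDD it truncates SDD and starts UDP, during RRP it restarts UDP,
    during UDP or ARP it is ignored (absolute refractoriness).  Returns the
    new state and the times (relative to the step start) of activation
    events emitted while the step elapsed.

    Phase transitions follow SDD -> UDP -> ARP -> RRP -> SDD, each phase
    lasting its configured duration; the activation event fires at the end
    of UDP.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    spec = state.spec
    phase, elapsed = state.phase, state.elapsed
    if stimulated and phase in ("SDD", "RRP"):
        phase, elapsed = "UDP", 0.0
    events: list[float] = []
    t = 0.0
    remaining = dt
    # walk through phase boundaries that fall inside the step
    while True:
        dur = spec.duration(phase)
        left = dur - elapsed
        if math.isinf(left) or left > remaining:
            elapsed += remaining
            break
        t += left
        remaining -= left
        if phase == "UDP":
            events.append(t)
        phase, elapsed = _NEXT_PHASE[phase], 0.0
        if remaining == 0.0:
            break
    return replace(state, phase=phase, elapsed=elapsed), events


@dataclass
class Network:
    """A set of coupled automata keyed by name."""

    automata: dict[str, AutomatonSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.automata.items():
            for target, _delay in spec.neighbors:
                if target not in self.automata:
                    raise ConfigurationError(
                        f"{name} conducts to unknown automaton {target!r}"
                    )
        self._check_zero_delay_loops()

    def _check_zero_delay_loops(self) -> None:
        # A cycle along edges whose delay and target UDP are both zero would
        # propagate instantaneously forever.
        zero_edges: dict[str, list[str]] = {}
        for name, spec in self.automata.items():
            for target, delay in spec.neighbors:
                if delay == 0.0 and self.automata[target].udp == 0.0:
                    zero_edges.setdefault(name, []).append(target)
        visiting: set[str] = set()
        done: set[str] = set()

        def visit(node: str) -> None:
            if node in done:
                return
            if node in visiting:
                raise ConfigurationError(
                    "zero-delay instantaneous propagation loop detected"
                )
            visiting.add(node)
            for nxt in zero_edges.get(node, ()):
                visit(nxt)
            visiting.discard(node)
            done.add(node)

        for node in zero_edges:
            visit(node)

    @property
    def pacemakers(self) -> list[str]:
        return [n for n, s in self.automata.items() if s.pacemaker]


@dataclass
class ActivationSchedule:
    """Per-automaton ordered activation times plus QRS markers (seconds)."""

    activations: dict[str, list[float]]

    def __post_init__(self) -> None:
        for name, times in self.activations.items():
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name}: activation times not increasing")

    @property
    def qrs(self) -> list[float]:
        return list(self.activations.get("LV", []))

    def to_csv(self, path) -> None:
        """Export as two columns: automaton, time_s."""
        with open(path, "w") as fh:
            fh.write("automaton,time_s\n")
            for name in sorted(self.activations):
                for t in self.activations[name]:
                    fh.write(f"{name},{t:.9f}\n")


def run_conduction(network: Network, duration: float) -> ActivationSchedule:
    """Event-driven simulation of the conduction network over ``duration`` s.

    Returns the deterministic activation schedule.  Uses a priority queue of
    phase-transition and stimulation-arrival events; stimulation semantics
    match :func:`step_automaton`.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not network.automata:
        return ActivationSchedule(activations={})

    phase: dict[str, str] = {}
    # token invalidates scheduled phase-ends after a preemptive stimulation
    token: dict[str, int] = {}
    activations: dict[str, list[float]] = {n: [] for n in network.automata}

    heap: list[tuple[float, int, str, str, int]] = []
    seq = 0

    def schedule_phase_end(t: float, name: str) -> None:
        nonlocal seq
        dur = network.automata[name].duration(phase[name])
        if math.isinf(dur):
            return
        seq += 1
        heapq.heappush(heap, (t + dur, seq, "end", name, token[name]))

    for name in network.automata:
        phase[name] = "SDD"
        token[name] = 0
        schedule_phase_end(0.0, name)

    while heap:
        t, _, kind, name, tok = heapq.heappop(heap)
        if t > duration:
            break
        spec = network.automata[name]
        if kind == "end":
            if tok != token[name]:
                continue  # stale: phase was preempted
            old = phase[name]
            phase[name] = _NEXT_PHASE[old]
            token[name] += 1
            if old == "UDP":
                activations[name].append(t)
                for target, delay in spec.neighbors:
                    seq += 1
                    heapq.heappush(heap, (t + delay, seq, "stim", target, -1))
            schedule_phase_end(t, name)
        else:  # stimulation arrival
            if phase[name] in ("SDD", "RRP"):
                phase[name] = "UDP"
                token[name] += 1
                schedule_phase_end(t, name)

    return ActivationSchedule(activations=activations)


def qrs_times(schedule: ActivationSchedule) -> list[float]:
    """QRS markers: the ventricular (LV) activation instants."""
    return schedule.qrs


def standard_network(
    T: float = 1.0,
    nav_delay: float = 0.03,
    ra_delay: float = 0.01,
    la_delay: float = 0.03,
    av_udp: float = 0.09,
) -> Network:
    """The seven-automaton network (NSA, RA, LA, NAV, UH, RV, LV).

    NSA is the pacemaker; its four phase durations scale with the heart
    period ``T`` so that SDD+UDP+ARP+RRP = T.  Atria are stimulated directly
    from NSA with per-atrium delays; the AV nodal delay is modelled as the
    NAV UDP duration.  Non-pacemaker automata have infinite SDD (they fire
    only when stimulated).
    """
    if T <= 0:
        raise ValueError("heart period T must be > 0")
    inf = math.inf
    auto = {
        "NSA": AutomatonSpec(
            "NSA", sdd=0.57 * T, udp=0.03 * T, arp=0.25 * T, rrp=0.15 * T,
            neighbors=(("RA", ra_delay), ("LA", la_delay), ("NAV", nav_delay)),
            pacemaker=True,
        ),
        "RA": AutomatonSpec("RA", inf, 0.02, 0.25 * T, 0.10 * T),
        "LA": AutomatonSpec("LA", inf, 0.02, 0.25 * T, 0.10 * T),
        "NAV": AutomatonSpec("NAV", inf, av_udp, 0.25 * T, 0.10 * T,
                             neighbors=(("UH", 0.01),)),
        "UH": AutomatonSpec("UH", inf, 0.02, 0.25 * T, 0.10 * T,
                            neighbors=(("RV", 0.01), ("LV", 0.01))),
        "RV": AutomatonSpec("RV", inf, 0.02, 0.25 * T, 0.10 * T),
        "LV": AutomatonSpec("LV", inf, 0.02, 0.25 * T, 0.10 * T),
    }
    return Network(automata=auto)
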