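"""Deterministic synchronous dynamics, attractors, ice and in-ice modules.

All node functions are evaluated from the time-t state only, so the update
is order-independent and the trajectory from a given state is unique. On a
finite state space every trajectory is eventually periodic; the attractor is
found by exact state-recurrence detection (hashing with full-state
verification, never probabilistic).

"Ice" is the set of nodes whose state is constant over the attractor; the
remaining active nodes split into weakly connected components — "lakes of
activity" or *in-ice modules* — each with its own local period. The global
attractor is the composite of the module attractors (lcm of local periods).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lcm

import numpy as np

from .network import KauffmanSystem, encode_inputs

__all__ = [
    "Trajectory",
    "AttractorInfo",
    "IceModule",
    "IceReport",
    "step",
    "simulate",
    "find_attractor",
    "attractor_window",
    "classify_ice",
    "find_in_ice_modules",
    "ice_report",
]

LCM_CAP = 10**9  # above this the global period is reported as not composed


@dataclass
class Trajectory:
    """A time-indexed state sequence states[t], t = 0..t_max."""

    states: np.ndarray  # (t_max+1, N)

    @property
    def t_max(self) -> int:
        return self.states.shape[0] - 1


@dataclass(frozen=True)
class AttractorInfo:
    """First recurrence structure of a trajectory.

    transient_length is the number of steps before the first state that
    recurs; period >= 1 is the cycle length (1 = point attractor).
    """

    found: bool
    transient_length: int = 0
    period: int = 0


@dataclass
class IceModule:
    """One lake of activity: its node set and local period."""

    nodes: np.ndarray
    period: int


@dataclass
class IceReport:
    """Frozen/active partition of the nodes over the attractor."""

    ice_mask: np.ndarray  # (N,) bool, True = frozen
    modules: list[IceModule]
    global_period: int | None = None  # None when not composed (lcm above cap)

    @property
    def ice_fraction(self) -> float:
        return float(self.ice_mask.mean())


def step(system: KauffmanSystem, state: np.ndarray) -> np.ndarray:
    """One synchronous update: every node reads its time-t inputs only."""
    idx = encode_inputs(np.asarray(state), system.inputs, system.spec.s)
    return system.functions[np.arange(system.spec.N), idx]


def simulate(system: KauffmanSystem, state: np.ndarray | None = None, t_max: int = 100) -> Trajectory:
    """Iterate `step` for t_max steps; returns all t_max+1 states."""
    if state is None:
        state = system.state
    states = np.empty((t_max + 1, system.spec.N), dtype=np.int64)
    states[0] = state
    for t in range(t_max):
        states[t + 1] = step(system, states[t])
    return Trajectory(states)


def find_attractor(
    system: KauffmanSystem, state: np.ndarray | None = None, t_cap: int = 1000
) -> AttractorInfo:
    """Detect the first state recurrence within t_cap steps.

    Visited states are hashed by their byte image; a hash hit is verified
    against the stored full state so the answer is exact even under
    collisions.
    """
    if t_cap < 1:
        raise ValueError("t_cap must be >= 1")
    if state is None:
        state = system.state
    cur = np.asarray(state, dtype=np.int64)
    seen: dict[bytes, list[tuple[int, np.ndarray]]] = {}
    seen[cur.tobytes()] = [(0, cur)]
    pows = system.spec.s ** np.arange(system.spec.K)
    flat = system.functions.ravel()
    offs = np.arange(system.spec.N) * system.spec.n_table_entries
    inputs = system.inputs
    for t in range(1, t_cap + 1):
        cur = flat[offs + cur[inputs] @ pows]
        key = cur.tobytes()
        bucket = seen.get(key)
        if bucket is not None:
            for t0, st0 in bucket:
                if np.array_equal(st0, cur):
                    return AttractorInfo(found=True, transient_length=t0, period=t - t0)
            bucket.append((t, cur))
        else:
            seen[key] = [(t, cur)]
    return AttractorInfo(found=False)


def attractor_window(
    system: KauffmanSystem, state: np.ndarray | None = None, t_cap: int = 1000
) -> tuple[Trajectory, AttractorInfo]:
    """Simulate just past the attractor and return (window, info).

    The window covers t = 0 .. transient + period, i.e. at least one full
    attractor rotation past the transient. Raises if no recurrence is found
    within t_cap.
    """
    info = find_attractor(system, state, t_cap)
    if not info.found:
        raise RuntimeError(f"no attractor found within t_cap={t_cap} steps")
    window = simulate(system, state, info.transient_length + info.period)
    return window, info


def _window_recurrence(window: Trajectory) -> AttractorInfo:
    """First recurrence inside an already-simulated window."""
    seen: dict[bytes, int] = {}
    for t in range(window.t_max + 1):
        key = window.states[t].tobytes()
        if key in seen:
            t0 = seen[key]
            if np.array_equal(window.states[t0], window.states[t]):
                return AttractorInfo(True, t0, t - t0)
        seen[key] = t
    return AttractorInfo(False)


def classify_ice(system: KauffmanSystem, window: Trajectory) -> IceReport:
    """Frozen-node mask over the attractor portion of `window`.

    A node is ice iff its state is constant over one full attractor period
    (the transient is excluded: lakes may freeze and re-emerge, so only the
    recurring regime counts). The window must contain a full rotation, i.e.
    at least one recurrence, else an insufficient-window error is raised.
    """
    info = _window_recurrence(window)
    if not info.found:
        raise ValueError(
            "insufficient window: no state recurrence inside it (extend past the transient)"
        )
    cyc = window.states[info.transient_length : info.transient_length + info.period]
    ice = (cyc == cyc[0]).all(axis=0)
    return IceReport(ice_mask=ice, modules=[], global_period=info.period)


def _local_period(cyc_states: np.ndarray, global_period: int) -> int:
    """Smallest divisor p of the global period with states[t] == states[t+p]."""
    for p in range(1, global_period + 1):
        if global_period % p:
            continue
        if np.array_equal(cyc_states[: global_period - p], cyc_states[p:global_period]):
            return p
    return global_period


def find_in_ice_modules(system: KauffmanSystem, window: Trajectory) -> IceReport:
    """Lakes of activity: weakly connected components of the active nodes.

    Connectivity is taken over the link graph restricted to non-ice nodes
    (undirected, so two interacting lakes count as one). Each module gets
    the period of its nodes' joint state sequence; the global period is the
    lcm of the local ones when that stays under LCM_CAP.
    """
    info = _window_recurrence(window)
    if not info.found:
        raise ValueError(
            "insufficient window: no state recurrence inside it (extend past the transient)"
        )
    report = classify_ice(system, window)
    active = np.flatnonzero(~report.ice_mask)
    if active.size == 0:
        report.global_period = 1
        return report

    # union-find over active-active links
    pos = {int(n): i for i, n in enumerate(active)}
    parent = list(range(active.size))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for tgt in active:
        for src in system.inputs[tgt]:
            j = pos.get(int(src))
            if j is not None:
                a, b = find(pos[int(tgt)]), find(j)
                if a != b:
                    parent[a] = b

    groups: dict[int, list[int]] = {}
    for i, n in enumerate(active):
        groups.setdefault(find(i), []).append(int(n))

    cyc = window.states[info.transient_length : info.transient_length + info.period + 1]
    modules = []
    for nodes in groups.values():
        nodes_arr = np.array(sorted(nodes), dtype=np.int64)
        p = _local_period(cyc[:, nodes_arr], info.period)
        modules.append(IceModule(nodes=nodes_arr, period=p))
    modules.sort(key=lambda m: int(m.nodes[0]))

    g = 1
    for m in modules:
        g = lcm(g, m.period)
        if g > LCM_CAP:
            g = None
            break
    report.modules = modules
    report.global_period = g
    return report


def ice_report(system: KauffmanSystem, state: np.ndarray | None = None, t_cap: int = 1000) -> IceReport:
    """Convenience: find the attractor from `state` and report ice + modules."""
    window, _ = attractor_window(system, state, t_cap)
    return find_in_ice_modules(system, window)
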