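"""Shared fixtures and hand-built reference systems.

The heavy session fixtures (full 1200-process crocodiles at N=400) are
computed once and shared across the damage / evolution / acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import halfchaos as hc


def build_system(N, K, s, inputs, functions, state, topology_type="er", seed=0):
    """Assemble a KauffmanSystem from explicit arrays (for hand-built cases)."""
    spec = hc.NetworkSpec(N=N, K=K, s=s, topology_type=topology_type, seed=seed)
    return hc.KauffmanSystem(
        spec=spec,
        inputs=np.asarray(inputs, dtype=np.int64),
        functions=np.asarray(functions, dtype=np.int64),
        state=np.asarray(state, dtype=np.int64),
    )


def step_oracle(system, state):
    """Independent scalar-loop implementation of the synchronous update."""
    s, K = system.spec.s, system.spec.K
    out = np.empty(system.spec.N, dtype=np.int64)
    for n in range(system.spec.N):
        idx = 0
        for j in range(K):
            idx += int(state[system.inputs[n, j]]) * s**j
        out[n] = system.functions[n, idx]
    return out


def naive_damage_A(base, disturbance, tmx):
    """Twin-run damage oracle: no recurrence shortcut, no extension."""
    disturbed = hc.apply_disturbance(base, disturbance)
    bstate = base.state.copy()
    dstate = base.state.copy()
    A = [0]
    for _ in range(tmx):
        bstate = hc.step(base, bstate)
        dstate = hc.step(disturbed, dstate)
        A.append(int((bstate != dstate).sum()))
    return np.array(A)


def successor_map_attractor(system, state, n_states):
    """Exhaustive oracle: build the successor of every state of the full
    state space, then walk from `state`; returns (transient, period)."""
    N, s = system.spec.N, system.spec.s
    codes = np.arange(n_states)
    digits = (codes[:, None] // s ** np.arange(N)) % s
    pows = s ** np.arange(system.spec.K)
    succ = np.zeros(n_states, dtype=np.int64)
    for n in range(N):
        idx = digits[:, system.inputs[n]] @ pows
        succ += system.functions[n][idx] * s**n
    x = int(np.asarray(state) @ (s ** np.arange(N)))
    seen = {}
    t = 0
    while x not in seen:
        seen[x] = t
        x = int(succ[x])
        t += 1
    return seen[x], t - seen[x]


def two_lakes_system():
    """Hand-built N=10, K=2, s=2 net: period-2 and period-3 lakes in ice.

    Nodes 0-1: mutual NOT (blinker, period 2 from (0,0)). Nodes 2-4: a copy
    ring carrying a single 1-pulse (period 3). Nodes 5-9: constant-0
    functions (always ice). All lake nodes' second input reads frozen node
    9, so the lakes are independent; global period is lcm(2,3) = 6.
    """
    N, K, s = 10, 2, 2
    inputs = np.zeros((N, K), dtype=np.int64)
    functions = np.zeros((N, s**K), dtype=np.int64)
    state = np.zeros(N, dtype=np.int64)
    # NOT of input slot 0: entries indexed little-endian (x0 + 2*x1)
    not0 = [1, 0, 1, 0]
    copy0 = [0, 1, 0, 1]
    inputs[0] = (1, 9)
    functions[0] = not0
    inputs[1] = (0, 9)
    functions[1] = not0
    # copy ring 2 <- 4 <- 3 <- 2
    inputs[2] = (4, 9)
    functions[2] = copy0
    inputs[3] = (2, 9)
    functions[3] = copy0
    inputs[4] = (3, 9)
    functions[4] = copy0
    state[2] = 1  # the pulse
    for n in range(5, N):
        inputs[n] = (0, 1)  # constant function, inputs irrelevant
    return build_system(N, K, s, inputs, functions, state)


@pytest.fixture(scope="session")
def chaotic_system_400():
    spec = hc.NetworkSpec(N=400, K=3, s=4, topology_type="er", seed=11)
    return hc.random_system(spec)


@pytest.fixture(scope="session")
def chaotic_croc_400(chaotic_system_400):
    """Full crocodile of a fully random (chaotic-parameter) net, tmx=1000."""
    return hc.crocodile(chaotic_system_400, tmx=1000)


@pytest.fixture(scope="session")
def pas_system_400():
    spec = hc.NetworkSpec(N=400, K=3, s=4, topology_type="er", seed=7)
    return hc.make_point_attractor(hc.random_system(spec))


@pytest.fixture(scope="session")
def pas_croc_400(pas_system_400):
    """Full crocodile of a point-attractor system, tmx=1000."""
    return hc.crocodile(pas_system_400, tmx=1000)
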