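"""Multi-valued Kauffman networks: topology, function tables, disturbances.

A Kauffman network here is a directed network of ``N`` nodes. Every node has
exactly ``K`` input links (out-degree ``k`` varies) and carries an ``s``-valued
state in ``{0, ..., s-1}``. Each node owns a lookup table of ``s**K`` output
values, one per input tuple, and the whole network is updated synchronously
and deterministically. ``s = 2`` recovers the classical Boolean case.

Three topology families are supported, all with fixed in-degree ``K``:

``er``
    Erdős–Rényi-like: each node's K sources drawn uniformly at random.
``ss``
    single-scale: growth from a (K+1)-clique, new nodes attach uniformly.
``sf``
    scale-free: growth with preferential attachment on out-degree.

A *disturbance* is the elementary perturbation of the damage experiments: a
permanent change of one node's function table at exactly one position — the
input tuple the node observes at t = 0 of the undisturbed run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._rng import substream

__all__ = [
    "NetworkSpec",
    "KauffmanSystem",
    "Disturbance",
    "input_index",
    "encode_inputs",
    "generate_topology",
    "generate_functions",
    "generate_state",
    "random_system",
    "make_point_attractor",
    "enumerate_disturbances",
    "apply_disturbance",
]

TopologyType = Literal["er", "ss", "sf"]


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable generation parameters of a network ensemble member.

    Parameters
    ----------
    N : int
        Number of nodes (>= 2).
    K : int
        In-degree, identical for every node (>= 1). Requires N > K so that
        K distinct non-self sources exist.
    s : int
        Number of equally probable signal variants (>= 2).
    topology_type : {"er", "ss", "sf"}
        Wiring family, see module docstring.
    seed : int
        Global seed; expanded into named substreams for topology, functions
        and initial state.
    """

    N: int
    K: int
    s: int
    topology_type: TopologyType = "er"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.s < 2:
            raise ValueError(f"s must be >= 2, got {self.s}")
        if self.N <= self.K:
            raise ValueError(f"need N > K for K distinct non-self sources (N={self.N}, K={self.K})")
        if self.topology_type not in ("er", "ss", "sf"):
            raise ValueError(f"unknown topology_type {self.topology_type!r}")

    @property
    def n_table_entries(self) -> int:
        """Lookup-table length per node, s**K."""
        return self.s**self.K


@dataclass
class KauffmanSystem:
    """A concrete network: wiring + function tables + current initial state.

    Attributes
    ----------
    spec : NetworkSpec
    inputs : (N, K) int array
        ``inputs[n, j]`` is the source node feeding input slot j of node n.
        Slots are ordered; slot 0 is the least significant digit of the
        table address (little-endian encoding).
    functions : (N, s**K) int array
        ``functions[n, a]`` is node n's output for encoded input tuple a.
    state : (N,) int array
        The initial (t = 0) network state.
    """

    spec: NetworkSpec
    inputs: np.ndarray
    functions: np.ndarray
    state: np.ndarray

    def __post_init__(self) -> None:
        N, K, s = self.spec.N, self.spec.K, self.spec.s
        self.inputs = np.asarray(self.inputs, dtype=np.int64)
        self.functions = np.asarray(self.functions, dtype=np.int64)
        self.state = np.asarray(self.state, dtype=np.int64)
        if self.inputs.shape != (N, K):
            raise ValueError(f"inputs shape {self.inputs.shape} != {(N, K)}")
        if self.functions.shape != (N, s**K):
            raise ValueError(f"functions shape {self.functions.shape} != {(N, s**K)}")
        if self.state.shape != (N,):
            raise ValueError(f"state shape {self.state.shape} != {(N,)}")
        if (self.inputs < 0).any() or (self.inputs >= N).any():
            raise ValueError("input source index out of range")
        if (self.functions < 0).any() or (self.functions >= s).any():
            raise ValueError("function table entry out of range [0, s-1]")
        if (self.state < 0).any() or (self.state >= s).any():
            raise ValueError("state value out of range [0, s-1]")

    def copy(self) -> "KauffmanSystem":
        return KauffmanSystem(
            spec=self.spec,
            inputs=self.inputs.copy(),
            functions=self.functions.copy(),
            state=self.state.copy(),
        )

    def with_state(self, state: np.ndarray) -> "KauffmanSystem":
        return KauffmanSystem(self.spec, self.inputs, self.functions, np.asarray(state))

    def out_degrees(self) -> np.ndarray:
        """Out-degree k of every node (number of input slots it feeds)."""
        return np.bincount(self.inputs.ravel(), minlength=self.spec.N)

    def equal(self, other: "KauffmanSystem") -> bool:
        return (
            self.spec == other.spec
            and np.array_equal(self.inputs, other.inputs)
            and np.array_equal(self.functions, other.functions)
            and np.array_equal(self.state, other.state)
        )


@dataclass(frozen=True)
class Disturbance:
    """A permanent one-entry function change.

    ``input_index`` is always the encoding of the node's input tuple at t = 0
    of the undisturbed trajectory, so the changed entry is guaranteed to be
    addressed at the first step.
    """

    node: int
    input_index: int
    new_output: int


def input_index(input_tuple, s: int) -> int:
    """Encode an ordered K-tuple of signal values as a table address.

    Little-endian positional encoding: slot 0 is the least significant digit,
    so the address is sum_j x_j * s**j. Bijective over [0, s**K - 1].
    """
    idx = 0
    for j, x in enumerate(input_tuple):
        x = int(x)
        if not 0 <= x < s:
            raise ValueError(f"signal value {x} out of range [0, {s - 1}]")
        idx += x * s**j
    return idx


def encode_inputs(state: np.ndarray, inputs: np.ndarray, s: int) -> np.ndarray:
    """Vectorized `input_index` for every node given a network state."""
    K = inputs.shape[1]
    pows = s ** np.arange(K)
    return state[inputs] @ pows


def _growth_topology(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """ss/sf growth: seed (K+1)-clique, then attach nodes one at a time.

    sf uses preferential attachment with weight (out-degree + 1); the +1
    smoothing keeps zero-out-degree nodes reachable. Node identities are
    randomly permuted afterwards so growth order leaves no positional trace.
    """
    N, K = spec.N, spec.K
    inputs = np.empty((N, K), dtype=np.int64)
    out_deg = np.zeros(N, dtype=np.int64)
    # seed clique: each of the first K+1 nodes takes all K others as inputs
    for n in range(K + 1):
        src = [m for m in range(K + 1) if m != n]
        inputs[n] = src
        out_deg[src] += 1
    for n in range(K + 1, N):
        if spec.topology_type == "ss":
            src = rng.choice(n, size=K, replace=False)
        else:  # sf
            w = out_deg[:n] + 1.0
            src = rng.choice(n, size=K, replace=False, p=w / w.sum())
        inputs[n] = src
        out_deg[src] += 1
    perm = rng.permutation(N)
    relabeled = np.empty((N, K), dtype=np.int64)
    relabeled[perm] = perm[inputs]
    return relabeled


def generate_topology(spec: NetworkSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a wiring with fixed in-degree K; returns the (N, K) inputs array.

    Self-links and duplicate links are never produced. Total directed links
    is exactly K*N for every family.
    """
    if rng is None:
        rng = substream(spec.seed, "topology")
    N, K = spec.N, spec.K
    if spec.topology_type == "er":
        inputs = np.empty((N, K), dtype=np.int64)
        for n in range(N):
            src = rng.choice(N - 1, size=K, replace=False)
            src[src >= n] += 1  # skip self
            inputs[n] = src
        return inputs
    return _growth_topology(spec, rng)


def generate_functions(spec: NetworkSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform i.i.d. function tables: (N, s**K) entries in [0, s-1]."""
    if rng is None:
        rng = substream(spec.seed, "functions")
    return rng.integers(0, spec.s, size=(spec.N, spec.n_table_entries), dtype=np.int64)


def generate_state(spec: NetworkSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random initial state."""
    if rng is None:
        rng = substream(spec.seed, "state")
    return rng.integers(0, spec.s, size=spec.N, dtype=np.int64)


def random_system(spec: NetworkSpec) -> KauffmanSystem:
    """Fully random system: topology, functions and initial state from
    named substreams of ``spec.seed``."""
    return KauffmanSystem(
        spec=spec,
        inputs=generate_topology(spec),
        functions=generate_functions(spec),
        state=generate_state(spec),
    )


def make_point_attractor(system: KauffmanSystem) -> KauffmanSystem:
    """Turn the initial state into a fixed point (a PAS).

    For every node, the single table entry addressed by the node's input
    tuple under the initial state is overwritten with the node's own initial
    state value. All other entries keep their random values, so no other
    statistically controlled parameter deviates from randomness.
    """
    sys2 = system.copy()
    idx = encode_inputs(sys2.state, sys2.inputs, sys2.spec.s)
    sys2.functions[np.arange(sys2.spec.N), idx] = sys2.state
    return sys2


def observed_indices(system: KauffmanSystem) -> np.ndarray:
    """Encoded input tuple of each node at t = 0 (the disturbable addresses)."""
    return encode_inputs(system.state, system.inputs, system.spec.s)


def enumerate_disturbances(system: KauffmanSystem) -> list[Disturbance]:
    """The complete disturbance set: N*(s-1) one-entry changes.

    For each node, each of the s-1 values different from the current output
    at the node's t = 0 input tuple.
    """
    s = system.spec.s
    idx = observed_indices(system)
    out = []
    for n in range(system.spec.N):
        cur = int(system.functions[n, idx[n]])
        for v in range(s):
            if v != cur:
                out.append(Disturbance(node=n, input_index=int(idx[n]), new_output=v))
    return out


def random_disturbance(system: KauffmanSystem, rng: np.random.Generator) -> Disturbance:
    """One disturbance drawn uniformly from the complete set (without
    materializing it)."""
    n = int(rng.integers(system.spec.N))
    idx = int(encode_inputs(system.state, system.inputs, system.spec.s)[n])
    cur = int(system.functions[n, idx])
    v = int(rng.integers(system.spec.s - 1))
    if v >= cur:
        v += 1
    return Disturbance(node=n, input_index=idx, new_output=v)


def apply_disturbance(system: KauffmanSystem, d: Disturbance) -> KauffmanSystem:
    """Return a twin system differing in exactly one table entry.

    The original is left untouched (damage experiments compare the twins).
    """
    cur = int(system.functions[d.node, d.input_index])
    if d.new_output == cur:
        raise ValueError(
            f"invalid disturbance: new_output {d.new_output} equals current entry at "
            f"node {d.node}, input_index {d.input_index}"
        )
    if not 0 <= d.new_output < system.spec.s:
        raise ValueError(f"new_output {d.new_output} out of range [0, {system.spec.s - 1}]")
    sys2 = system.copy()
    sys2.functions[d.node, d.input_index] = d.new_output
    return sys2
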