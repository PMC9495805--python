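"""Stability-enhancement operators for chaotic-parameter networks.

Four families of interventions that raise post-disturbance order without
touching N, K or s:

* **Feedback conversion** — census the short directed cycles, sign each by
  the influence signs of its links, and convert positive loops to negative
  by inverting one link (recomposing the target's function with the value
  reversal x -> s-1-x on that input slot). The recursive variant repeats
  the census-and-convert pass until no positive short loops remain.
* **PAS regulation** — for a point-attractor system, redirect input tuples
  near the observed (PAS) tuple back to the node's frozen state, a pull-back
  regulation of strength a (all distance-1 tuples), b (one random
  distance-1 tuple) or c (none).
* **Function narrowing** — iteratively bias each node's table toward its
  most common output value, raising internal homogeneity P (the frequency
  of the modal output; P = 1/s is unbiased, P = 1 is a constant function).
* **Modular construction** — wire the network as equal modules with a
  controlled fraction of inter-module links.

Conversion, regulation and narrowing change only function tables, never the
wiring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

from ._rng import substream
from .dynamics import step
from .network import KauffmanSystem, NetworkSpec, generate_functions, generate_state, generate_topology

__all__ = [
    "LoopRecord",
    "link_influence_sign",
    "find_feedback_loops",
    "convert_positive_to_negative",
    "add_pas_regulation",
    "internal_homogeneity",
    "narrow_functions",
    "build_modular_network",
]

SIGN_CORR_THRESHOLD = 0.1


@dataclass
class LoopRecord:
    """A simple directed cycle with per-link influence signs.

    `sign` is the product of the nonzero link signs: "+", "-", or
    "indeterminate" when every link sign is 0.
    """

    cycle: tuple[int, ...]  # node sequence, starts at the smallest node id
    link_signs: tuple[int, ...]  # sign of link cycle[i] -> cycle[(i+1) % len]
    sign: str


def _input_slot(system: KauffmanSystem, source: int, target: int) -> int:
    slots = np.flatnonzero(system.inputs[target] == source)
    if slots.size == 0:
        raise ValueError(f"no link {source} -> {target}")
    return int(slots[0])


def _slot_digits(n_entries: int, slot: int, s: int) -> np.ndarray:
    """Value of input digit `slot` for every encoded table address."""
    return (np.arange(n_entries) // s**slot) % s


def link_influence_sign(system: KauffmanSystem, source: int, target: int) -> int:
    """Influence sign of a link, in {-1, 0, +1}.

    Spearman rank correlation between the value on the input slot and the
    target's output over all s**K table entries; 0 when |rho| < 0.1 (or the
    output is constant). At s = 2 this reduces to the Boolean convention
    (activating / inhibiting / irrelevant input).
    """
    slot = _input_slot(system, source, target)
    s = system.spec.s
    x = _slot_digits(system.spec.n_table_entries, slot, s)
    y = system.functions[target]
    if (y == y[0]).all() or (x == x[0]).all():
        return 0
    rho = spearmanr(x, y).statistic
    if np.isnan(rho) or abs(rho) < SIGN_CORR_THRESHOLD:
        return 0
    return 1 if rho > 0 else -1


def topology_digraph(system: KauffmanSystem) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(system.spec.N))
    for tgt in range(system.spec.N):
        for src in system.inputs[tgt]:
            g.add_edge(int(src), int(tgt))
    return g


def find_feedback_loops(system: KauffmanSystem, max_len: int = 3) -> list[LoopRecord]:
    """All simple directed cycles of length <= max_len, signed.

    Deterministic ordering: each cycle is rotated to start at its smallest
    node, and records are sorted by (length, node sequence).
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2 (self-loops are excluded by topology)")
    g = topology_digraph(system)
    records = []
    sign_cache: dict[tuple[int, int], int] = {}

    def cached_sign(src: int, tgt: int) -> int:
        key = (src, tgt)
        if key not in sign_cache:
            sign_cache[key] = link_influence_sign(system, src, tgt)
        return sign_cache[key]

    for cyc in nx.simple_cycles(g, length_bound=max_len):
        i0 = int(np.argmin(cyc))
        cyc = tuple(cyc[i0:] + cyc[:i0])
        signs = tuple(cached_sign(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc)))
        nonzero = [x for x in signs if x != 0]
        if not nonzero:
            sign = "indeterminate"
        else:
            sign = "+" if int(np.prod(nonzero)) > 0 else "-"
        records.append(LoopRecord(cycle=cyc, link_signs=signs, sign=sign))
    records.sort(key=lambda r: (len(r.cycle), r.cycle))
    return records


def invert_link(system: KauffmanSystem, source: int, target: int) -> KauffmanSystem:
    """Recompose the target's function with x -> s-1-x on the link's slot.

    f'(..., x_j, ...) = f(..., s-1-x_j, ...): a pure permutation of the
    table, so the output-value multiset (and hence homogeneity) is
    unchanged — inversion never narrows functions.
    """
    slot = _input_slot(system, source, target)
    s = system.spec.s
    n = system.spec.n_table_entries
    digits = _slot_digits(n, slot, s)
    permuted = np.arange(n) + (s - 1 - 2 * digits) * s**slot
    sys2 = system.copy()
    sys2.functions[target] = system.functions[target][permuted]
    return sys2


def convert_positive_to_negative(
    system: KauffmanSystem,
    max_len: int = 3,
    recursive: bool = False,
    max_passes: int = 10,
) -> tuple[KauffmanSystem, dict]:
    """Convert positive short feedback loops to negative ones.

    One pass: census the loops, and for each positive loop invert its
    lexicographically smallest link (each distinct link at most once per
    pass). The recursive variant repeats passes until no positive loop of
    length <= max_len remains or `max_passes` is hit; the returned info dict
    reports passes used and positive loops remaining (with a warning flag
    when the cap was hit).
    """
    current = system
    passes = 0
    while True:
        loops = find_feedback_loops(current, max_len)
        positive = [r for r in loops if r.sign == "+"]
        if not positive or passes >= (max_passes if recursive else 1):
            break
        to_invert = set()
        for rec in positive:
            links = [
                (rec.cycle[i], rec.cycle[(i + 1) % len(rec.cycle)]) for i in range(len(rec.cycle))
            ]
            to_invert.add(min(links))
        for src, tgt in sorted(to_invert):
            current = invert_link(current, src, tgt)
        passes += 1
        if not recursive:
            loops = find_feedback_loops(current, max_len)
            positive = [r for r in loops if r.sign == "+"]
            break
    info = {
        "passes": passes,
        "positive_remaining": len(positive),
        "warning": recursive and len(positive) > 0,
    }
    return current, info


def add_pas_regulation(
    system: KauffmanSystem,
    level: Literal["a", "b", "c"],
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> KauffmanSystem:
    """Feedback regulation pulling states back toward the point attractor.

    For each node, input tuples at Hamming distance 1 from the node's PAS
    input tuple are redirected to output the node's PAS state: level "a"
    redirects all K(s-1) of them (strong regulation), "b" one uniformly
    chosen tuple per node (small regulation), "c" none. The PAS entry
    itself is never touched, so the point attractor is preserved exactly.
    Requires a PAS input.
    """
    if level not in ("a", "b", "c"):
        raise ValueError(f"regulation level must be 'a', 'b' or 'c', got {level!r}")
    if not np.array_equal(step(system, system.state), system.state):
        raise ValueError("add_pas_regulation requires a point-attractor system (PAS)")
    if level == "c":
        return system.copy()
    if rng is None:
        rng = substream(seed, "regulation")
    s, K = system.spec.s, system.spec.K
    sys2 = system.copy()
    from .network import observed_indices

    pas_idx = observed_indices(system)
    for node in range(system.spec.N):
        base = int(pas_idx[node])
        neighbors = []
        for slot in range(K):
            cur = (base // s**slot) % s
            for v in range(s):
                if v != cur:
                    neighbors.append(base + (v - cur) * s**slot)
        if level == "b":
            neighbors = [neighbors[int(rng.integers(len(neighbors)))]]
        sys2.functions[node, neighbors] = system.state[node]
    return sys2


def internal_homogeneity(system: KauffmanSystem) -> tuple[np.ndarray, float]:
    """Per-node P (frequency of the modal output value) and the network mean."""
    s = system.spec.s
    counts = np.stack([(system.functions == v).sum(axis=1) for v in range(s)])
    P = counts.max(axis=0) / system.spec.n_table_entries
    return P, float(P.mean())


def narrow_functions(
    system: KauffmanSystem,
    target_P: float,
    iterations: int = 50,
    frac_per_iter: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[KauffmanSystem, dict]:
    """Iterative function narrowing toward mean homogeneity >= target_P.

    Each iteration redirects, per node, a random `frac_per_iter` share of
    table entries to the node's current modal output value. P never
    decreases across iterations. Returns (system, info) with a warning flag
    when the target was unreachable within `iterations`.
    """
    if not 1.0 / system.spec.s < target_P <= 1.0:
        raise ValueError(f"target_P must lie in (1/s, 1], got {target_P}")
    if rng is None:
        rng = substream(seed, "narrowing")
    sys2 = system.copy()
    n = system.spec.n_table_entries
    k = max(1, int(round(frac_per_iter * n)))
    _, mean_P = internal_homogeneity(sys2)
    it = 0
    while mean_P < target_P and it < iterations:
        for node in range(system.spec.N):
            tbl = sys2.functions[node]
            modal = int(np.bincount(tbl, minlength=system.spec.s).argmax())
            pick = rng.choice(n, size=k, replace=False)
            tbl[pick] = modal
        _, mean_P = internal_homogeneity(sys2)
        it += 1
    info = {"iterations": it, "mean_P": mean_P, "warning": mean_P < target_P}
    return sys2, info


def build_modular_network(
    spec: NetworkSpec, n_modules: int, inter_frac: float
) -> KauffmanSystem:
    """A random system wired as equal modules with tunable coupling.

    N must be divisible by n_modules. Each module's internal wiring follows
    spec.topology_type on the module's nodes; then each link is
    independently rewired with probability `inter_frac` to a uniformly
    random source in a different module. Functions and initial state are
    fully random.
    """
    if spec.N % n_modules:
        raise ValueError(f"N={spec.N} not divisible by n_modules={n_modules}")
    if not 0.0 <= inter_frac <= 1.0:
        raise ValueError("inter_frac must lie in [0, 1]")
    m = spec.N // n_modules
    if m <= spec.K:
        raise ValueError(f"module size {m} must exceed K={spec.K}")
    rng = substream(spec.seed, "modular-topology")
    inputs = np.empty((spec.N, spec.K), dtype=np.int64)
    sub_spec_base = NetworkSpec(N=m, K=spec.K, s=spec.s, topology_type=spec.topology_type, seed=0)
    for mod in range(n_modules):
        sub = generate_topology(sub_spec_base, rng)
        inputs[mod * m : (mod + 1) * m] = sub + mod * m
    # rewire a Bernoulli(inter_frac) subset of links across modules
    for node in range(spec.N):
        mod = node // m
        for slot in range(spec.K):
            if rng.random() < inter_frac:
                while True:
                    src = int(rng.integers(spec.N))
                    if src // m != mod and src not in inputs[node]:
                        inputs[node, slot] = src
                        break
    return KauffmanSystem(
        spec=spec,
        inputs=inputs,
        functions=generate_functions(spec, substream(spec.seed, "modular-functions")),
        state=generate_state(spec, substream(spec.seed, "modular-state")),
    )
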