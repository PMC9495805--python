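"""Annealed (Derrida) approximation of damage spreading.

In the annealed picture the network is redrawn every step, so damage
propagates as a branching-style map on the damage fraction d. A node's
output changes when at least one of its K inputs is damaged — probability
1 - (1-d)**K — and its freshly random output then differs from the
undisturbed one with probability (s-1)/s:

    d_{t+1} = (1 - (1 - d_t)**K) * (s - 1) / s

Its slope at d = 0 is the damage-propagation coefficient

    w = K (s - 1) / s,

which plays the role of a Lyapunov exponent: w > 1 means chaotic
parameters. For w > 1 the map has a nonzero stable fixed point d* — the
*chaotic Derrida equilibrium* — where avalanches saturate; it also marks the
right-peak maximum of P(d) for fully random quenched networks. At w <= 1
(edge of chaos: s = 2, K = 2 gives exactly w = 1) only d = 0 remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AnnealedParams",
    "damage_coefficient",
    "derrida_step",
    "derrida_equilibrium",
    "annealed_damage_mc",
]


def _check_sk(s: int, K: int) -> None:
    if s < 2:
        raise ValueError(f"s must be >= 2, got {s}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")


def damage_coefficient(s: int, K: int) -> float:
    """w = K(s-1)/s, the expected one-step damage multiplication."""
    _check_sk(s, K)
    return K * (s - 1) / s


def derrida_step(d, s: int, K: int):
    """One application of the annealed damage map (vectorized in d)."""
    _check_sk(s, K)
    d = np.asarray(d, dtype=float)
    if (d < 0).any() or (d > 1).any():
        raise ValueError("damage fraction d must lie in [0, 1]")
    out = (1.0 - (1.0 - d) ** K) * (s - 1) / s
    return float(out) if out.ndim == 0 else out


def derrida_equilibrium(s: int, K: int, tol: float = 1e-12) -> float:
    """The chaotic Derrida equilibrium d*.

    Largest fixed point of the map in [0, 1]; 0 when w <= 1 (no chaotic
    equilibrium at or below the edge of chaos). Found by bracketed root
    solving from the right, since d = 0 is always a fixed point.
    """
    _check_sk(s, K)
    if damage_coefficient(s, K) <= 1.0:
        return 0.0

    def g(d: float) -> float:
        return derrida_step(d, s, K) - d

    # g > 0 just above 0 when w > 1, and g(1) = (s-1)/s - 1 < 0
    lo = 1e-9
    while g(lo) <= 0:  # pragma: no cover - w>1 guarantees positivity near 0
        lo *= 10
    return float(brentq(g, lo, 1.0, xtol=tol))


def annealed_damage_mc(
    d: float, s: int, K: int, n_trials: int = 100_000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Monte-Carlo annealed model: mechanical oracle for `derrida_step`.

    Each trial: K inputs independently damaged with probability d; if any is
    damaged, the node's output is redrawn uniformly (old and new outputs
    both uniform on [0, s-1]) and the trial counts as damaged when they
    differ. Returns (estimate, standard error).
    """
    _check_sk(s, K)
    if rng is None:
        rng = np.random.default_rng()
    any_hit = (rng.random((n_trials, K)) < d).any(axis=1)
    old = rng.integers(0, s, size=n_trials)
    new = rng.integers(0, s, size=n_trials)
    damaged = any_hit & (old != new)
    p = damaged.mean()
    se = float(np.sqrt(p * (1 - p) / n_trials))
    return float(p), se


@dataclass(frozen=True)
class AnnealedParams:
    """(s, K) with the derived coefficient w and equilibrium d*."""

    s: int
    K: int
    w: float
    d_star: float

    @classmethod
    def from_sk(cls, s: int, K: int) -> "AnnealedParams":
        return cls(s=s, K=K, w=damage_coefficient(s, K), d_star=derrida_equilibrium(s, K))
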