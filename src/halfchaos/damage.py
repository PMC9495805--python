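"""Twin-system damage propagation: A(t) series, crocodiles, P(d), regimes.

The damage experiment runs two copies of a network from the same initial
state: the original, and a twin whose function table differs in exactly one
entry (the entry addressed at t = 0). ``A(t)`` counts the nodes whose states
differ at time t; ``d(t) = A(t)/N``. The *crocodile* is the complete
ensemble of A(t) over all N(s-1) available disturbances of one network,
together with ``q(t)`` — the fraction of processes whose damage is still
small at time t.

The joint (base state, disturbed state) pair evolves deterministically, so
once a pair state recurs the whole future of A(t) is an exact periodic
extension; this also captures *secondary initiations* (damage re-ignited by
the permanent change later in the run) exactly. Runs whose pair never recurs
within tmx are reported raw with ``recurrence.found = False``.

The damage-size distribution P(d) at tmx has, for a half-chaotic network,
two peaks — small (ordered) and large (chaotic, at the Derrida equilibrium)
— separated by an empty gap; fully random networks show a single peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import AttractorInfo, step
from .network import Disturbance, KauffmanSystem, apply_disturbance, enumerate_disturbances

__all__ = [
    "DamageSeries",
    "CrocodileResult",
    "DamageDistribution",
    "damage_run",
    "crocodile",
    "damage_distribution",
    "classify_regime",
]

#: Small-avalanche threshold (the A < 150 convention at N = 400), kept as a
#: fraction of N so it transfers to other sizes.
DEFAULT_THRESHOLD_FRAC = 0.375

#: Minimal width of the empty band around the small-damage threshold for a
#: distribution to count as gapped (see `damage_distribution`).
MIN_GAP_WIDTH = 0.05


@dataclass
class DamageSeries:
    """A(t) of one disturbance process.

    Attributes
    ----------
    A : int array
        Damage sizes A(0..t_last); A(0) = 0 always (the change is in the
        function, not in the state). When the pair recurred before tmx the
        series is extended periodically to tmx, so len(A) == tmx + 1 unless
        the run was truncated by `stop_at_explosion`.
    exploded_at : int or None
        First t with A(t) >= threshold.
    recurrence : AttractorInfo
        Transient/period of the joint (base, disturbed) pair process.
    """

    disturbance: Disturbance
    A: np.ndarray
    d_final: float
    exploded_at: int | None
    recurrence: AttractorInfo
    truncated: bool = False


@dataclass
class CrocodileResult:
    """Complete disturbance ensemble of one network."""

    series: list[DamageSeries]
    q: np.ndarray  # q[t], t = 0..tmx
    N: int
    K: int
    s: int
    tmx: int
    threshold: int  # absolute A threshold used


@dataclass
class DamageDistribution:
    """P(d) at a fixed time, with peak/gap decomposition.

    d values are exact counts A/N (bin width 1/N), so an empty gap is
    literal, not a binning artifact. The gap band is the maximal run of
    unoccupied d values containing the small-damage threshold; it is
    reported as [g_lo, g_hi] with g_lo the largest occupied d below and
    g_hi the smallest occupied d above (NaN bounds when one side is empty).
    """

    d_values: np.ndarray
    masses: np.ndarray
    d_threshold: float
    left_mass: float
    right_mass: float
    left_mode: float
    right_mode: float
    gap_lo: float
    gap_hi: float

    @property
    def gap_width(self) -> float:
        if np.isnan(self.gap_lo) or np.isnan(self.gap_hi):
            return 0.0
        return self.gap_hi - self.gap_lo

    @property
    def gap_empty(self) -> bool:
        """True when no mass sits strictly between the two peaks' inner edges."""
        return self.gap_width > 0.0


def _fast_arrays(system: KauffmanSystem):
    """Precomputed pieces of the update rule for tight loops."""
    s, K, N = system.spec.s, system.spec.K, system.spec.N
    pows = s ** np.arange(K)
    flat = system.functions.ravel()
    offs = np.arange(N) * system.spec.n_table_entries
    return system.inputs, pows, flat, offs


def _base_trajectory(system: KauffmanSystem, tmx: int) -> np.ndarray:
    inputs, pows, flat, offs = _fast_arrays(system)
    states = np.empty((tmx + 1, system.spec.N), dtype=np.int64)
    states[0] = system.state
    st = states[0]
    for t in range(tmx):
        st = flat[offs + st[inputs] @ pows]
        states[t + 1] = st
    return states


def damage_run(
    base: KauffmanSystem,
    disturbance: Disturbance,
    tmx: int = 1000,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    base_traj: np.ndarray | None = None,
    stop_at_explosion: bool = False,
) -> DamageSeries:
    """Run one twin-system damage process up to tmx.

    Parameters
    ----------
    base_traj : optional precomputed undisturbed trajectory (tmx+1, N);
        pass it when running many disturbances of the same base.
    stop_at_explosion : if True, stop as soon as A(t) reaches the threshold
        and return a truncated series (used by evolutionary runs that only
        need the accept/reject verdict; explosions never fall back below
        the threshold in practice, see the q(t) definition).
    """
    if tmx < 1:
        raise ValueError("tmx must be >= 1")
    N = base.spec.N
    threshold = int(np.ceil(threshold_frac * N))
    disturbed = apply_disturbance(base, disturbance)
    if base_traj is None:
        base_traj = _base_trajectory(base, tmx)

    A = np.empty(tmx + 1, dtype=np.int64)
    A[0] = 0
    dstate = base.state.copy()
    seen: dict[bytes, int] = {dstate.tobytes() + base_traj[0].tobytes(): 0}
    exploded_at: int | None = None
    recurrence = AttractorInfo(found=False)
    inputs, pows, flat, offs = _fast_arrays(disturbed)

    for t in range(1, tmx + 1):
        dstate = flat[offs + dstate[inputs] @ pows]
        a = int((dstate != base_traj[t]).sum())
        A[t] = a
        if exploded_at is None and a >= threshold:
            exploded_at = t
            if stop_at_explosion:
                return DamageSeries(
                    disturbance, A[: t + 1].copy(), a / N, exploded_at, recurrence, truncated=True
                )
        key = dstate.tobytes() + base_traj[t].tobytes()
        t0 = seen.get(key)
        if t0 is not None:
            recurrence = AttractorInfo(found=True, transient_length=t0, period=t - t0)
            if t < tmx:  # extend A periodically over the pair cycle
                cycle = A[t0:t].copy()
                A[t0:] = np.resize(cycle, tmx + 1 - t0)
            if exploded_at is None:
                over = np.flatnonzero(A >= threshold)
                exploded_at = int(over[0]) if over.size else None
            break
        seen[key] = t

    return DamageSeries(disturbance, A, float(A[tmx]) / N, exploded_at, recurrence)


def crocodile(
    system: KauffmanSystem,
    tmx: int = 1000,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> CrocodileResult:
    """Run the complete disturbance set and compute q(t).

    q(t) is the fraction of the N(s-1) processes with A(t) < threshold
    (instantaneous criterion; explosions are one-way in practice so this
    coincides with "still ordered").
    """
    spec = system.spec
    threshold = int(np.ceil(threshold_frac * spec.N))
    base_traj = _base_trajectory(system, tmx)
    series = [
        damage_run(system, d, tmx, threshold_frac, base_traj=base_traj)
        for d in enumerate_disturbances(system)
    ]
    A_mat = np.stack([s.A for s in series])
    q = (A_mat < threshold).mean(axis=0)
    return CrocodileResult(
        series=series, q=q, N=spec.N, K=spec.K, s=spec.s, tmx=tmx, threshold=threshold
    )


def damage_distribution(result: CrocodileResult, at_t: int | None = None) -> DamageDistribution:
    """Histogram of d at time `at_t` (default tmx), with peaks and gap.

    Left peak = mass at d < threshold/N, right peak = mass at or above;
    modes are the most frequent exact d value on each side. The gap band is
    the open interval between the largest occupied d below the threshold
    and the smallest occupied d above it.
    """
    if not result.series:
        raise ValueError("empty crocodile result")
    if at_t is None:
        at_t = result.tmx
    if at_t > result.tmx:
        raise ValueError(f"at_t={at_t} beyond tmx={result.tmx}")
    N = result.N
    counts = np.bincount([int(s.A[at_t]) for s in result.series], minlength=N + 1)
    masses = counts / counts.sum()
    d_values = np.arange(N + 1) / N
    d_thr = result.threshold / N

    left = d_values < d_thr
    left_mass = float(masses[left].sum())
    right_mass = float(masses[~left].sum())
    left_mode = float(d_values[left][np.argmax(masses[left])]) if left_mass > 0 else float("nan")
    right_mode = (
        float(d_values[~left][np.argmax(masses[~left])]) if right_mass > 0 else float("nan")
    )
    occ = d_values[masses > 0]
    below = occ[occ < d_thr]
    above = occ[occ >= d_thr]
    gap_lo = float(below.max()) if below.size else float("nan")
    gap_hi = float(above.min()) if above.size else float("nan")
    return DamageDistribution(
        d_values=d_values,
        masses=masses,
        d_threshold=d_thr,
        left_mass=left_mass,
        right_mass=right_mass,
        left_mode=left_mode,
        right_mode=right_mode,
        gap_lo=gap_lo,
        gap_hi=gap_hi,
    )


def classify_regime(
    dist: DamageDistribution,
    eps: float = 0.05,
    min_gap_width: float = MIN_GAP_WIDTH,
) -> str:
    """Classify a P(d) as ordered / chaotic / half_chaotic / indeterminate.

    ordered: right mass < eps; chaotic: left mass < eps; half_chaotic: both
    masses >= eps and the empty band between the peaks is at least
    `min_gap_width` wide (the two-peaks-with-a-gap signature); anything else
    is indeterminate.
    """
    if dist.right_mass < eps:
        return "ordered"
    if dist.left_mass < eps:
        return "chaotic"
    if dist.gap_width >= min_gap_width:
        return "half_chaotic"
    return "indeterminate"
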