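"""PAS-seeded evolution that produces and maintains half-chaos.

Starting from a point-attractor system (PAS), disturbances are drawn
uniformly from the complete one-entry set and the resulting damage is
measured against the small-avalanche threshold. A change is *accepted* as an
evolutionary change when the final damage stays in the left peak (below the
threshold); the disturbed system then becomes the new base and further
disturbances act on it. Most small-damage outcomes of a PAS are again PAS,
so to move the system to a more natural regime with short (but not point)
attractors, an anti-PAS rule additionally rejects accepted candidates whose
attractor period is below ``min_attractor`` (default 7: attractors smaller
than seven are not accepted).

The evolved systems stay half-chaotic (evolutionary stability): damage
distributions keep both peaks with an empty gap, and the activity organizes
into a few in-ice modules ("lakes") whose local attractors compose the
global one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .damage import (
    DEFAULT_THRESHOLD_FRAC,
    CrocodileResult,
    DamageDistribution,
    classify_regime,
    crocodile,
    damage_distribution,
    damage_run,
    _base_trajectory,
)
from .dynamics import IceReport, find_attractor, ice_report
from .network import Disturbance, KauffmanSystem, apply_disturbance, random_disturbance

__all__ = [
    "EvolutionConfig",
    "TrialRecord",
    "EvolutionLog",
    "HalfChaosReport",
    "evolve",
    "check_half_chaos",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of one evolutionary run.

    min_attractor = 1 disables the anti-PAS rule (pure small-damage
    acceptance). An attractor not found within `attractor_cap` counts as
    long enough (a long attractor is not "too small") and is logged as
    period = None. trial_cap defaults to 50 * n_accepts.
    """

    n_accepts: int = 20
    tmx: int = 1000
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    min_attractor: int = 7
    attractor_cap: int = 1000
    trial_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_attractor < 1:
            raise ValueError("min_attractor must be >= 1")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must lie in (0, 1)")

    @property
    def effective_trial_cap(self) -> int:
        return self.trial_cap if self.trial_cap is not None else 50 * self.n_accepts


@dataclass
class TrialRecord:
    trial: int
    disturbance: Disturbance
    d_final: float
    period: int | None  # None = not checked or not found within cap
    accepted: bool
    reason: str  # "accepted" | "damage" | "attractor"


@dataclass
class EvolutionLog:
    trials: list[TrialRecord] = field(default_factory=list)
    n_accepted: int = 0
    completed: bool = False
    warning: str | None = None

    @property
    def accepted_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.accepted]


def evolve(system: KauffmanSystem, config: EvolutionConfig) -> tuple[KauffmanSystem, EvolutionLog]:
    """Iterated accept/reject evolution from a PAS (or half-chaotic) base.

    The initial state is kept fixed across accepted changes, so the
    disturbance set is always defined at the same t = 0 state. Stops after
    `config.n_accepts` acceptances or `effective_trial_cap` trials
    (returning a partial log with a warning in the latter case).

    Damage runs are truncated at the first explosion: a process whose
    damage reaches the threshold is rejected immediately (explosions do not
    return below the threshold; the accept decision only needs the verdict).
    """
    rng = substream(config.seed, "evolution")
    current = system
    base_traj = _base_trajectory(current, config.tmx)
    log = EvolutionLog()

    for trial in range(config.effective_trial_cap):
        if log.n_accepted >= config.n_accepts:
            break
        d = random_disturbance(current, rng)
        series = damage_run(
            current,
            d,
            tmx=config.tmx,
            threshold_frac=config.threshold_frac,
            base_traj=base_traj,
            stop_at_explosion=True,
        )
        if series.exploded_at is not None or series.d_final >= config.threshold_frac:
            log.trials.append(TrialRecord(trial, d, series.d_final, None, False, "damage"))
            continue
        candidate = apply_disturbance(current, d)
        period: int | None = None
        if config.min_attractor > 1:
            info = find_attractor(candidate, candidate.state, config.attractor_cap)
            period = info.period if info.found else None
            if info.found and info.period < config.min_attractor:
                log.trials.append(TrialRecord(trial, d, series.d_final, period, False, "attractor"))
                continue
        log.trials.append(TrialRecord(trial, d, series.d_final, period, True, "accepted"))
        log.n_accepted += 1
        current = candidate
        base_traj = _base_trajectory(current, config.tmx)

    log.completed = log.n_accepted >= config.n_accepts
    if not log.completed:
        log.warning = (
            f"trial cap {config.effective_trial_cap} exhausted with "
            f"{log.n_accepted}/{config.n_accepts} acceptances"
        )
    return current, log


@dataclass
class HalfChaosReport:
    """End-to-end half-chaos diagnostic of one network."""

    regime: str
    distribution: DamageDistribution
    crocodile: CrocodileResult
    ice: IceReport | None

    @property
    def ice_fraction(self) -> float | None:
        return None if self.ice is None else self.ice.ice_fraction

    @property
    def module_count(self) -> int | None:
        return None if self.ice is None else len(self.ice.modules)

    @property
    def global_period(self) -> int | None:
        return None if self.ice is None else self.ice.global_period


def check_half_chaos(
    system: KauffmanSystem,
    tmx: int = 1000,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    attractor_cap: int | None = None,
) -> HalfChaosReport:
    """Measure the half-chaos signature of a network.

    Runs the complete crocodile, classifies P(d) at tmx, and (when the
    attractor is found within the cap) reports ice fraction, in-ice module
    count and global period.
    """
    if attractor_cap is None:
        attractor_cap = tmx
    croc = crocodile(system, tmx=tmx, threshold_frac=threshold_frac)
    dist = damage_distribution(croc)
    regime = classify_regime(dist)
    try:
        ice = ice_report(system, system.state, t_cap=attractor_cap)
    except RuntimeError:
        ice = None  # attractor not found within cap
    return HalfChaosReport(regime=regime, distribution=dist, crocodile=croc, ice=ice)
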