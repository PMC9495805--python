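"""PAS-seeded evolution: small-damage acceptance and PAS persistence.

Starting from a point-attractor system, disturbances with small final
damage are accepted as evolutionary changes. Nearly all accepted systems
are again point attractors - the reason the anti-PAS minimum-attractor rule
exists (and why, at these parameters, it rejects nearly everything).
"""

import halfchaos as hc

spec = hc.NetworkSpec(N=200, K=3, s=4, topology_type="er", seed=9)
pas = hc.make_point_attractor(hc.random_system(spec))

cfg = hc.EvolutionConfig(n_accepts=20, tmx=400, min_attractor=1, trial_cap=500, seed=9)
evolved, log = hc.evolve(pas, cfg)
accepted = log.accepted_trials
print(f"trials: {len(log.trials)}, accepted: {log.n_accepted}")
periods = []
cur = pas
for rec in accepted:
    cur = hc.apply_disturbance(cur, rec.disturbance)
    periods.append(hc.find_attractor(cur, cur.state, 500).period)
frac_pas = sum(p == 1 for p in periods) / len(periods)
print(f"accepted systems that are again PAS: {100 * frac_pas:.1f}%")

rep = hc.check_half_chaos(evolved, tmx=400)
print(
    f"evolved net: regime={rep.regime}, left mass {rep.distribution.left_mass:.3f}, "
    f"right mass {rep.distribution.right_mass:.3f}"
)
print(f"ice fraction {rep.ice_fraction:.2f}, in-ice modules: {rep.module_count}")

# with the anti-PAS rule (min attractor 7) nearly every small-damage trial
# is rejected, because period>=7 outcomes are vanishingly rare here:
cfg7 = hc.EvolutionConfig(n_accepts=5, tmx=400, min_attractor=7, trial_cap=500, seed=9)
_, log7 = hc.evolve(pas, cfg7)
reasons = [t.reason for t in log7.trials]
print(
    f"\nmin_attractor=7: {len(log7.trials)} trials -> "
    f"{reasons.count('damage')} damage-rejected, "
    f"{reasons.count('attractor')} attractor-rejected, {log7.n_accepted} accepted"
)
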