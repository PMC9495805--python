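"""Damage-propagation "crocodile": the complete disturbance ensemble.

Runs all N(s-1) one-entry function disturbances of (a) a fully random
network and (b) a point-attractor system at chaotic parameters (s=4, K=3),
and summarizes q(t) (fraction of still-ordered processes) and the damage
size distribution P(d) at tmx.
"""

import halfchaos as hc

spec = hc.NetworkSpec(N=400, K=3, s=4, topology_type="er", seed=5)
d_star = hc.derrida_equilibrium(4, 3)

for label, system in [
    ("fully random", hc.random_system(spec)),
    ("point attractor", hc.make_point_attractor(hc.random_system(spec))),
]:
    croc = hc.crocodile(system, tmx=400)
    dist = hc.damage_distribution(croc)
    regime = hc.classify_regime(dist)
    print(f"{label}: {len(croc.series)} disturbance processes")
    print(f"  q(tmx) = {croc.q[-1]:.3f}   (fraction of processes with A < {croc.threshold})")
    print(
        f"  P(d): left mass {dist.left_mass:.3f}, right mass {dist.right_mass:.3f}, "
        f"right mode {dist.right_mode:.3f} (Derrida d* = {d_star:.3f})"
    )
    print(f"  gap band [{dist.gap_lo:.3f}, {dist.gap_hi:.3f}] -> regime: {regime}")
# both right peaks sit on the Derrida equilibrium d*. The fully random net
# keeps only a small fade fraction (left mass ~ the avalanche extinction
# probability, 0.05-0.1 depending on seed); the PAS roughly doubles the left
# (ordered) peak and widens the empty gap - the half-chaos signature

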