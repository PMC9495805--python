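"""Annealed (Derrida) theory: coefficient w, damage map, equilibrium.

Compares the closed-form annealed map against its mechanical Monte-Carlo
counterpart and prints the chaotic equilibrium for the default parameters.
"""

import numpy as np

import halfchaos as hc

for s, K in [(4, 3), (2, 2), (2, 1)]:
    p = hc.AnnealedParams.from_sk(s, K)
    print(f"s={s}, K={K}: w = {p.w:.4g}, chaotic equilibrium d* = {p.d_star:.4f}")
# w > 1 means chaotic parameters; at s=2, K=2 the coefficient is exactly 1
# (edge of chaos) and no chaotic equilibrium exists

rng = np.random.default_rng(0)
print("\nannealed map vs Monte-Carlo (s=4, K=3):")
for d in (0.05, 0.1, 0.3):
    closed = hc.derrida_step(d, 4, 3)
    mc, se = hc.annealed_damage_mc(d, 4, 3, n_trials=100_000, rng=rng)
    print(f"  d={d:.2f}: map {closed:.4f}, MC {mc:.4f} +- {se:.4f}")
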