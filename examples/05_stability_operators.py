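"""Stability-enhancement operators: regulation, narrowing, modularity.

Each operator is applied to matched networks and judged by the ordered
fraction q(tmx) or the right-peak (chaotic) mass of P(d).
"""

import halfchaos as hc

# 1. PAS regulation: pull distance-1 input tuples back to the frozen state
spec = hc.NetworkSpec(N=150, K=3, s=4, topology_type="er", seed=2)
pas = hc.make_point_attractor(hc.random_system(spec))
print("PAS regulation (right-peak mass of P(d), lower = more ordered):")
for level, name in (("c", "none"), ("b", "small"), ("a", "strong")):
    reg = hc.add_pas_regulation(pas, level, seed=2)
    dist = hc.damage_distribution(hc.crocodile(reg, tmx=300))
    print(f"  level {level} ({name}): right mass {dist.right_mass:.3f}")

# 2. function narrowing: bias tables toward each node's modal output
print("\nfunction narrowing (q(tmx), higher = more ordered):")
sys0 = hc.random_system(spec)
print(f"  P=0.25 (unbiased): q = {hc.crocodile(sys0, tmx=300).q[-1]:.3f}")
for target in (0.5, 0.75):
    nar, _ = hc.narrow_functions(sys0, target_P=target, seed=2)
    print(f"  P={target}: q = {hc.crocodile(nar, tmx=300).q[-1]:.3f}")

# 3. modularity at s=2, K=4 (module size 10, 5% inter-module links)
spec2 = hc.NetworkSpec(N=150, K=4, s=2, topology_type="er", seed=2)
base_q = hc.crocodile(hc.random_system(spec2), tmx=300).q[-1]
sysm = hc.build_modular_network(spec2, n_modules=15, inter_frac=0.05)
mod_q = hc.crocodile(sysm, tmx=300).q[-1]
print(f"\nmodularity (s=2, K=4): baseline q = {base_q:.3f}, modular q = {mod_q:.3f}")

# 4. feedback-loop census on a small net
loops = hc.find_feedback_loops(hc.random_system(spec2), max_len=3)
signs = [r.sign for r in loops]
print(
    f"loop census (len<=3): {len(loops)} loops, "
    f"{signs.count('+')} positive, {signs.count('-')} negative"
)
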