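"""The current-injection machinery, step by step, on a 1000-neuron group.

Shows the designated injectable pool g(G), its 10% per-step perturbation,
a fixed-band count draw, and the three linear ramp-count formulas with
their algebraic endpoints.
"""

import numpy as np

from empathynet import StimLevels, designate_targets, perturb_targets, ramp_count, select_fixed_band

levels = StimLevels()
rng = np.random.default_rng(0)
size, p = 1000, 10_000

g = designate_targets(size, levels, rng)
print(f"|g(G)| = floor({size} * H) = {len(g)} injectable neurons")

g_t = perturb_targets(g, size, 0.10, rng)
print(f"perturbation swapped {len(set(g) - set(g_t))} members (10% of the pool)")

c_t = select_fixed_band(g_t, size, levels.M, levels.H, rng)
print(f"fixed (M, H) band drew |c_t| = {len(c_t)} of the pool "
      f"(uniform in [{int(size*levels.M)}, {int(size*levels.H)}])")

print("\nramp counts (injected neurons) across phase 2, decreasing H -> L:")
for t in (p, int(1.25 * p), int(1.5 * p), int(1.75 * p), 2 * p):
    count = ramp_count(size, levels.H, levels.L, t, p, phase_index=2)
    print(f"  t/p = {t/p:4.2f}: {count:4d}  (= |G| * {count/size:.3f})")
print("endpoints equal |G|*H and |G|*L exactly; at t = 2p the injected "
      f"proportion is {ramp_count(size, levels.H, levels.L, 2*p, p, phase_index=2)/size} = L")
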