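"""The mPFC ventral--dorsal self--other gradient.

Close-other representations are sampled from a negative binomial with
r=7, p=0.0025 (ventral, high indices) and distant-other representations
from r=14, p=0.035 (dorsal, low indices).  This script draws both
populations over a 2000-cell axis and prints their separation.
"""

import numpy as np

from empathynet import GradientSpec, sample_mpfc_gradient_targets

spec = GradientSpec()
rng = np.random.default_rng(7)
n = 2000

for which, (r, p) in (("close", spec.close_other), ("distant", spec.distant_other)):
    draws = sample_mpfc_gradient_targets(spec, which, n, 20_000, rng)
    untrunc = r * (1 - p) / p
    print(f"{which}-other NB(r={r}, p={p}): untruncated mean {untrunc:.0f}, "
          f"in-range mean index {draws.mean():.0f} "
          f"(5-95% band {np.percentile(draws, 5):.0f}-{np.percentile(draws, 95):.0f})")

print("\nThe close-other band sits ventrally (high indices), the distant-other")
print("band dorsally, so close-other stimulation preferentially engages the")
print("caregiving projections, whose mPFC-side endpoints follow the close-other")
print("distribution.")
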