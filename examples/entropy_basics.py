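"""Compute the four entropy measures on a seeded white-noise signal.

ApEn and SampEn use the Chebyshev distance (and therefore react to the
signal's amplitude); RangeEnA/B use the normalised range distance and
do not. Values are in nats; higher means less regular.
"""

import numpy as np

from rangeen import NoiseSpec, apen, gen_noise, rangeen_a, rangeen_b, sampen

x = gen_noise(NoiseSpec("white", 1000, seed=42))

print(f"signal: {x.label}, N={len(x)}, m=2, r=0.2")
for name, fn in (("ApEn", apen), ("SampEn", sampen),
                 ("RangeEnA", rangeen_a), ("RangeEnB", rangeen_b)):
    ev = fn(x, m=2, r=0.2)
    print(f"  {name:9s} = {ev.value:.4f}")

# scaling the signal by 5 changes the classical measures, not RangeEn
y = 5.0 * x.values
print("\nafter multiplying the signal by 5:")
print(f"  ApEn      = {apen(y, m=2, r=0.2).value:.4f}   (was amplitude-sensitive)")
print(f"  RangeEnB  = {rangeen_b(y, m=2, r=0.2).value:.4f}   (identical by construction)")
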