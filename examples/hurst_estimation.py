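"""Rescaled-range (R/S) Hurst estimation, noise vs motion convention.

The R/S procedure takes an increment-like series. White noise analysed
directly gives H near 0.5; a Brownian path must be differenced first
(kind="motion") — fed in directly it saturates near 1.
"""

import numpy as np

from rangeen import hurst_rs, rescaled_range_curve

rng = np.random.default_rng(0)
noise = rng.standard_normal(1000)
path = np.cumsum(noise)

print("R/S curve of the white noise (segment_length, mean R/S):")
for p in rescaled_range_curve(noise):
    print(f"  L={p.segment_length:5d}  R/S={p.mean_rs:8.2f}  "
          f"({p.n_segments_used} segments)")

print(f"\nwhite noise, kind='noise' : H = {hurst_rs(noise).hurst:.3f}")
print(f"Brownian path, kind='motion': H = {hurst_rs(path, kind='motion').hurst:.3f}")
print(f"Brownian path, kind='noise' : H = {hurst_rs(path).hurst:.3f}  (saturates)")
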