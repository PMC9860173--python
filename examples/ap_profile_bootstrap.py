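"""Normalized AP expression profile of a stripe line, with bootstrap band.

Simulates 10 replicate embryos of an eveS2-like stripe (AP 0.35), extracts
the central-band profile from each, normalizes against the posterior tail,
and bootstraps the per-line mean profile (1000 replicates, 95 % envelope).
"""

import numpy as np

from embryoexpress import (EmbryoGeometry, PatternSpec, bootstrap_band,
                           fit_embryo_frame, mask_embryo, render_embryo)
from embryoexpress.patterns import ap_stripe
from embryoexpress.profiles import profile_pipeline

geometry = EmbryoGeometry()
pattern = PatternSpec([ap_stripe(0.35, 0.05, 400.0)], baseline=40.0)

profiles = []
for seed in range(10):
    image, _ = render_embryo(geometry, pattern, noise=40.0, seed=100 + seed)
    mask = mask_embryo(image)
    frame = fit_embryo_frame(mask, anterior_end="left")
    profiles.append(profile_pipeline(image, frame, band_fraction=0.30,
                                     mask=mask.mask))

band = bootstrap_band(profiles, n_boot=1000, ci=0.95, seed=1)
peak = band.grid[np.argmax(band.mean)]
print(f"embryos profiled:      {len(profiles)}")
print(f"profile peak position: AP = {peak:.3f} (true stripe at 0.350)")
print(f"peak height:           {band.mean.max():.1f} "
      f"[{band.lower[np.argmax(band.mean)]:.1f}, "
      f"{band.upper[np.argmax(band.mean)]:.1f}] (95% band)")
print()
print("Intensities are in posterior-tail units: the tail background maps to")
print("0 and its median to 1, so peak height is relative to posterior signal.")
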