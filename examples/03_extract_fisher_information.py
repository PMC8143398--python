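"""Extract sqrt Fisher information via the Cramér–Rao bound.

With the bound assumed tight, sqrt(I_F) = (1 + b')/sigma pointwise; its
integral over orientation is the total encoding resource and its normalized
form is the efficient-coding prior over orientation.
"""

import numpy as np

from psyfi import (CohortSpec, combined_participant, extract_sqrt_fi,
                   simulate_cohort, sliding_profile)

data = simulate_cohort(CohortSpec(rng_seed=0))

for group in ("NT", "ASD"):
    pooled = combined_participant(data, group, "woFB")
    fp = extract_sqrt_fi(sliding_profile(pooled, window_deg=4.0))
    prior = fp.prior
    near_cardinal = np.abs((fp.grid_deg + 45) % 90 - 45) <= 10
    near_oblique = np.abs(fp.grid_deg % 90 - 45) <= 10
    print(f"{group}: total sqrt-FI = {fp.total:.2f}   "
          f"prior near cardinals = {prior[near_cardinal].mean():.3f}, "
          f"near obliques = {prior[near_oblique].mean():.3f}")
# Total sqrt-FI is the group's encoding capacity (larger for NT); the prior
# (band-averaged: the pointwise nonparametric profile is noisy) peaks at
# cardinal orientations for both groups, echoing natural-scene orientation
# statistics (a uniform prior would sit at 1/pi ~ 0.318 everywhere).
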