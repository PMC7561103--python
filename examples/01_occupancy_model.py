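"""Evaluate the two-site occupancy model across a titration.

Builds the 4-fold concentration ladder, computes the probe occupancy
distribution for a cooperative (C=5) and an independent-sites (C=1) model,
and prints the average number of sites filled at each concentration.
"""

import numpy as np

from emsafit import make_ladder, mean_sites_filled, mixture_occupancy, statistical_weight

KD = 40.0   # nM, single-site dissociation constant
F = 0.85    # fraction of probes competent to bind two complexes

ladder = make_ladder(2.5, 4, 5)
alpha = statistical_weight(ladder, KD)

print(f"{'conc (nM)':>10} {'P0':>7} {'P1':>7} {'P2':>7}   sites filled (C=5 / C=1)")
coop = mixture_occupancy(alpha, 5.0, F)
for i, c in enumerate(ladder):
    filled5 = mean_sites_filled(alpha[i], 5.0, F)
    filled1 = mean_sites_filled(alpha[i], 1.0, F)
    print(
        f"{c:>10.1f} {coop.p0[i]:>7.3f} {coop.p1[i]:>7.3f} {coop.p2[i]:>7.3f}"
        f"   {filled5:.3f} / {filled1:.3f}"
    )

# Cooperativity shifts weight from the single-shift band into the supershift:
# at 40 nM (alpha = 1) the C=5 model fills ~1.38 sites vs ~0.95 for C=1.
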