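"""Turn chemotaxis off and compare small versus large spheroids.

The self-generated chemoattractant holds cells together (attraction up
the gradient toward the dense core). That brake on dispersal only
matters where enough chemical accumulates: removing chemotaxis barely
changes a 50-um spheroid but visibly raises the final RRM of a 160-um
one. Six seeds per condition keep this demo quick; the test suite runs
the full 20-seed comparison with a KS test.
"""

import numpy as np

from spherocam import MechanismFlags, ablate, ks_compare, make_params, mean_rrm, run

params = make_params()
full = MechanismFlags()
no_chemo = ablate(full, "chemotaxis")
seeds = range(6)


def final_rrm(d, flags, seed):
    res = run(params.with_overrides(seed=seed), d, flags, n_steps=205)
    return mean_rrm(res.to_tracks(), res.initial_centroid_um()).final()


for d, label in ((5, "50 um (small)"), (16, "160 um (large)")):
    on = [final_rrm(d, full, s) for s in seeds]
    off = [final_rrm(d, no_chemo, s) for s in seeds]
    stat, p = ks_compare(on, off)
    print(f"{label}: final RRM {np.mean(on):.2f} with chemotaxis, "
          f"{np.mean(off):.2f} without (KS p = {p:.3f})")
print("Chemotaxis restrains invasion mainly in large spheroids, where the "
      "accumulated chemical field is strong enough to pull cells back.")
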