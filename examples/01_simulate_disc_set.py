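"""Generate replicate synthetic wing discs for several genotypes.

Builds three noisy replicate discs each for wild-type Ci, the
processing-resistant variant S849A, and the weakly activatable deletion
variant, then prints the anterior-plateau and boundary Ci-155 levels.
High anterior levels for the resistant variant (full-length protein is
never converted to repressor) and the wild-type boundary elevation are
the signatures the downstream decomposition relies on.
"""

import numpy as np

from hhquant import CH_CI, simulate_disc_set
from hhquant.simulate import GENOTYPES, SimParams

params = SimParams(noise_sd_frac=0.05, seed=0)
rng = np.random.default_rng(0)

for name in ("WT", "S849A", "D1270_1370"):
    discs = simulate_disc_set(params, GENOTYPES[name], n_discs=3, rng=rng)
    for d in discs:
        ci = d.channels[CH_CI]
        anterior = ci[d.x <= -100].mean()
        # sample just anterior of this disc's (jittered) compartment boundary
        at_boundary = (d.x > d.meta["true_offset"] - 4) & (d.x <= d.meta["true_offset"])
        boundary = ci[at_boundary].mean()
        print(
            f"{d.disc_id:>14s}  anterior Ci-155 = {anterior:7.1f} a.u.   "
            f"boundary Ci-155 = {boundary:7.1f} a.u.   "
            f"(true boundary offset {d.meta['true_offset']:+.1f} um)"
        )

print(
    "\nAnterior Ci-155 is ~3.5x higher for S849A than WT (no processing), and"
    "\nthe generator records each disc's true positional offset for recovery tests."
)
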