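"""Decompose Ci-155 profiles into degradation and processing-inhibition components.

Simulates three noisy discs per genotype (WT plus two processing-resistant
variants), aligns them on the ptc-lacZ maximum, and runs the
genotype-subtraction decomposition: the resistant profiles expose the
Hh-stimulated reduction R(x); adding R(x) to the WT profile yields the
no-reduction curve from which graded processing inhibition is landmarked.
"""

import numpy as np

from hhquant import align_profiles, decompose, fold_changes, simulate_disc_set
from hhquant.simulate import GENOTYPES, SimParams

params = SimParams(noise_sd_frac=0.05, seed=0)
rng = np.random.default_rng(0)
aligned = {
    name: align_profiles(simulate_disc_set(params, GENOTYPES[name], 3, rng=rng))
    for name in ("WT", "S849A", "P13A")
}

result = decompose(aligned["WT"], [aligned["S849A"], aligned["P13A"]])
fold_red, fold_span = fold_changes(result)

print(f"anterior maximum of resistant Ci-155 : {result.c_max_anterior:7.1f} a.u.")
print(f"reduction at the boundary            : {np.interp(0, result.grid, result.reduction):7.1f} a.u.")
print(f"processing first inhibited at        : {result.x_first_inh:6.1f} um")
print(f"processing 50% inhibited at          : {result.x_half_inh:6.1f} um")
print(f"processing fully inhibited at        : {result.x_full_inh:6.1f} um")
print(f"fold reduction by the boundary       : {fold_red:5.2f}")
print(f"fold span of processing inhibition   : {fold_span:5.2f}")

print(
    "\nPositions are in um with the ptc-lacZ maximum (the compartment boundary)"
    "\nat 0; both fold changes exceed 2, i.e. each graded process alone would"
    "\nchange Ci-155 levels more than two-fold across the AP border."
)
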