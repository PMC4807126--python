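"""UV-crosslinking kinetics: how fast free F57Bpa KCNE1 enters the complex.

Simulates per-sweep peak-current diaries under repeated 300 ms UV flashes
for each construct co-expressed with photo-reactive F57Bpa KCNE1, and for
the wild-type rundown controls.  One-phase fits give the rundown constant
K_RD; two-phase fits with K_RD held fixed isolate the crosslinking rate
K_XL, which counts the clefts still open to free beta-subunits.
"""

import dataclasses

from ikstools import (
    crosslink_summary,
    fit_one_phase,
    fit_two_phase_constrained,
    simulate_uv_diary,
)
from ikstools import constructs as C

print("rundown controls (wild-type KCNE1, one-phase fits):")
for name, model in C.RUNDOWN.items():
    diary = simulate_uv_diary(model, seed=0, construct=name)
    fit = fit_one_phase(diary)
    print(f"  {name:13s} K_RD = {fit.k_slow_per_s:.4f} /s")

print("\ncrosslinking groups (F57Bpa KCNE1, 6 noisy cells each, "
      "slow rate held at the construct's K_RD):")
groups = {}
for j, (name, model) in enumerate(C.CROSSLINK.items()):
    noisy = dataclasses.replace(model, noise_cv=C.GROUP_NOISE_CV)
    groups[name] = [
        fit_two_phase_constrained(
            simulate_uv_diary(noisy, seed=100 * j + c, cell_id=f"{name}-{c}"),
            model.k_rd_per_s)
        for c in range(6)]
table = crosslink_summary(groups)
print(table.round(4).to_string(index=False))
print("\nK_XL falls with the number of occupied clefts "
      "(KCNQ1 4 free > EQQQQ 3 > EQQ 2 > EQ 0): free KCNE1 keeps binding "
      "as long as clefts remain, i.e. the stoichiometry is variable up to "
      "4:4.  EQ reports no detectable fast phase - its decay is pure "
      "rundown.")
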