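"""Tail-current G-V curves and Boltzmann midpoints per construct.

Simulates noiseless isochronal activation families (4 s steps from -80 to
+100 mV, tail at -40 mV) for the constructs with published midpoints,
extracts normalized tail amplitudes and fits each cell's Boltzmann
sigmoid g(V) = 1/(1 + exp((V1/2 - V)/k)).
"""

import numpy as np

from ikstools import (
    AnalysisConfig,
    extract_tail_amplitudes,
    fit_boltzmann,
    simulate_macroscopic_family,
    summarize_v12,
)
from ikstools import constructs as C

cfg = AnalysisConfig()
voltages = np.arange(-80.0, 101.0, 10.0)
fits = {}
for name in ("KCNQ1", "KCNQ1+KCNE1", "KCNQ1+F57Bpa", "EQ"):
    fam = simulate_macroscopic_family(C.MACRO[name], voltages, fs=1000.0,
                                      seed=1, construct=name)
    fits[name] = [fit_boltzmann(extract_tail_amplitudes(fam, cfg))]

print(summarize_v12(fits).round(2).to_string(index=False))
print("\nV1/2 is the half-activation voltage: KCNQ1 alone activates near "
      "-15.5 mV and saturating KCNE1 shifts activation ~45 mV depolarized; "
      "k ~ 12 mV is the slope factor (voltage sensitivity).")
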