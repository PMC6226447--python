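"""Recovery of a planted rare population across dilution levels.

For each rare fraction between 0.5% and 5%, a minor population is planted
into a ~2000-cell major background, the full pipeline is run, and the F1
of the IQR-based rare call is measured against the true labels. Detection
should stay strong across the whole dilution range.
"""

import warnings

import numpy as np

import firescore as fs

print("rare_fraction  F1 (mean over 2 seeds)")
for frac in [0.005, 0.01, 0.025, 0.05]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1s = [fs.planted_rare_f1(rare_fraction=frac, seed=s) for s in (0, 1)]
    print(f"{frac:>12.3f}  {np.mean(f1s):.3f}")
# F1 is precision/recall balance w.r.t. the planted minor cells; values
# near 1 mean the IQR fence recovers the population almost exactly even
# when it makes up only half a percent of the data.
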