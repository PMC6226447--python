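"""Empirical check that scoring time grows linearly with the cell count.

Sketching visits each cell L times over M genes and hashing is a single
integer dot product, so the whole scoring stage is O(N * L * M). Doubling
the number of cells at fixed (L, M) should therefore roughly double the
wall time, and tens of thousands of cells should score in seconds.
"""

import time

import numpy as np

import firescore as fs

rng = np.random.default_rng(0)
times = {}
for n in [10_000, 20_000, 40_000]:
    values = rng.lognormal(0.0, 1.0, size=(n, 1000))
    t0 = time.time()
    d, _, _ = fs.sketch_densities(values, fs.SketchParams(seed=1))
    fs.fire_scores(d)
    times[n] = time.time() - t0
    print(f"N={n:>6d}: {times[n]:.2f}s")

print(f"40k/20k time ratio: {times[40_000]/times[20_000]:.2f} "
      "(≈2 means linear scaling)")
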