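"""Nonparametric blockwise Granger causality and the directed asymmetry index.

Simulates a unidirectional 2-parcel network (P0 -> P1 at 20 Hz), estimates
directional GC spectra through the Wilson factorization of the multitaper CSD,
compares the result with the parametric Geweke spectrum computed from the true
VAR coefficients, and reports the DAI at the coupling peak.
"""

import numpy as np

from specdag import (
    Edge,
    NetworkSpec,
    blockwise_gc,
    compute_dai,
    multitaper_csd,
    parametric_gc_spectrum,
    segment,
    simulate_mvar,
    wilson_factorize,
)

spec = NetworkSpec(
    n_parcels=2, components_per_parcel=1,
    edges=[Edge(0, 1, strength=0.15, f0_hz=20.0, bw_hz=10.0)],
    fs=256.0, trial_length_s=60.0, n_trials=30, seed=42,
)
csd = multitaper_csd(segment(simulate_mvar(spec), 4.0, 0.5), 2.0)
factors = wilson_factorize(csd)
gc_ab, gc_ba = blockwise_gc(factors, [0], [1])
dai = compute_dai(gc_ab, gc_ba)

p_ab, _ = parametric_gc_spectrum(spec.coefficients(), np.eye(2), spec.fs, csd.freqs, [0], [1])
pk = int(np.argmax(p_ab))
print(f"coupling peak at {csd.freqs[pk]:.2f} Hz")
print(f"GC P0->P1 at peak: nonparametric {gc_ab[pk]:.3f}, parametric oracle {p_ab[pk]:.3f}")
print(f"GC P1->P0 at peak: {gc_ba[pk]:.5f}  (no reverse coupling was simulated)")
print(f"DAI at peak: {dai[pk]:.3f}  (+1 = flow entirely P0->P1, -1 = reverse)")
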