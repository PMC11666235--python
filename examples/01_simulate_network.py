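"""Simulate a two-parcel MVAR network with a band-specific directed edge.

Builds a network in which parcel P0 drives parcel P1 through a damped
resonance centered at 10 Hz, simulates trials, and verifies that the target
parcel's multitaper spectrum peaks where the closed-form VAR spectrum says it
should.
"""

import numpy as np

from specdag import Edge, NetworkSpec, analytic_csd, multitaper_csd, segment, simulate_mvar

spec = NetworkSpec(
    n_parcels=2,
    components_per_parcel=1,
    edges=[Edge(source=0, target=1, strength=0.3, f0_hz=10.0, bw_hz=4.0)],
    fs=256.0,
    trial_length_s=60.0,
    n_trials=8,
    seed=7,
)
print(f"companion spectral radius: {spec.spectral_radius():.3f}  (< 1: stationary)")

epochs = segment(simulate_mvar(spec), win_s=4.0, overlap_s=0.5)
print(f"{epochs.n_trials} epochs of {epochs.n_channels} channels x {epochs.n_samples} samples")

csd = multitaper_csd(epochs, smoothing_hz=2.0)
S_true = analytic_csd(spec.coefficients(), np.eye(2), spec.fs, csd.freqs)

band = (csd.freqs > 2) & (csd.freqs < 20)
f_emp = csd.freqs[band][np.argmax(csd.S[band, 1, 1].real)]
f_th = csd.freqs[np.argmax(S_true[:, 1, 1].real)]
print(f"target-parcel spectral peak: empirical {f_emp:.2f} Hz, closed form {f_th:.2f} Hz")
print("-> the directed edge injects oscillatory influence in its stated band")
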