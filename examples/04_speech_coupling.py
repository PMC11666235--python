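"""Gaussian-copula MI between a speech-like envelope and parcel activity.

Injects a low-frequency amplitude envelope into one parcel with a 130 ms
delay (the brain lags the speech), then sweeps the assumed lag and shows that
the theta-band MI between the envelope's and the parcel components' complex
spectra peaks at the injected delay.
"""

import numpy as np

from specdag import BandDefinition, NetworkSpec, make_envelope_driven_parcel, mi_lag_sweep

theta = BandDefinition("theta", 4.0, 8.0)
spec = NetworkSpec(n_parcels=1, components_per_parcel=3, edges=[],
                   fs=256.0, trial_length_s=60.0, n_trials=6, seed=3)
epochs, envelope = make_envelope_driven_parcel(spec, lag_ms=130.0, snr=2.0)

parcel = epochs.data[:, epochs.channels_of("P0"), :]
sweep = mi_lag_sweep(parcel, envelope, spec.fs, theta, lags_ms=np.arange(0.0, 261.0, 26.0))
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
best = sweep.loc[sweep["mi_nats"].idxmax(), "lag_ms"]
print(f"\nMI peaks at {best:.0f} ms - the injected brain-lags-speech delay (130 ms)")
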