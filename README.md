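# specdag

Frequency-resolved **directed connectivity** between multi-component brain
parcels: nonparametric blockwise Granger causality (GC) via Wilson spectral
matrix factorization, the directed asymmetry index (DAI), cluster-based
permutation group statistics, and Gaussian-copula mutual information (GCMI)
between a speech-like envelope and parcel activity.

The package targets the analysis setting of MEG/EEG studies of speech
production and perception, where each atlas parcel is summarized by its three
strongest SVD components and the question is *which direction* information
flows between parcel pairs, *at which frequencies* — e.g. low-frequency
top–down influences versus high-frequency bottom–up signaling. Raw recordings
of this kind are typically privacy-restricted, so the package includes a
first-class synthetic generator producing MVAR networks with known
frequency-specific directed structure, used to validate every stage against
ground truth and closed-form oracles.

## The statistics at the core

For a parcel pair with blocks X and Y (block = the parcel's components), the
joint cross-spectral density S(f), estimated by multitaper (4 s windows,
500 ms overlap, 2 Hz smoothing), is factorized by Wilson's algorithm as
S(f) = H(f) Σ H(f)\*. The Geweke blockwise measure of directed influence is

    F_{X→Y}(f) = ln det S_YY(f) − ln det( S_YY(f) − H_YX(f) Σ_{X|Y} H_YX(f)* ),
    Σ_{X|Y} = Σ_XX − Σ_XY Σ_YY⁻¹ Σ_YX,

and the two directions of a pair are combined into the directed asymmetry
index

    DAI(f) = (F_{A→B} − F_{B→A}) / (F_{A→B} + F_{B→A}) ∈ [−1, 1],

whose sign gives the dominant direction at each frequency. Group inference
uses dependent-samples t statistics on DAI (against zero, or speaking vs
listening) with cluster-based permutation correction across frequencies and
parcel pairs (5000 permutations, α = 0.05), summarized per canonical band
(Delta/Theta 0–7, alpha 7–13, beta 15–30, gamma 30–60, high gamma 60–90 Hz)
as directed edge lists and node strengths. Speech–brain coupling is GCMI
between the envelope's and the parcel components' band-averaged complex
spectra with the envelope leading by 130 ms, correlated with connectivity
across participants under a permutation-corrected Pearson test.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

`examples/02_granger_dai.py` simulates a two-parcel network in which P0
drives P1 through a 20 Hz resonance, estimates the directional GC spectra
nonparametrically, and compares them with the parametric Geweke spectrum
computed from the true VAR coefficients:

```
coupling peak at 19.50 Hz
GC P0->P1 at peak: nonparametric 1.109, parametric oracle 1.143
GC P1->P0 at peak: 0.00003  (no reverse coupling was simulated)
DAI at peak: 1.000  (+1 = flow entirely P0->P1, -1 = reverse)
```

The nonparametric estimate agrees with the oracle to ~3 % at the coupling
peak, the reverse direction is four orders of magnitude smaller, and the DAI
correctly reports one-sided flow. `examples/04_speech_coupling.py` injects an
envelope into a parcel with a 130 ms delay and sweeps the assumed lag:

```
 lag_ms  mi_nats
  0.000    0.170
 ...
104.000    2.402
130.000    3.489
156.000    2.238
 ...

MI peaks at 130 ms - the injected brain-lags-speech delay (130 ms)
```

The remaining examples cover network simulation (`01`), cohort-level cluster
statistics with band summaries and node strength (`03`), and the one-call
pipeline (`05`).

## Command line

A thin CLI mirrors the pipeline stages:

```bash
specdag simulate --config net.yaml --out epochs.h5
specdag csd --epochs epochs.h5 --out csd.h5 --win 4 --overlap 0.5 --smoothing 2
specdag gc --csd csd.h5 --out gc.tsv --fmax 100
specdag stats --dai gc_all.tsv --out edges.tsv --nperm 5000 --alpha 0.05 --seed 7
specdag coupling --epochs epochs.h5 --envelope env.h5 --parcel P0 --lag-ms 130
specdag run --config run.yaml --out rundir/   # full pipeline, seeded
```

All tabular outputs are TSV; array containers are HDF5; every run directory
carries a MANIFEST with the config hash and seed, and reruns with the same
seed are byte-identical.

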