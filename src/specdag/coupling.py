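"""Gaussian-copula mutual information between a speech-like envelope and
frequency-specific parcel activity, plus its cross-participant correlation
with directed connectivity.

The coupling statistic follows the Gaussian-copula MI (GCMI) estimator: each
feature column is rank-transformed and mapped through the inverse standard
normal CDF, which preserves dependence (the copula) while forcing Gaussian
marginals; MI is then the parametric Gaussian value
``0.5 ln(det Cx det Cy / det Cxy)`` with an analytic small-sample bias
correction. Brain features are the real and imaginary parts of the three
parcel components' multitaper spectral estimates averaged over the bins of a
band (2 s windows, 50% overlap, +-2 Hz smoothing); the envelope contributes
its own complex spectral estimate at the same bins, advanced by a fixed lag
(130 ms by default) so the brain signal lags the speech.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss
from scipy.special import digamma, ndtri
from scipy.stats import rankdata
from scipy import stats as sps

from .spectral import n_tapers_expected
from .stats import BandDefinition

__all__ = [
    "copnorm",
    "gcmi",
    "spectral_features",
    "parcel_envelope_mi",
    "mi_lag_sweep",
    "correlate_connectivity_coupling",
]


def copnorm(x: np.ndarray) -> np.ndarray:
    """Copula-normalize columns: average ranks -> inverse normal quantiles."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"column {j} is constant; MI is undefined")
        out[:, j] = ndtri(rankdata(col, method="average") / (n + 1.0))
    return out


def _gauss_entropy_logdet(C: np.ndarray) -> float:
    """0.5 * ln det C via Cholesky (the additive 2*pi*e constants cancel in MI)."""
    L = np.linalg.cholesky(C)
    return float(np.sum(np.log(np.diag(L))))


def _entropy_bias(n: int, d: int) -> float:
    """Bias of the plug-in Gaussian entropy (nats): subtracting it makes MI
    comparable across sample sizes."""
    psiterms = digamma((n - np.arange(1, d + 1)) / 2.0) / 2.0
    dterm = (np.log(2.0 / (n - 1))) / 2.0
    return float(d * dterm + psiterms.sum())


def gcmi(x: np.ndarray, y: np.ndarray, bias_correct: bool = True) -> float:
    """Gaussian-copula mutual information between feature sets, in nats.

    ``x`` (n, dx) and ``y`` (n, dy) are copula-normalized column-wise, then
    MI is computed from the Gaussian model on the transformed data. The
    analytic small-sample bias of the three entropy terms is subtracted by
    default; the corrected value can be slightly negative for independent
    data (clip downstream if a nonnegative coupling score is needed).
    """
    cx = copnorm(x)
    cy = copnorm(y)
    n, dx = cx.shape
    dy = cy.shape[1]
    if n <= dx + dy + 3:
        raise ValueError(f"need n > dx + dy + 3 samples, got n={n}, dx={dx}, dy={dy}")
    joint = np.concatenate([cx, cy], axis=1)
    joint = joint - joint.mean(axis=0)
    C = joint.T @ joint / (n - 1)
    Cx = C[:dx, :dx]
    Cy = C[dx:, dx:]
    mi = _gauss_entropy_logdet(Cx) + _gauss_entropy_logdet(Cy) - _gauss_entropy_logdet(C)
    if bias_correct:
        mi -= _entropy_bias(n, dx) + _entropy_bias(n, dy) - _entropy_bias(n, dx + dy)
    return float(mi)


def _window_spectra(
    x: np.ndarray, fs: float, win_s: float, overlap_frac: float, smoothing_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Complex multitaper spectral estimates of sliding windows.

    ``x`` is (channels, samples) for one trial. Returns (windows, channels,
    freqs) complex array (taper-averaged FFTs of demeaned windows) and the
    frequency grid.
    """
    n_ch, T = x.shape
    nwin = int(round(win_s * fs))
    step = int(round(win_s * (1.0 - overlap_frac) * fs))
    K = n_tapers_expected(win_s, smoothing_hz)
    if K < 1:
        raise ValueError("smoothing too small for window length: no tapers")
    tapers = dpss(nwin, NW=win_s * smoothing_hz, Kmax=K)
    starts = np.arange(0, T - nwin + 1, step)
    segs = np.stack([x[:, s : s + nwin] for s in starts])  # (w, ch, nwin)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    X = rfft(segs[:, :, None, :] * tapers[None, None, :, :], axis=-1)  # (w, ch, K, f)
    return X.mean(axis=2), rfftfreq(nwin, 1.0 / fs)


def spectral_features(
    parcel_data: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    band: BandDefinition,
    lag_ms: float = 130.0,
    win_s: float = 2.0,
    overlap_frac: float = 0.5,
    smoothing_hz: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired brain/envelope spectral feature matrices for GCMI.

    ``parcel_data`` is (n_trials, n_components, n_samples), ``envelope``
    (n_trials, n_samples) sampled at the same rate and aligned to trial
    onsets. The envelope is advanced by ``lag_ms`` relative to the brain
    signal (brain lags speech), both are cut into ``win_s`` windows with
    ``overlap_frac`` overlap, and each window's taper-averaged complex
    spectrum is averaged over the band's bins. Features are the real and
    imaginary parts: 2 x n_components brain dims, 2 envelope dims, one row
    per window pooled across trials.
    """
    parcel_data = np.asarray(parcel_data, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if parcel_data.ndim != 3:
        raise ValueError("parcel_data must be (trials, components, samples)")
    lag = int(round(lag_ms / 1000.0 * fs))
    T = parcel_data.shape[2]
    if lag >= T:
        raise ValueError("lag exceeds trial length")
    brain_rows, env_rows = [], []
    for tr in range(parcel_data.shape[0]):
        # realign: brain(t) against env(t - lag), common support of length T - lag
        xb = parcel_data[tr, :, lag:]
        xe = envelope[tr, : T - lag][None, :] if lag > 0 else envelope[tr][None, :]
        Xb, freqs = _window_spectra(xb, fs, win_s, overlap_frac, smoothing_hz)
        Xe, _ = _window_spectra(xe, fs, win_s, overlap_frac, smoothing_hz)
        bidx = band.bins(freqs)
        if bidx.size == 0:
            raise ValueError(
                f"band {band.name} ({band.f_low}-{band.f_high} Hz) has no bins on the "
                f"{freqs[1] - freqs[0]:.3g} Hz grid of {win_s} s windows"
            )
        zb = Xb[:, :, bidx].mean(axis=2)  # (w, comps)
        ze = Xe[:, 0, bidx].mean(axis=1)  # (w,)
        brain_rows.append(np.concatenate([zb.real, zb.imag], axis=1))
        env_rows.append(np.stack([ze.real, ze.imag], axis=1))
    return np.concatenate(brain_rows), np.concatenate(env_rows)


def parcel_envelope_mi(
    parcel_data: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    band: BandDefinition,
    lag_ms: float = 130.0,
    clip_negative: bool = True,
    **kwargs,
) -> float:
    """Single speech-brain coupling value for one parcel: GCMI between the
    envelope's and the components' band-averaged complex spectra at the given
    lag, windows pooled across trials. Bias-corrected; negative estimates are
    clipped to 0 unless ``clip_negative=False``."""
    brain, env = spectral_features(parcel_data, envelope, fs, band, lag_ms=lag_ms, **kwargs)
    mi = gcmi(brain, env)
    return max(mi, 0.0) if clip_negative else mi


def mi_lag_sweep(
    parcel_data: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    band: BandDefinition,
    lags_ms,
    **kwargs,
) -> pd.DataFrame:
    """Diagnostic MI-vs-lag curve (columns lag_ms, mi_nats)."""
    rows = [
        {"lag_ms": float(l), "mi_nats": parcel_envelope_mi(parcel_data, envelope, fs, band, lag_ms=l, **kwargs)}
        for l in lags_ms
    ]
    return pd.DataFrame(rows)


def correlate_connectivity_coupling(
    dai_vals: np.ndarray,
    mi_vals: np.ndarray,
    parcels=None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Cross-participant Pearson correlation between connectivity and coupling,
    permutation-corrected across parcels (one band at a time).

    ``dai_vals`` is (n_participants, n_parcels) — e.g. per-band mean DAI from
    each parcel to a fixed target — and ``mi_vals`` (n_participants,) the
    coupling value of the target. Pearson r per parcel is converted to
    ``t = r sqrt((n-2)/(1-r^2))``; parcels crossing the two-sided threshold
    form (singleton) clusters whose |t| is compared against the null obtained
    by shuffling the participant pairing, pooling the maximum |t| over
    parcels. Results are per band and not corrected across bands.
    """
    dai_vals = np.asarray(dai_vals, dtype=float)
    mi_vals = np.asarray(mi_vals, dtype=float).ravel()
    if dai_vals.ndim != 2 or dai_vals.shape[0] != mi_vals.shape[0]:
        raise ValueError("dai_vals (n, parcels) and mi_vals (n,) must be paired by participant")
    n, P = dai_vals.shape
    if n < 5:
        raise ValueError("need at least 5 participants")
    if parcels is None:
        parcels = list(range(P))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def _r_to_t(r):
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        return r * np.sqrt((n - 2) / (1.0 - r**2))

    def _corr(m):
        dz = dai_vals - dai_vals.mean(axis=0)
        mz = m - m.mean()
        denom = np.sqrt((dz**2).sum(axis=0) * (mz**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (dz * mz[:, None]).sum(axis=0) / denom

    r_obs = _corr(mi_vals)
    t_obs = _r_to_t(r_obs)
    t_crit = sps.t.ppf(1.0 - cluster_alpha / 2.0, n - 2)

    null_max = np.empty(n_perm)
    for k in range(n_perm):
        t_null = np.abs(_r_to_t(_corr(mi_vals[rng.permutation(n)])))
        null_max[k] = t_null.max()

    pvals = np.ones(P)
    supra = np.abs(t_obs) > t_crit
    for j in np.flatnonzero(supra):
        pvals[j] = (1.0 + np.sum(null_max >= abs(t_obs[j]))) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "parcel": parcels,
            "r": r_obs,
            "t": t_obs,
            "p": pvals,
            "significant": supra & (pvals <= alpha),
        }
    )
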