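"""Epoch segmentation and multitaper cross-spectral density estimation.

The connectivity pipeline operates on a stack of equal-length epochs cut from
continuous trials (4 s windows with 500 ms overlap by default) and estimates
the cross-spectral density (CSD) matrix of all channels with DPSS multitapers.
The CSD is the frequency-resolved covariance of the channels and is the sole
input to the spectral factorization / Granger stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = ["EpochSet", "CrossSpectralDensity", "segment", "multitaper_csd", "n_epochs_expected", "n_tapers_expected"]


@dataclass
class EpochSet:
    """Segmented multi-channel time series.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_samples). "Trials" may be
        continuous recordings before :func:`segment` or short epochs after.
    fs
        Sampling rate in Hz.
    channel_parcel
        Sequence of length n_channels mapping every channel to the parcel it
        belongs to (string labels; a parcel may own several components).
    condition
        Optional condition label ("speaking", "listening", ...).
    """

    data: np.ndarray
    fs: float
    channel_parcel: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (trials, channels, samples), got shape {self.data.shape}")
        self.channel_parcel = np.asarray(self.channel_parcel)
        if self.channel_parcel.shape[0] != self.data.shape[1]:
            raise ValueError(
                f"channel_parcel has {self.channel_parcel.shape[0]} entries "
                f"for {self.data.shape[1]} channels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def parcels(self) -> list:
        """Unique parcel labels in channel order of first appearance."""
        seen: list = []
        for p in np.asarray(self.channel_parcel).tolist():
            if p not in seen:
                seen.append(p)
        return seen

    def channels_of(self, parcel) -> np.ndarray:
        """Indices of the channels belonging to one parcel."""
        return np.flatnonzero(self.channel_parcel == parcel)

    def select_parcels(self, parcels) -> "EpochSet":
        idx = np.concatenate([self.channels_of(p) for p in parcels])
        return replace(self, data=self.data[:, idx, :], channel_parcel=self.channel_parcel[idx])


@dataclass
class CrossSpectralDensity:
    """Hermitian spectral matrix S(f) averaged over tapers and epochs.

    ``S`` has shape (n_freqs, n_channels, n_channels) on the one-sided grid
    ``freqs`` in [0, fs/2]; ``n_fft`` records the window length so that the
    full (two-sided) grid can be reconstructed by Hermitian extension.
    """

    S: np.ndarray
    freqs: np.ndarray
    fs: float
    n_fft: int
    n_tapers: int
    smoothing_hz: float
    n_epochs_averaged: int
    channel_parcel: np.ndarray = field(default=None)

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def select_channels(self, idx) -> "CrossSpectralDensity":
        """Sub-CSD of a channel subset (exact: the CSD of a subsystem is the
        corresponding submatrix)."""
        idx = np.asarray(idx)
        cp = None if self.channel_parcel is None else np.asarray(self.channel_parcel)[idx]
        return replace(self, S=self.S[:, idx[:, None], idx[None, :]], channel_parcel=cp)


def n_epochs_expected(trial_s: float, win_s: float, overlap_s: float) -> int:
    """Number of full windows per trial: floor((T - win)/(win - overlap)) + 1."""
    step = win_s - overlap_s
    return int(np.floor((trial_s - win_s) / step + 1e-9)) + 1


def segment(continuous: EpochSet, win_s: float = 4.0, overlap_s: float = 0.5) -> EpochSet:
    """Cut continuous trials into overlapping epochs.

    Windows advance by ``win_s - overlap_s``; trailing partial windows are
    dropped. With 60 s trials, 4 s windows and 500 ms overlap this yields
    17 epochs per trial.
    """
    if not 0 <= overlap_s < win_s:
        raise ValueError(f"need 0 <= overlap_s < win_s, got overlap={overlap_s}, win={win_s}")
    n_win = int(round(win_s * continuous.fs))
    n_step = int(round((win_s - overlap_s) * continuous.fs))
    T = continuous.n_samples
    if n_win > T:
        raise ValueError(f"window of {win_s} s ({n_win} samples) exceeds trial length {T} samples")
    starts = np.arange(0, T - n_win + 1, n_step)
    epochs = np.stack(
        [continuous.data[t, :, s : s + n_win] for t in range(continuous.n_trials) for s in starts],
        axis=0,
    )
    return replace(continuous, data=epochs)


def n_tapers_expected(win_s: float, smoothing_hz: float) -> int:
    """DPSS taper count floor(2*T*W) - 1 for half-bandwidth ``smoothing_hz``."""
    return int(np.floor(2.0 * win_s * smoothing_hz + 1e-9)) - 1


def multitaper_csd(epochs: EpochSet, smoothing_hz: float = 2.0) -> CrossSpectralDensity:
    """Multitaper cross-spectral density over all channels.

    Each epoch is demeaned per channel, multiplied with ``K = floor(2*T*W)-1``
    unit-energy DPSS tapers of half-bandwidth W = ``smoothing_hz``, and the
    outer products of the one-sided FFTs are averaged over tapers and epochs.
    The result is scaled as a one-sided spectral density (units^2/Hz): summing
    the diagonal over the grid times the bin width recovers signal variance.

    4 s windows with 2 Hz smoothing give K = 15 tapers on a 0.25 Hz grid.
    """
    n = epochs.n_samples
    win_s = n / epochs.fs
    K = n_tapers_expected(win_s, smoothing_hz)
    if K < 1:
        raise ValueError(
            f"smoothing {smoothing_hz} Hz on {win_s:.3g} s windows yields {K} tapers; "
            "need smoothing_hz * win_s >= 1"
        )
    tapers = dpss(n, NW=win_s * smoothing_hz, Kmax=K)  # (K, n), unit energy
    x = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    # (epochs, K, channels, freqs)
    X = rfft(x[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    freqs = rfftfreq(n, 1.0 / epochs.fs)
    # average outer products over epochs and tapers
    S = np.einsum("ekcf,ekdf->fcd", X, np.conj(X)) / (epochs.n_trials * K)
    # one-sided density scaling (tapers have unit energy)
    scale = np.full(len(freqs), 2.0 / epochs.fs)
    scale[0] = 1.0 / epochs.fs
    if n % 2 == 0:
        scale[-1] = 1.0 / epochs.fs
    S *= scale[:, None, None]
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # enforce exact Hermitian symmetry
    return CrossSpectralDensity(
        S=S,
        freqs=freqs,
        fs=epochs.fs,
        n_fft=n,
        n_tapers=K,
        smoothing_hz=smoothing_hz,
        n_epochs_averaged=epochs.n_trials,
        channel_parcel=epochs.channel_parcel,
    )
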