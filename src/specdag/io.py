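"""HDF5 and TSV persistence for the pipeline's containers."""

from __future__ import annotations

import h5py
import numpy as np

from .spectral import CrossSpectralDensity, EpochSet

__all__ = ["save_epochs", "load_epochs", "save_csd", "load_csd"]


def save_epochs(path, es: EpochSet, **attrs) -> None:
    """Write an EpochSet: /data (trials x channels x samples), /fs,
    /channel_parcel; condition and extra metadata as root attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data)
        f.create_dataset("fs", data=float(es.fs))
        f.create_dataset(
            "channel_parcel", data=np.asarray([str(p) for p in es.channel_parcel], dtype="S")
        )
        if es.condition is not None:
            f.attrs["condition"] = es.condition
        for k, v in attrs.items():
            f.attrs[k] = v


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][...],
            fs=float(f["fs"][()]),
            channel_parcel=np.array([s.decode() for s in f["channel_parcel"][...]]),
            condition=f.attrs.get("condition"),
        )


def save_csd(path, csd: CrossSpectralDensity, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("csd", data=csd.S)
        f.create_dataset("freqs", data=csd.freqs)
        f.attrs["fs"] = csd.fs
        f.attrs["n_fft"] = csd.n_fft
        f.attrs["n_tapers"] = csd.n_tapers
        f.attrs["smoothing_hz"] = csd.smoothing_hz
        f.attrs["n_epochs_averaged"] = csd.n_epochs_averaged
        if csd.channel_parcel is not None:
            f.create_dataset(
                "channel_parcel", data=np.asarray([str(p) for p in csd.channel_parcel], dtype="S")
            )
        for k, v in attrs.items():
            f.attrs[k] = v


def load_csd(path) -> CrossSpectralDensity:
    with h5py.File(path, "r") as f:
        cp = None
        if "channel_parcel" in f:
            cp = np.array([s.decode() for s in f["channel_parcel"][...]])
        return CrossSpectralDensity(
            S=f["csd"][...],
            freqs=f["freqs"][...],
            fs=float(f.attrs["fs"]),
            n_fft=int(f.attrs["n_fft"]),
            n_tapers=int(f.attrs["n_tapers"]),
            smoothing_hz=float(f.attrs["smoothing_hz"]),
            n_epochs_averaged=int(f.attrs["n_epochs_averaged"]),
            channel_parcel=cp,
        )
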