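"""Reduce multi-channel parcels to their strongest SVD components.

A parcel with many source channels is summarized by the projections of its
(demeaned) channel matrix onto the top-k left singular vectors, scaled by the
singular values — exactly the rank-k signal subspace with its power preserved.
The three strongest components per parcel form the "block" used by the
blockwise Granger stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spectral import EpochSet

__all__ = ["ParcelBlock", "svd_reduce", "reduce_parcels"]

_RANK_RTOL = 1e-10


@dataclass
class ParcelBlock:
    """Top-k component time series of one parcel."""

    parcel: object
    components: np.ndarray        # (k, n_samples), rows orthogonal
    singular_values: np.ndarray   # descending
    explained_variance: np.ndarray  # fraction per component, sums to <= 1
    loadings: np.ndarray          # (n_channels, k) left singular vectors

    @property
    def k(self) -> int:
        return self.components.shape[0]


def svd_reduce(X: np.ndarray, k: int = 3, parcel: object = None, demean: bool = True) -> ParcelBlock:
    """Top-``k`` SVD components of a channels x samples matrix.

    Components are ``s_i * v_i`` (projections onto left singular vectors), so
    mutually orthogonal with norms equal to the singular values. The sign of
    each component is fixed by making its largest-magnitude channel loading
    positive, so repeated runs are bit-identical.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (channels x samples)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(channels, samples)={min(X.shape)}")
    if demean:
        X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    total = float(np.sum(s**2))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| channel positive per component
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    return ParcelBlock(
        parcel=parcel,
        components=s[:, None] * Vt,
        singular_values=s,
        explained_variance=s**2 / total,
        loadings=U,
    )


def reduce_parcels(es: EpochSet, k: int = 3) -> tuple[EpochSet, pd.DataFrame]:
    """Apply per-parcel SVD reduction to every parcel of an epoch set.

    The decomposition is computed once per parcel on the trials concatenated in
    time (channels demeaned over the concatenation), then every trial is
    projected onto the retained subspace. Returns the reduced epochs (k
    channels per parcel) and an explained-variance table.
    """
    parcels = es.parcels
    n_trials, _, n_samp = es.data.shape
    out = np.empty((n_trials, len(parcels) * k, n_samp))
    labels = []
    rows = []
    for j, p in enumerate(parcels):
        ch = es.channels_of(p)
        Xcat = es.data[:, ch, :].transpose(1, 0, 2).reshape(len(ch), -1)
        block = svd_reduce(Xcat, k=k, parcel=p)
        mean = Xcat.mean(axis=1, keepdims=True)
        out[:, j * k : (j + 1) * k, :] = np.einsum(
            "ck,tcn->tkn", block.loadings, es.data[:, ch, :] - mean[None]
        )
        labels.extend([p] * k)
        for i in range(k):
            rows.append(
                {
                    "parcel": p,
                    "component": i,
                    "singular_value": block.singular_values[i],
                    "explained_variance": block.explained_variance[i],
                }
            )
    reduced = replace(es, data=out, channel_parcel=np.array(labels))
    return reduced, pd.DataFrame(rows)
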