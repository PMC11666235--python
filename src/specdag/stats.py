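"""Group-level statistics on DAI spectra: dependent-samples t tests with
cluster-based permutation correction, band summaries, and node strength.

The observed statistic is a paired t across participants at every
(pair, frequency-bin) cell — DAI against zero, or speaking minus listening.
Cells exceeding the two-sided cluster-forming threshold are grouped into
frequency-contiguous, same-sign clusters within each pair; a cluster's mass is
its summed t. The null distribution is built by randomly sign-flipping each
participant's map (the exact exchangeable null for paired, symmetric data; a
between-condition contrast flips the per-participant condition difference,
equivalent to swapping condition labels). Family-wise error across frequencies
AND parcels is controlled by pooling the maximum |mass| over all pairs and
bins per permutation. Testing runs separately within each canonical band and
is not corrected across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "Cluster",
    "ClusterResult",
    "dai_group_test",
    "band_summary",
    "node_strength",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError(f"band {self.name}: f_low must be < f_high")

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        return np.flatnonzero((freqs >= self.f_low - 1e-9) & (freqs <= self.f_high + 1e-9))


#: Canonical analysis bands (Hz).
DEFAULT_BANDS = (
    BandDefinition("delta_theta", 0.0, 7.0),
    BandDefinition("alpha", 7.0, 13.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma", 30.0, 60.0),
    BandDefinition("high_gamma", 60.0, 90.0),
)

#: Theta band used for speech-envelope coupling.
THETA_COUPLING = BandDefinition("theta", 4.0, 8.0)


@dataclass
class Cluster:
    band: str
    pair_index: int
    pair: object
    bin_indices: np.ndarray  # indices into the full frequency grid
    mass: float
    sign: int
    p: float

    @property
    def members(self) -> set:
        return {(self.pair_index, int(b)) for b in self.bin_indices}


@dataclass
class ClusterResult:
    clusters: list
    t_obs: np.ndarray      # (n_pairs, n_bins) observed t map (NaN where untestable)
    freqs: np.ndarray
    pairs: list
    n_perm: int
    alpha: float
    contrast: str
    bands: tuple = field(default_factory=tuple)

    def significant(self, alpha: float | None = None) -> list:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]


def _t_stats(signs: np.ndarray, data0: np.ndarray, sumsq: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Paired t for sign-flipped data. ``data0`` is (n, C) with NaNs zeroed,
    ``sumsq`` the per-cell sum of squares (flip-invariant), ``counts`` the
    per-cell non-NaN n. ``signs`` is (n_perm, n). Returns (n_perm, C)."""
    mean = (signs @ data0) / counts
    var = (sumsq - counts * mean**2) / np.maximum(counts - 1, 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / counts)
    t[:, counts < 2] = np.nan
    return t


def _max_run_sum(vals: np.ndarray, mask: np.ndarray) -> float:
    """Max sum of ``vals`` over contiguous True runs of ``mask`` (0 if none)."""
    if not mask.any():
        return 0.0
    cs = np.cumsum(np.where(mask, vals, 0.0))
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    sums = cs[ends - 1] - np.where(starts > 0, cs[np.maximum(starts - 1, 0)], 0.0)
    return float(sums.max())


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs in a 1-D mask."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask.size and mask[0]:
        starts = [0] + starts
    if mask.size and mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def _null_max_masses(t_perm: np.ndarray, crit: np.ndarray, P: int, B: int) -> np.ndarray:
    """Per-permutation maximum |cluster mass| pooled over pairs and bins.

    A guard column between pairs prevents runs from crossing pair boundaries.
    """
    n_perm = t_perm.shape[0]
    out = np.empty(n_perm)
    pad = np.full((P, 1), np.nan)
    critg = np.concatenate([crit.reshape(P, B), pad], axis=1).ravel()
    for k in range(n_perm):
        tg = np.concatenate([t_perm[k].reshape(P, B), pad], axis=1).ravel()
        with np.errstate(invalid="ignore"):
            pos = tg > critg
            neg = tg < -critg
        out[k] = max(_max_run_sum(tg, pos), _max_run_sum(-tg, neg))
    return out


def dai_group_test(
    dai: np.ndarray,
    freqs: np.ndarray,
    pairs: list | None = None,
    contrast: str = "vs_zero",
    dai2: np.ndarray | None = None,
    bands=None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    perm_chunk: int = 256,
) -> ClusterResult:
    """Cluster-corrected group test of DAI spectra.

    Parameters
    ----------
    dai
        (n_participants, n_pairs, n_bins); NaN marks undefined bins, which
        are excluded listwise per cell.
    contrast
        ``"vs_zero"`` tests DAI against zero; ``"between_conditions"``
        requires ``dai2`` (same participants, second condition) and tests the
        paired difference ``dai - dai2``.
    bands
        Iterable of :class:`BandDefinition`; each band is tested in its own
        permutation run (no correction across bands). ``None`` treats the
        whole grid as one band.
    n_perm, alpha, cluster_alpha
        Permutations for the max-mass null (default 5000); final cluster
        alpha (default 0.05); two-sided cluster-forming alpha on the t
        distribution with per-cell df.
    """
    dai = np.asarray(dai, dtype=float)
    if dai.ndim != 3:
        raise ValueError("dai must be (participants, pairs, bins)")
    n, P, B = dai.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if contrast == "between_conditions":
        if dai2 is None:
            raise ValueError("between_conditions contrast requires dai2")
        dai2 = np.asarray(dai2, dtype=float)
        if dai2.shape != dai.shape:
            raise ValueError("dai and dai2 must be paired: identical shapes")
        data = dai - dai2
    elif contrast == "vs_zero":
        data = dai
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low; p-value resolution is 1/{n_perm + 1}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs)
    if pairs is None:
        pairs = list(range(P))
    band_list = tuple(bands) if bands is not None else (BandDefinition("all", -1.0, float(freqs[-1])),)

    flat = data.reshape(n, P * B)
    nanmask = np.isnan(flat)
    data0 = np.where(nanmask, 0.0, flat)
    counts_all = (~nanmask).sum(axis=0).astype(float)
    sumsq_all = np.sum(data0**2, axis=0)

    # observed t map on the full grid
    t_obs = _t_stats(np.ones((1, n)), data0, sumsq_all, np.maximum(counts_all, 1.0))[0]
    t_obs[counts_all < 2] = np.nan
    t_obs_map = t_obs.reshape(P, B)

    crit_all = np.full(P * B, np.nan)
    ok = counts_all >= 2
    crit_all[ok] = sps.t.ppf(1.0 - cluster_alpha / 2.0, counts_all[ok] - 1)

    clusters: list = []
    for band in band_list:
        bidx = band.bins(freqs) if band.name != "all" else np.arange(B)
        if bidx.size == 0:
            raise ValueError(f"band {band.name} has no bins on the analyzed grid")
        sel = (np.arange(P)[:, None] * B + bidx[None, :]).ravel()
        d0 = data0[:, sel]
        ssq = sumsq_all[sel]
        cnt = counts_all[sel]
        crit = crit_all[sel]
        Bb = bidx.size

        t_band = t_obs[sel].reshape(P, Bb)
        critb = crit.reshape(P, Bb)
        obs_clusters = []
        for p_i in range(P):
            with np.errstate(invalid="ignore"):
                pos = t_band[p_i] > critb[p_i]
                neg = t_band[p_i] < -critb[p_i]
            for mask, sign in ((pos, 1), (neg, -1)):
                for s0, s1 in _runs(mask):
                    obs_clusters.append(
                        Cluster(
                            band=band.name,
                            pair_index=p_i,
                            pair=pairs[p_i],
                            bin_indices=bidx[s0:s1],
                            mass=float(np.sum(t_band[p_i, s0:s1])),
                            sign=sign,
                            p=1.0,
                        )
                    )
        if obs_clusters:
            null_max = np.empty(n_perm)
            done = 0
            while done < n_perm:
                k = min(perm_chunk, n_perm - done)
                signs = rng.choice([-1.0, 1.0], size=(k, n))
                t_perm = _t_stats(signs, d0, ssq, np.maximum(cnt, 1.0))
                null_max[done : done + k] = _null_max_masses(t_perm, crit, P, Bb)
                done += k
            for c in obs_clusters:
                c.p = float((1.0 + np.sum(null_max >= abs(c.mass))) / (1.0 + n_perm))
        clusters.extend(obs_clusters)

    return ClusterResult(
        clusters=clusters,
        t_obs=t_obs_map,
        freqs=freqs,
        pairs=pairs,
        n_perm=n_perm,
        alpha=alpha,
        contrast=contrast,
        bands=band_list,
    )


def band_summary(result: ClusterResult, bands=DEFAULT_BANDS, alpha: float | None = None) -> pd.DataFrame:
    """Significant directed edges per band.

    A cluster on pair (A, B) with positive sign is the edge A->B, negative
    sign B->A. An edge is emitted for every band its cluster overlaps by at
    least one bin; the weight is the mean |t| over the overlapping bins. A
    cluster spanning a band boundary therefore appears in both bands.
    """
    a = result.alpha if alpha is None else alpha
    rows = []
    for band in bands:
        if band.f_low > result.freqs[-1] + 1e-9:
            raise ValueError(f"band {band.name} lies outside the analyzed grid (max {result.freqs[-1]} Hz)")
        bset = set(band.bins(result.freqs).tolist())
        for c in result.significant(a):
            overlap = sorted(bset.intersection(c.bin_indices.tolist()))
            if not overlap:
                continue
            A, Bp = c.pair if isinstance(c.pair, tuple) else (c.pair, c.pair)
            src, dst = (A, Bp) if c.sign > 0 else (Bp, A)
            tvals = result.t_obs[c.pair_index, overlap]
            rows.append(
                {
                    "band": band.name,
                    "from": src,
                    "to": dst,
                    "mean_t": float(np.mean(np.abs(tvals))),
                    "n_bins": len(overlap),
                    "p": c.p,
                }
            )
    df = pd.DataFrame(rows, columns=["band", "from", "to", "mean_t", "n_bins", "p"])
    if len(df):
        # several clusters of one direction overlapping a band are one edge
        df = (
            df.groupby(["band", "from", "to"], as_index=False, sort=True)
            .agg(mean_t=("mean_t", "max"), n_bins=("n_bins", "sum"), p=("p", "min"))
        )
    return df


def node_strength(edges: pd.DataFrame) -> pd.DataFrame:
    """Outgoing/incoming significant-edge counts and summed weights per node
    and band. Each directed edge contributes one outgoing count to its source
    and one incoming count to its target, so per band the totals balance."""
    rows = []
    if len(edges) == 0:
        return pd.DataFrame(columns=["band", "node", "out_count", "in_count", "out_weight", "in_weight"])
    for band, grp in edges.groupby("band"):
        nodes = sorted(set(grp["from"]) | set(grp["to"]), key=str)
        for node in nodes:
            out = grp[grp["from"] == node]
            inc = grp[grp["to"] == node]
            rows.append(
                {
                    "band": band,
                    "node": node,
                    "out_count": len(out),
                    "in_count": len(inc),
                    "out_weight": float(out["mean_t"].sum()),
                    "in_weight": float(inc["mean_t"].sum()),
                }
            )
    return pd.DataFrame(rows, columns=["band", "node", "out_count", "in_count", "out_weight", "in_weight"])
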