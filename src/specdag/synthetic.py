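"""Synthetic MVAR parcel networks with known frequency-specific directed coupling.

The generator emulates the statistical structure the connectivity analysis
assumes: a handful of brain parcels, each represented by a small block of
component time series (three per parcel by default, standing in for the three
strongest SVD components of a source-localized parcel), driven by a stable
multivariate autoregressive (VAR) process. Directed edges between parcels are
realized as damped-resonance cross-regression terms, so each edge injects
influence in a chosen frequency band (center frequency + bandwidth) and the
analytic spectrum of the network is available in closed form for oracles.

A cohort generator adds participant-level coefficient jitter and per-condition
edge strengths, and an envelope generator mixes a low-frequency amplitude
envelope (mimicking the slow amplitude modulation of continuous speech) into
one designated parcel at a fixed lag, for the coupling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt

from .spectral import EpochSet

__all__ = [
    "Edge",
    "NetworkSpec",
    "ParticipantCohort",
    "CohortData",
    "StabilityError",
    "simulate_mvar",
    "make_envelope",
    "make_envelope_driven_parcel",
    "make_cohort",
    "analytic_transfer",
    "analytic_csd",
]


class StabilityError(ValueError):
    """Raised when a VAR coefficient set is not covariance-stationary."""


@dataclass(frozen=True)
class Edge:
    """Directed coupling between two parcels, band-limited by a damped resonance.

    The edge turns the source components it uses into damped AR(2) resonators
    with a pole pair at the center frequency, ``a1 = 2 r cos(2 pi f0 / fs)``,
    ``a2 = -r^2``, pole radius ``r = exp(-pi * bandwidth / fs)``, and adds a
    lag-1 cross-regression coefficient ``strength`` from those components to
    the target components. The transmitted influence is therefore concentrated
    around ``f0`` (the source's resonance), which is where the directed GC
    spectrum peaks. A zero-strength edge is a no-op. Because the resonance
    lives in the source dynamics, all edges leaving one component must share a
    single (f0, bandwidth); use ``source_comp``/``target_comp`` to route
    different bands through different components (``None`` couples all source
    components to all target components).
    """

    source: int
    target: int
    strength: float
    f0_hz: float
    bw_hz: float = 8.0
    source_comp: int | None = None
    target_comp: int | None = None


@dataclass
class NetworkSpec:
    """Specification of one synthetic parcel network.

    Defaults mirror the recording geometry the analysis expects: 3 components
    per parcel, 256 Hz sampling, 60 s trials.
    """

    n_parcels: int
    components_per_parcel: int = 3
    model_order: int = 2
    edges: tuple = ()
    noise_scale: float = 1.0
    fs: float = 256.0
    trial_length_s: float = 60.0
    n_trials: int = 1
    seed: int = 0
    # intrinsic per-channel AR(2): mild low-pass dynamics, identical across
    # channels so that acausal structure never leaks in by construction
    intrinsic_a1: float = 0.5
    intrinsic_a2: float = -0.1

    def __post_init__(self) -> None:
        if self.components_per_parcel < 1:
            raise ValueError("components_per_parcel must be >= 1")
        if self.model_order < 2:
            raise ValueError("model_order must be >= 2 (damped-resonance edges use lags 1 and 2)")
        self.edges = tuple(e if isinstance(e, Edge) else Edge(*e) for e in self.edges)
        for e in self.edges:
            if not (0 <= e.source < self.n_parcels and 0 <= e.target < self.n_parcels):
                raise ValueError(f"edge {e} references a parcel outside 0..{self.n_parcels - 1}")
            if self.fs <= 2.0 * e.f0_hz:
                raise ValueError(
                    f"fs={self.fs} Hz violates Nyquist for edge center frequency {e.f0_hz} Hz"
                )

    @property
    def n_channels(self) -> int:
        return self.n_parcels * self.components_per_parcel

    def channel_parcel(self) -> np.ndarray:
        return np.array([f"P{p}" for p in range(self.n_parcels) for _ in range(self.components_per_parcel)])

    def parcel_channels(self, parcel: int) -> np.ndarray:
        k = self.components_per_parcel
        return np.arange(parcel * k, (parcel + 1) * k)

    def coefficients(self) -> np.ndarray:
        """VAR coefficient tensor A of shape (model_order, n_ch, n_ch)."""
        nc = self.n_channels
        A = np.zeros((self.model_order, nc, nc))
        idx = np.arange(nc)
        A[0, idx, idx] = self.intrinsic_a1
        A[1, idx, idx] = self.intrinsic_a2
        resonance: dict[int, tuple[float, float]] = {}
        for e in self.edges:
            if e.strength == 0.0:
                continue  # zero coupling is a no-op, identical to an absent edge
            r = np.exp(-np.pi * e.bw_hz / self.fs)
            theta = 2.0 * np.pi * e.f0_hz / self.fs
            src = self.parcel_channels(e.source)
            tgt = self.parcel_channels(e.target)
            if e.source_comp is not None:
                src = src[[e.source_comp]]
            if e.target_comp is not None:
                tgt = tgt[[e.target_comp]]
            for s in src:
                band = (e.f0_hz, e.bw_hz)
                if s in resonance and resonance[s] != band:
                    raise ValueError(
                        f"channel {s} would carry two different resonances "
                        f"{resonance[s]} and {band}; route edges of different bands "
                        "through different source components"
                    )
                resonance[s] = band
                A[0, s, s] = 2.0 * r * np.cos(theta)
                A[1, s, s] = -r * r
            # normalize by source-component count so `strength` is the block
            # gain independent of how many components carry the edge
            for t in tgt:
                A[0, t, src] += e.strength / len(src)
        return A

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix."""
        A = self.coefficients()
        p, nc, _ = A.shape
        comp = np.zeros((p * nc, p * nc))
        comp[:nc, :] = np.concatenate(list(A), axis=1)
        comp[nc:, : (p - 1) * nc] = np.eye((p - 1) * nc)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def check_stable(self) -> float:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StabilityError(
                f"VAR is unstable: companion-matrix spectral radius {rho:.4f} >= 1"
            )
        return rho

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        edges = tuple(Edge(**e) for e in cfg.pop("edges", []))
        return cls(edges=edges, **cfg)


def simulate_mvar(spec: NetworkSpec, rng: np.random.Generator | None = None) -> EpochSet:
    """Simulate trials from the VAR network defined by ``spec``.

    Innovations are i.i.d. Gaussian with covariance ``noise_scale * I``. A
    burn-in of ``10 * model_order * fs`` samples is discarded per trial so the
    output is drawn from the stationary distribution.
    """
    spec.check_stable()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    A = spec.coefficients()
    p, nc, _ = A.shape
    n = int(round(spec.trial_length_s * spec.fs))
    burn = int(10 * spec.model_order * spec.fs)
    sd = np.sqrt(spec.noise_scale)
    out = np.empty((spec.n_trials, nc, n))
    for tr in range(spec.n_trials):
        eps = rng.standard_normal((n + burn, nc)) * sd
        x = np.zeros((n + burn, nc))
        for t in range(p, n + burn):
            acc = eps[t]
            for k in range(p):
                acc = acc + A[k] @ x[t - 1 - k]
            x[t] = acc
        out[tr] = x[burn:].T
    return EpochSet(data=out, fs=spec.fs, channel_parcel=spec.channel_parcel())


# ---------------------------------------------------------------------------
# analytic oracles


def analytic_transfer(A: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """VAR transfer function H(f) = (I - sum_k A_k e^{-i 2 pi f (k+1) / fs})^{-1}."""
    p, nc, _ = A.shape
    z = np.exp(-2j * np.pi * np.asarray(freqs)[:, None] * (np.arange(1, p + 1))[None, :] / fs)
    Af = np.tensordot(z, A, axes=(1, 0))  # (nf, nc, nc)
    return np.linalg.inv(np.eye(nc)[None] - Af)


def analytic_csd(A: np.ndarray, Sigma: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Closed-form VAR spectral density S(f) = H(f) Sigma H(f)^* / fs (one-sided
    scaling with the doubling factor applied away from DC/Nyquist)."""
    H = analytic_transfer(A, fs, freqs)
    S = H @ Sigma[None] @ np.conj(np.swapaxes(H, 1, 2))
    freqs = np.asarray(freqs)
    scale = np.where((freqs > 0) & (freqs < fs / 2), 2.0, 1.0) / fs
    return S * scale[:, None, None]


# ---------------------------------------------------------------------------
# envelope-driven parcel


def make_envelope(
    n_samples: int, fs: float, rng: np.random.Generator, cutoff_hz: float = 8.0
) -> np.ndarray:
    """Low-pass-filtered rectified noise, z-scored: a stand-in for the slow
    amplitude modulation of continuous speech (spectral content <= ``cutoff_hz``)."""
    w = np.abs(rng.standard_normal(n_samples + int(4 * fs)))
    b, a = butter(4, cutoff_hz / (fs / 2.0), btype="low")
    env = filtfilt(b, a, w)[int(2 * fs) : int(2 * fs) + n_samples]
    return (env - env.mean()) / env.std()


def make_envelope_driven_parcel(
    spec: NetworkSpec,
    lag_ms: float = 130.0,
    snr: float = 1.0,
    drive_parcel: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Simulate the network and mix a lagged envelope into one parcel.

    The designated parcel's components become ``x + sqrt(snr * var(x)) *
    env(t - lag)`` — the brain signal lags the envelope by ``lag_ms``. ``snr``
    is the variance ratio of the injected envelope to the intrinsic component
    signal (0 leaves the parcel untouched). Returns the epochs and the
    envelope aligned to trial onsets, shape (n_trials, n_samples).
    """
    if lag_ms < 0:
        raise ValueError("lag_ms must be >= 0")
    lag = int(round(lag_ms / 1000.0 * spec.fs))
    n = int(round(spec.trial_length_s * spec.fs))
    if lag >= n:
        raise ValueError(f"lag {lag_ms} ms exceeds trial length {spec.trial_length_s} s")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    es = simulate_mvar(spec, rng=rng)
    envs = np.empty((spec.n_trials, n))
    chans = spec.parcel_channels(drive_parcel)
    for tr in range(spec.n_trials):
        # generate with lead-in so env(t - lag) exists for every t
        full = make_envelope(n + lag, spec.fs, rng)
        envs[tr] = full[lag:]
        if snr > 0:
            delayed = full[:n]  # env(t - lag) aligned to trial sample t
            for c in chans:
                g = np.sqrt(snr * es.data[tr, c].var())
                es.data[tr, c] = es.data[tr, c] + g * delayed
    return es, envs


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class ParticipantCohort:
    """A cohort of participants sharing one network layout.

    ``conditions`` maps a condition label to the edge set active in that
    condition (both conditions share the parcel layout; they differ only in
    edge strengths). ``between_participant_sd`` multiplicatively jitters each
    edge strength per participant: ``strength * (1 + sd * z)``.
    """

    base: NetworkSpec
    n_participants: int = 30
    between_participant_sd: float = 0.1
    conditions: dict = field(default_factory=dict)
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not self.conditions:
            self.conditions = {"speaking": tuple(self.base.edges)}


@dataclass
class CohortData:
    """Per-participant, per-condition epochs plus the ground-truth edge table."""

    epochs: dict  # (participant, condition) -> EpochSet
    truth: pd.DataFrame  # columns: condition, source, target, f_low, f_high, strength
    cohort: ParticipantCohort
    specs: dict = None  # (participant, condition) -> realized NetworkSpec


def _jitter_edges(edges, sd: float, rng: np.random.Generator):
    return tuple(
        replace(e, strength=e.strength * (1.0 + sd * rng.standard_normal())) for e in edges
    )


def make_cohort(cohort: ParticipantCohort, rng: np.random.Generator | None = None) -> CohortData:
    """Generate epochs for every participant and condition.

    Unstable jittered coefficient draws are resampled up to ``max_retries``
    times before raising :class:`StabilityError`.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    epochs: dict = {}
    specs: dict = {}
    for i in range(cohort.n_participants):
        for cond, edges in cohort.conditions.items():
            spec_i = None
            for _ in range(cohort.max_retries):
                cand = replace(
                    cohort.base,
                    edges=_jitter_edges(edges, cohort.between_participant_sd, rng),
                )
                if cand.spectral_radius() < 1.0:
                    spec_i = cand
                    break
            if spec_i is None:
                raise StabilityError(
                    f"participant {i}, condition {cond}: no stable coefficient draw "
                    f"in {cohort.max_retries} retries"
                )
            es = simulate_mvar(spec_i, rng=rng)
            es.condition = cond
            epochs[(i, cond)] = es
            specs[(i, cond)] = spec_i
    rows = [
        {
            "condition": cond,
            "source": e.source,
            "target": e.target,
            "f_low": e.f0_hz - e.bw_hz,
            "f_high": e.f0_hz + e.bw_hz,
            "strength": e.strength,
        }
        for cond, edges in cohort.conditions.items()
        for e in edges
    ]
    truth = pd.DataFrame(rows, columns=["condition", "source", "target", "f_low", "f_high", "strength"])
    return CohortData(epochs=epochs, truth=truth, cohort=cohort, specs=specs)
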