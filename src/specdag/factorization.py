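"""Wilson's algorithm for spectral matrix factorization.

Factorizes a Hermitian, positive semi-definite cross-spectral density S(f)
into a causal (minimum-phase) transfer function H(f) and an innovation
covariance Sigma such that S(f) = H(f) Sigma H(f)^* at every frequency. This
is the step that makes Granger causality computable without fitting an
autoregressive model: the one-sided CSD is extended Hermitian-symmetrically to
the full circle, an initial spectral factor is refined by Wilson's
Newton-type iteration, and the lag-zero coefficient of the converged factor
yields Sigma.

The implementation follows the classic fixed-point scheme
``psi_{k+1} = psi_k [psi_k^{-1} S psi_k^{-H} + I]_+`` where ``[.]_+`` keeps
the causal (non-negative-lag) part of a para-Hermitian function, with the
lag-zero term halved and upper-triangularized so the factor stays unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

from .spectral import CrossSpectralDensity

__all__ = ["SpectralFactors", "FactorizationError", "wilson_factorize"]

logger = logging.getLogger(__name__)


class FactorizationError(ValueError):
    """Raised when the input CSD cannot be factorized (e.g. non-PSD bins)."""


@dataclass
class SpectralFactors:
    """Result of the Wilson factorization.

    ``H`` is on the one-sided grid ``freqs`` (same grid as the input CSD);
    ``Sigma`` is the real innovation covariance. ``residual`` is the maximum
    over bins of the relative reconstruction error ||H Sigma H^* - S|| / ||S||.
    """

    H: np.ndarray          # (n_freqs, n_ch, n_ch) complex
    Sigma: np.ndarray      # (n_ch, n_ch) real
    freqs: np.ndarray
    fs: float
    iterations: int
    residual: float
    converged: bool

    def reconstruct(self) -> np.ndarray:
        """S_hat(f) = H(f) Sigma H(f)^* on the one-sided grid."""
        return self.H @ self.Sigma[None] @ np.conj(np.swapaxes(self.H, 1, 2))


def _hermitian_extend(S: np.ndarray, n_fft: int) -> np.ndarray:
    """Extend a one-sided CSD stack to the full two-sided FFT grid.

    For real signals S(-f) = conj(S(f)); the one-sided grid has
    ``n_fft//2 + 1`` bins when ``n_fft`` is even, ``(n_fft+1)//2`` when odd.
    """
    m = S.shape[0]
    full = np.empty((n_fft,) + S.shape[1:], dtype=complex)
    full[:m] = S
    for k in range(m, n_fft):
        full[k] = np.conj(S[n_fft - k])
    return full


def _plus_operator(g: np.ndarray, m: int) -> np.ndarray:
    """Causal part of a para-Hermitian matrix function on the full grid.

    Keeps lags 0..m-1, zeroes the rest; the lag-0 coefficient is halved and
    upper-triangularized (splitting it evenly between the causal factor and
    its adjoint while pinning the constant unitary freedom).
    """
    gam = ifft(g, axis=0)
    gam[0] = np.triu(0.5 * gam[0])
    gam[m:] = 0.0
    return fft(gam, axis=0)


def wilson_factorize(
    csd: CrossSpectralDensity,
    tol: float = 1e-9,
    max_iter: int = 100,
    loading: float = 1e-8,
    raise_on_nonconvergence: bool = False,
) -> SpectralFactors:
    """Factorize ``csd`` as S(f) = H(f) Sigma H(f)^*.

    Parameters
    ----------
    csd
        One-sided CSD on the full FFT grid (DC through Nyquist included).
    tol
        Convergence target: maximum over bins of the relative reconstruction
        residual in Frobenius norm.
    max_iter
        Iteration cap; non-convergence is reported on the result (and logged),
        never silent.
    loading
        If the smallest eigenvalue of any bin is negative, ``loading x mean
        diagonal power`` is added to every diagonal. Bins negative beyond
        that tolerance raise :class:`FactorizationError`.
    """
    S = np.asarray(csd.S, dtype=complex)
    m, nc, _ = S.shape
    n_fft = csd.n_fft
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    # convert the one-sided spectral density to the two-sided S = H Sigma H^*
    # convention (undo the doubling and the 1/fs scaling), so the extended
    # spectrum is smooth across DC/Nyquist and Sigma comes out in signal units
    scale = np.full(m, 0.5 * csd.fs)
    scale[0] = csd.fs
    if n_fft % 2 == 0:
        scale[-1] = csd.fs
    S = S * scale[:, None, None]

    evals = np.linalg.eigvalsh(S)
    mean_power = float(np.mean(np.real(np.einsum("fii->fi", S))))
    min_eval = float(evals.min())
    if min_eval < -loading * mean_power * 10:
        bad = int(np.argmin(evals.min(axis=1)))
        raise FactorizationError(
            f"CSD is not positive semi-definite at bin {bad} "
            f"(f={csd.freqs[bad]:.3g} Hz): smallest eigenvalue {min_eval:.3e}"
        )
    if min_eval < 0:
        S = S + (loading * mean_power) * np.eye(nc)[None]

    Sfull = _hermitian_extend(S, n_fft)
    # init: upper Cholesky factor of the lag-0 covariance, constant over f
    gamma0 = np.real(ifft(Sfull, axis=0)[0])
    gamma0 = 0.5 * (gamma0 + gamma0.T) + loading * mean_power * np.eye(nc)
    R = np.linalg.cholesky(gamma0).T
    psi = np.broadcast_to(R.astype(complex), Sfull.shape).copy()

    I = np.eye(nc)
    Snorm = np.linalg.norm(Sfull, axis=(1, 2))
    Snorm = np.where(Snorm > 0, Snorm, 1.0)
    residual = np.inf
    it = 0
    stall = 0
    for it in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(np.swapaxes(psi_inv, 1, 2)) + I[None]
        psi = psi @ _plus_operator(g, m)
        recon = psi @ np.conj(np.swapaxes(psi, 1, 2))
        prev = residual
        residual = float(np.max(np.linalg.norm(recon - Sfull, axis=(1, 2)) / Snorm))
        if residual <= tol:
            break
        # estimated spectra hit a finite-lag representability floor above tol;
        # stop once the residual no longer improves rather than spinning
        if residual >= prev * (1.0 - 1e-3):
            stall += 1
            if stall >= 5:
                break
        else:
            stall = 0
    converged = residual <= tol
    if not converged:
        msg = (
            f"Wilson iteration stopped after {it} iterations with residual "
            f"{residual:.3e} above tol {tol:.1e}"
        )
        if raise_on_nonconvergence:
            raise FactorizationError(msg)
        logger.warning(msg)
    else:
        logger.info("Wilson factorization converged in %d iterations (residual %.3e)", it, residual)

    A0 = np.real(ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi[:m] @ np.linalg.inv(A0)
    return SpectralFactors(
        H=H,
        Sigma=Sigma,
        freqs=np.asarray(csd.freqs),
        fs=csd.fs,
        iterations=it,
        residual=residual,
        converged=converged,
    )
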