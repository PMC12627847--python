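"""Closed-form properties of known vector-autoregressive (VAR) models.

The synthetic generator plants directed influence through the cross terms
of a bivariate VAR.  This module computes, from the *known* coefficients,
the quantities an estimator should recover: stability, the spectral
density matrix, the autocovariance sequence, and Geweke's time-domain and
frequency-domain Granger causality (GC).  These closed forms are the
ground-truth route against which the data-driven estimator in
:mod:`thetamark.connectivity` is validated; the two share no code path
beyond this module's transfer-function algebra being re-derived from
fitted (not true) coefficients there.

Conventions: a VAR(p) ``x_t = sum_k A[k] @ x_{t-k} + e_t`` with innovation
covariance ``sigma``; ``A`` has shape (p, n, n); channel 0 is the driver
("PFC") and channel 1 the receiver ("BNST") in the forward direction.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

__all__ = [
    "companion_matrix",
    "spectral_radius",
    "is_stable",
    "var_spectral_matrix",
    "var_autocovariance",
    "time_domain_gc",
    "spectral_gc_from_coeffs",
]


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Companion (block) form of VAR coefficient matrices A, shape (p, n, n)."""
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    F = np.zeros((n * p, n * p))
    F[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        F[n:, :-n] = np.eye(n * (p - 1))
    return F


def spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stable iff < 1)."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def is_stable(A: np.ndarray, tol: float = 1.0) -> bool:
    return spectral_radius(A) < tol


def _transfer(A: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Transfer function H(f) = (I - sum_k A_k z^-k)^-1 at each frequency.

    Returns array of shape (len(freqs), n, n).
    """
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    Af = np.eye(n)[None] - np.einsum("fk,kij->fij", z, A.astype(complex))
    return np.linalg.inv(Af)


def var_spectral_matrix(A, sigma, freqs, fs) -> np.ndarray:
    """Spectral density matrix S(f) = H Σ H* / fs of a known VAR.

    One-sided density would carry a factor 2; this returns the two-sided
    density on the positive half-axis, matching the convention used by the
    Geweke decomposition (integrating gc over [0, fs/2] with df weights and
    doubling recovers the time-domain measure).
    """
    H = _transfer(A, np.asarray(freqs, float), fs)
    sigma = np.asarray(sigma, float)
    return np.einsum("fij,jk,flk->fil", H, sigma, H.conj()) / fs


def var_autocovariance(A, sigma, n_lags: int) -> np.ndarray:
    """Autocovariance sequence Γ_0..Γ_{n_lags} of a stable VAR.

    Solved exactly from the companion-form discrete Lyapunov equation,
    then propagated by the Yule–Walker recursion.
    """
    A = np.asarray(A, float)
    sigma = np.asarray(sigma, float)
    p, n, _ = A.shape
    F = companion_matrix(A)
    if np.max(np.abs(np.linalg.eigvals(F))) >= 1:
        raise ValueError("VAR is not stable; autocovariance undefined")
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = sigma
    G = solve_discrete_lyapunov(F, Q)
    # big Gamma holds [Γ(i-j)] blocks; extract Γ_0..Γ_{p-1} from first block row
    gammas = [G[:n, k * n:(k + 1) * n] for k in range(p)]
    while len(gammas) <= n_lags:
        k = len(gammas)
        nxt = sum(A[j] @ gammas[k - 1 - j] for j in range(p))
        gammas.append(nxt)
    return np.array(gammas[: n_lags + 1])


def _levinson(gamma: np.ndarray, order: int) -> float:
    """Innovation variance of the order-`order` AR fit to autocovariances
    gamma[0..order] (univariate Levinson–Durbin)."""
    v = gamma[0]
    a = np.zeros(order)
    for k in range(1, order + 1):
        acc = gamma[k] - np.dot(a[: k - 1], gamma[1:k][::-1])
        refl = acc / v
        a_new = a.copy()
        a_new[k - 1] = refl
        a_new[: k - 1] = a[: k - 1] - refl * a[: k - 1][::-1]
        a = a_new
        v = v * (1.0 - refl**2)
    return float(v)


def time_domain_gc(A, sigma, direction: str = "0->1", ar_order: int = 200) -> float:
    """Time-domain Geweke GC of a known VAR: ln(σ²_restricted / σ²_full).

    The restricted model is the univariate AR of the receiver alone, whose
    innovation variance is obtained exactly from the receiver's
    autocovariance sequence via Levinson–Durbin at high order; the full
    innovation variance is the receiver's entry of Σ (partialled on the
    contemporaneous driver innovation).
    """
    src, dst = (int(s) for s in direction.split("->"))
    sigma = np.asarray(sigma, float)
    gam = var_autocovariance(A, sigma, ar_order)
    gamma_dst = gam[:, dst, dst]
    sig_restricted = _levinson(gamma_dst, ar_order)
    # full-model conditional innovation variance of dst given src innovation
    sig_full = sigma[dst, dst] - sigma[dst, src] ** 2 / sigma[src, src]
    return float(np.log(sig_restricted / sig_full))


def spectral_gc_from_coeffs(A, sigma, freqs, fs) -> dict:
    """Geweke frequency-domain GC of a known bivariate VAR, both directions.

    Implements the standard normalisation: the transfer function is rotated
    so the innovations are orthogonalised with respect to the receiver, and

        gc_{src->dst}(f) = ln( S_dd(f) / (S_dd(f) - sigma_cond |H~_ds(f)|^2 / fs) )

    with ``sigma_cond`` the driver innovation variance partialled on the
    receiver.  Returns dict with keys ``"0->1"`` and ``"1->0"`` of per-
    frequency nonnegative arrays.
    """
    freqs = np.asarray(freqs, float)
    H = _transfer(A, freqs, fs)
    sigma = np.asarray(sigma, float)
    out = {}
    for src, dst in ((0, 1), (1, 0)):
        # rotate H so the src innovation is orthogonalised against dst;
        # then S_dd = (σ_dd |H̃_dd|² + σ_cond |H_ds|²)/fs splits into
        # intrinsic and causal parts with no cancellation
        Htilde_dd = H[:, dst, dst] + (sigma[dst, src] / sigma[dst, dst]) * H[:, dst, src]
        sig_cond = sigma[src, src] - sigma[dst, src] ** 2 / sigma[dst, dst]
        intrinsic = sigma[dst, dst] * np.abs(Htilde_dd) ** 2
        causal = sig_cond * np.abs(H[:, dst, src]) ** 2
        out[f"{src}->{dst}"] = np.log1p(
            causal / np.maximum(intrinsic, np.finfo(float).tiny)
        )
    return out
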