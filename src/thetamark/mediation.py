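"""Simple mediation (X → M → Y) with bootstrap inference.

Tests whether the theta biomarker (M) mediates the relation between the
behavioural bias (X) and clinical improvement (Y): OLS paths
a (X→M), b (M→Y adjusted for X) and c′ (direct X→Y adjusted for M);
indirect effect a×b with a bias-corrected percentile bootstrap CI over
patient-level (case) resampling.  The bias score is typically
non-normal, so a rank-based inverse normal transform is applied to X
beforehand (Blom offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.special import ndtr, ndtri

__all__ = ["rank_based_INT", "MediationResult", "mediate"]


def rank_based_INT(x, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom (3/8) offsets.

    Maps values through Φ⁻¹((rank − 3/8)/(n + 1/4)); ties get mid-ranks.
    Monotone, so Spearman correlations are preserved exactly.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    ranks = sstats.rankdata(x, method="average")
    return ndtri((ranks - offset) / (n + 1 - 2 * offset))


@dataclass
class MediationResult:
    a: float             # X -> M
    b: float             # M -> Y | X
    c_prime: float       # X -> Y | M
    indirect: float      # a * b
    ci_lower: float
    ci_upper: float
    n_boot: int
    ci_method: str       # "bc" (bias-corrected) or "percentile"
    n: int

    @property
    def significant(self) -> bool:
        """Indirect effect CI excludes zero."""
        return self.ci_lower > 0 or self.ci_upper < 0


def _paths(X, M, Y):
    """OLS point estimates (a, b, c_prime) on centred data."""
    Xc = X - X.mean()
    Mc = M - M.mean()
    Yc = Y - Y.mean()
    sxx = Xc @ Xc
    a = (Xc @ Mc) / sxx
    # Y ~ X + M via the 2x2 normal equations
    smm = Mc @ Mc
    sxm = Xc @ Mc
    det = sxx * smm - sxm**2
    if det <= 1e-12 * sxx * smm:
        raise ValueError("X and M are collinear; mediation paths undefined")
    sxy = Xc @ Yc
    smy = Mc @ Yc
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return a, b, c_prime


def mediate(X, M, Y, n_boot: int = 5000, seed: int = 0, ci: float = 0.95,
            method: str = "bc", apply_int: bool = False) -> MediationResult:
    """Bootstrap mediation of the indirect effect X → M → Y.

    Patient-level (case) resampling with ``n_boot`` draws; the CI is the
    bias-corrected percentile interval by default (``method="percentile"``
    switches to plain percentiles).  ``apply_int=True`` first applies the
    rank-based inverse normal transform to X.
    """
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    n = len(X)
    if not (len(M) == len(Y) == n):
        raise ValueError("X, M, Y must have equal length")
    if n < 6:
        raise ValueError("need at least 6 complete triples")
    if apply_int:
        X = rank_based_INT(X)
    a, b, c_prime = _paths(X, M, Y)
    point = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xb, Mb, Yb = X[idx], M[idx], Y[idx]
    Xc = Xb - Xb.mean(1, keepdims=True)
    Mc = Mb - Mb.mean(1, keepdims=True)
    Yc = Yb - Yb.mean(1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    sxm = np.einsum("ij,ij->i", Xc, Mc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    det = sxx * smm - sxm**2
    ok = (det > 1e-12 * np.maximum(sxx * smm, 1e-30)) & (sxx > 0)
    a_b = np.where(sxx > 0, sxm / np.where(sxx > 0, sxx, 1.0), np.nan)
    b_b = np.where(ok, (sxx * smy - sxm * sxy) / np.where(ok, det, 1.0), np.nan)
    boots = (a_b * b_b)[ok & np.isfinite(a_b * b_b)]

    alpha = 1.0 - ci
    if method == "bc":
        prop = np.mean(boots < point)
        prop = min(max(prop, 1.0 / (len(boots) + 1)),
                   1.0 - 1.0 / (len(boots) + 1))
        z0 = ndtri(prop)
        lo_q = ndtr(2 * z0 + ndtri(alpha / 2))
        hi_q = ndtr(2 * z0 + ndtri(1 - alpha / 2))
    elif method == "percentile":
        lo_q, hi_q = alpha / 2, 1 - alpha / 2
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = np.quantile(boots, [lo_q, hi_q])
    return MediationResult(
        a=float(a), b=float(b), c_prime=float(c_prime), indirect=float(point),
        ci_lower=float(lo), ci_upper=float(hi), n_boot=n_boot,
        ci_method=method, n=n,
    )
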