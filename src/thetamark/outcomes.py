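"""Clinical-score bookkeeping and cross-sectional outcome statistics.

Improvement fractions (pre − post)/pre, responder (≥50 % HAMD decrease)
and remission (follow-up HAMD-17 < 8) labels, Spearman feature–outcome
correlation matrices with Benjamini–Hochberg FDR, ridge regression with
permutation feature importance (3-fold CV penalty selection, importance =
held-out R² drop on shuffling one column, aggregated over many random
fold splits), simple univariate regressions, forward stepwise selection,
and paired Wilcoxon contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "improvement",
    "improvement_table",
    "spearman_matrix",
    "RidgeImportanceResult",
    "ridge_permutation_importance",
    "univariate_r2",
    "stepwise_select",
    "wilcoxon_paired",
    "bh_adjust",
]

SCALES = ("hamd", "madrs", "hama", "dars")
HORIZONS = ("3m", "6m", "12m")


def improvement(pre: float, post: float) -> float:
    """Fractional improvement (pre − post)/pre.

    Applied uniformly to all scales; for DARS (higher = less anhedonia)
    clinical improvement therefore yields *negative* values.
    """
    if pre == 0:
        raise ValueError("improvement undefined for a zero baseline score")
    return (pre - post) / pre


def improvement_table(cohort: pd.DataFrame, scales=SCALES,
                      horizons=HORIZONS) -> pd.DataFrame:
    """Per-patient improvements plus responder/remission labels.

    Expects columns ``<scale>_baseline`` and ``<scale>_<horizon>``.
    Missing follow-up visits are carried forward from the previous
    horizon.  Responder: HAMD improvement ≥ 0.5; remission: follow-up
    HAMD-17 < 8; partial responder: HAMD improvement in [0.25, 0.5).
    """
    if "patient_id" in cohort.columns:
        index = pd.Index(cohort["patient_id"], name="patient_id")
    else:
        index = cohort.index
    out = pd.DataFrame(index=index)
    cohort = cohort.set_axis(index, axis=0)
    for scale in scales:
        pre = cohort[f"{scale}_baseline"].astype(float)
        prev = None
        for horizon in horizons:
            col = f"{scale}_{horizon}"
            if col in cohort.columns:
                post = cohort[col].astype(float)
                if prev is not None:
                    post = post.fillna(prev)   # carry-forward policy
            elif prev is not None:
                post = prev
            else:
                continue
            prev = post
            out[f"{scale}_improvement_{horizon}"] = (pre - post) / pre
            if scale == "hamd":
                imp = out[f"hamd_improvement_{horizon}"]
                out[f"responder_{horizon}"] = imp >= 0.5
                out[f"remission_{horizon}"] = post < 8
                out[f"partial_responder_{horizon}"] = (imp >= 0.25) & (imp < 0.5)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(features: pd.DataFrame, outcomes: pd.DataFrame,
                    alpha: float = 0.05, fdr_family: str = "per_outcome"):
    """Spearman correlations of every feature against every outcome column.

    Returns ``(r, p, flags)`` DataFrames (features × outcomes).  ``flags``
    marks cells surviving BH-FDR at ``alpha`` with the family defined by
    ``fdr_family``: "per_outcome" (all features for one outcome, the
    default), "all" (every cell) or "none" (unadjusted p < alpha).
    Constant columns give NaN cells.
    """
    feats = features.select_dtypes(np.number)
    outs = outcomes.select_dtypes(np.number)
    common = feats.index.intersection(outs.index)
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} paired observations after index alignment"
        )
    feats = feats.loc[common]
    outs = outs.loc[common]
    r = pd.DataFrame(index=feats.columns, columns=outs.columns, dtype=float)
    p = r.copy()
    for oc in outs.columns:
        for fc in feats.columns:
            x, y = feats[fc], outs[oc]
            ok = x.notna() & y.notna()
            if ok.sum() < 4 or x[ok].nunique() <= 1 or y[ok].nunique() <= 1:
                continue
            rho, pv = sstats.spearmanr(x[ok], y[ok])
            r.loc[fc, oc] = rho
            p.loc[fc, oc] = pv
    flags = pd.DataFrame(False, index=r.index, columns=r.columns)
    if fdr_family == "none":
        flags[:] = p.lt(alpha).fillna(False)
    elif fdr_family == "per_outcome":
        for oc in p.columns:
            ok = p[oc].notna()
            if ok.any():
                flags.loc[ok, oc] = bh_adjust(p.loc[ok, oc]) < alpha
    elif fdr_family == "all":
        ok = p.notna()
        flat = p.values[ok.values]
        adj = bh_adjust(flat)
        tmp = np.full(p.shape, False)
        tmp[ok.values] = adj < alpha
        flags[:] = tmp
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    flags.attrs["fdr_family"] = fdr_family
    return r, p, flags


@dataclass
class RidgeImportanceResult:
    importances_mean: pd.Series    # mean held-out R² drop per feature
    importances_sem: pd.Series
    baseline_score: float          # mean held-out R² of the intact model
    n_iter: int
    alpha_counts: dict             # penalty -> times chosen


def _fold_splits(n, folds, rng):
    idx = rng.permutation(n)
    return np.array_split(idx, folds)


def ridge_permutation_importance(features: pd.DataFrame, y, folds: int = 3,
                                 n_iter: int = 10000, seed: int = 0,
                                 alphas=None) -> RidgeImportanceResult:
    """Permutation feature importance of a ridge regression model.

    Per iteration: a fresh random non-overlapping ``folds``-fold split; the
    ridge penalty is chosen by cross-validated error over a logarithmic
    grid (1e-3…1e3, 13 points); each feature's importance is the decrease
    in held-out R² when that column alone is shuffled in the validation
    folds.  Importances are averaged over iterations with their SEM.

    Features are z-scored per column before fitting so penalties are
    comparable across bands.  Ridge solutions come from a per-fold SVD,
    which yields all penalties at once.
    """
    X = features.select_dtypes(np.number).to_numpy(float)
    names = list(features.select_dtypes(np.number).columns)
    y = np.asarray(y, float)
    n, d = X.shape
    if np.ptp(y) == 0:
        raise ValueError("degenerate outcome: y is constant")
    if n < folds:
        raise ValueError(f"need at least {folds} samples")
    X = (X - X.mean(0)) / (X.std(0) + 1e-12)
    yc = y - y.mean()
    ss_tot = float((yc**2).sum())
    if alphas is None:
        alphas = np.logspace(-3, 3, 13)
    alphas = np.asarray(alphas, float)
    rng = np.random.default_rng(seed)

    def _fold_betas(splits, which_alphas):
        """Per-fold ridge solutions for the requested penalties."""
        out = []
        for k in range(folds):
            val = splits[k]
            tr = np.concatenate([splits[j] for j in range(folds) if j != k])
            U, s, Vt = np.linalg.svd(X[tr], full_matrices=False)
            uty = U.T @ yc[tr]
            # beta(alpha) = V diag(s/(s^2+alpha)) U'y, all alphas at once
            shrink = s[:, None] / (s[:, None] ** 2 + which_alphas[None, :])
            out.append((val, Vt.T @ (shrink * uty[:, None])))
        return out

    imp_sum = np.zeros(d)
    imp_sq = np.zeros(d)
    base_sum = 0.0
    alpha_counts: dict = {}
    for _ in range(n_iter):
        # penalty chosen by CV on one split; importance scored on a fresh
        # independent split so penalty selection cannot leak into the score
        sel = _fold_betas(_fold_splits(n, folds, rng), alphas)
        sse_alpha = np.zeros(len(alphas))
        for val, betas in sel:
            pred = X[val] @ betas
            sse_alpha += ((yc[val][:, None] - pred) ** 2).sum(axis=0)
        best = int(np.argmin(sse_alpha))
        a = float(alphas[best])
        alpha_counts[a] = alpha_counts.get(a, 0) + 1

        sse_base = 0.0
        sse_feat = np.zeros(d)
        for val, betas in _fold_betas(_fold_splits(n, folds, rng),
                                      np.array([a])):
            beta = betas[:, 0]
            Xv = X[val]
            resid = yc[val] - Xv @ beta
            sse_base += float(resid @ resid)
            perm = rng.permutation(len(val))
            delta = (Xv[perm] - Xv) * beta[None, :]     # per-feature shift
            shifted = resid[:, None] - delta
            sse_feat += (shifted**2).sum(axis=0)
        score_base = 1.0 - sse_base / ss_tot
        score_feat = 1.0 - sse_feat / ss_tot
        drop = score_base - score_feat
        imp_sum += drop
        imp_sq += drop**2
        base_sum += score_base

    mean = imp_sum / n_iter
    var = imp_sq / n_iter - mean**2
    sem = np.sqrt(np.maximum(var, 0) / n_iter)
    return RidgeImportanceResult(
        importances_mean=pd.Series(mean, index=names),
        importances_sem=pd.Series(sem, index=names),
        baseline_score=base_sum / n_iter,
        n_iter=n_iter,
        alpha_counts=alpha_counts,
    )


def univariate_r2(x, y):
    """Simple OLS regression of y on x: (R², two-sided p, slope sign)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = sstats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), int(np.sign(res.slope))


def stepwise_select(candidates: pd.DataFrame, y, p_enter: float = 0.05,
                    p_remove: float = 0.10):
    """Forward stepwise linear regression with backward pruning.

    Adds the candidate with the smallest partial-F p-value while it is
    below ``p_enter``; after each addition removes included predictors
    whose p rises above ``p_remove``.  An empty selection is a valid
    outcome, not an error.  Returns a dict with ``selected``, ``coef``,
    ``r2`` and ``pvalues``.
    """
    import statsmodels.api as sm

    X = candidates.select_dtypes(np.number)
    y = np.asarray(y, float)
    selected: list = []
    while True:
        remaining = [c for c in X.columns if c not in selected]
        best_p, best_c = np.inf, None
        for c in remaining:
            model = sm.OLS(y, sm.add_constant(X[selected + [c]])).fit()
            pv = model.pvalues[c]
            if pv < best_p:
                best_p, best_c = pv, c
        if best_c is None or best_p >= p_enter:
            break
        selected.append(best_c)
        while selected:
            model = sm.OLS(y, sm.add_constant(X[selected])).fit()
            worst = model.pvalues[selected].idxmax()
            if model.pvalues[worst] > p_remove:
                selected.remove(worst)
            else:
                break
    if not selected:
        return {"selected": [], "coef": {}, "r2": 0.0, "pvalues": {}}
    model = sm.OLS(y, sm.add_constant(X[selected])).fit()
    return {
        "selected": list(selected),
        "coef": model.params.to_dict(),
        "r2": float(model.rsquared),
        "pvalues": model.pvalues.to_dict(),
    }


def wilcoxon_paired(a, b):
    """Two-sided Wilcoxon signed-rank test on paired values: (z, p).

    All-zero differences give (0, 1).  z is the normal-approximation
    standardised statistic; p uses the exact null for small samples
    without ties.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = sstats.wilcoxon(a, b, alternative="two-sided", method="auto")
    nz = d[d != 0]
    n = len(nz)
    mu = n * (n + 1) / 4
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (res.statistic - mu) / sd if sd > 0 else 0.0
    return float(z), float(res.pvalue)
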