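"""Longitudinal tracking of wireless theta episodes.

Aligns repeated resting-state episodes with clinical phases (crossover:
pre/post sham, pre/post active, washout) and momentary VAS mood/anxiety
ratings: daily alignment of mean theta with HAMD (washout collapsed to a
single averaged point, both variables z-scored within patient), per-band
post-sham vs post-active paired contrasts with BH-FDR across bands, and
pooled episode-level state correlations (theta↔anxiety, theta↔mood,
anxiety↔mood) after within-patient centring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .outcomes import bh_adjust, wilcoxon_paired

__all__ = ["daily_align", "phase_contrast", "state_correlation"]

BAND_COLS = ["pow_theta", "pow_alpha", "pow_lbeta", "pow_hbeta", "pow_gamma"]


def daily_align(series: pd.DataFrame, hamd: pd.DataFrame) -> pd.DataFrame:
    """Pair daily mean theta with daily HAMD, z-scored within patient.

    ``series`` needs columns patient_id, day, phase, pow_theta; ``hamd``
    needs patient_id, day, hamd.  Episodes are averaged per day; all
    washout days of a patient collapse to one averaged point (collapse
    happens *before* normalisation); finally theta and HAMD are z-scored
    within patient.  Zero-variance patients are flagged and excluded
    (listed in ``result.attrs["excluded"]``).
    """
    daily = (series.groupby(["patient_id", "day"], as_index=False)
             .agg(pow_theta=("pow_theta", "mean"), phase=("phase", "first")))
    merged = daily.merge(hamd, on=["patient_id", "day"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping days between episodes and HAMD")

    rows = []
    for pid, grp in merged.groupby("patient_id"):
        wash = grp[grp["phase"] == "washout"]
        keep = grp[grp["phase"] != "washout"].copy()
        if not wash.empty:
            rows.append(pd.DataFrame({
                "patient_id": [pid], "day": [wash["day"].mean()],
                "phase": ["washout"], "pow_theta": [wash["pow_theta"].mean()],
                "hamd": [wash["hamd"].mean()],
            }))
        rows.append(keep)
    collapsed = pd.concat(rows, ignore_index=True)

    excluded = []
    out = []
    for pid, grp in collapsed.groupby("patient_id"):
        g = grp.copy()
        for col in ("pow_theta", "hamd"):
            sd = g[col].std(ddof=0)
            if sd == 0 or np.isnan(sd):
                excluded.append((pid, col))
                g = None
                break
            g[f"{col}_z"] = (g[col] - g[col].mean()) / sd
        if g is not None:
            out.append(g)
    result = (pd.concat(out, ignore_index=True) if out
              else collapsed.iloc[0:0].copy())
    result.attrs["excluded"] = excluded
    return result


def phase_contrast(series: pd.DataFrame, phase_a: str = "post-sham",
                   phase_b: str = "post-active", bands=None,
                   alpha: float = 0.05, min_patients: int = 5) -> pd.DataFrame:
    """Within-patient paired band-power contrast between two phases.

    Per band: each patient's episode-mean power in ``phase_a`` vs
    ``phase_b``; two-sided Wilcoxon signed-rank across patients; BH-FDR
    over the five bands.  Patients missing either phase are dropped (count
    in ``result.attrs["dropped"]``).
    """
    bands = bands or [c for c in BAND_COLS if c in series.columns]
    means = series.groupby(["patient_id", "phase"])[bands].mean()
    pa = means.xs(phase_a, level="phase")
    pb = means.xs(phase_b, level="phase")
    common = pa.index.intersection(pb.index)
    dropped = sorted(set(pa.index.symmetric_difference(pb.index)))
    if len(common) < min_patients:
        raise ValueError(
            f"only {len(common)} patients have both phases; need {min_patients}"
        )
    rows = []
    for band in bands:
        z, p = wilcoxon_paired(pa.loc[common, band], pb.loc[common, band])
        rows.append({"band": band, "n": len(common),
                     "mean_a": float(pa.loc[common, band].mean()),
                     "mean_b": float(pb.loc[common, band].mean()),
                     "z": z, "p": p})
    out = pd.DataFrame(rows).set_index("band")
    out["p_fdr"] = bh_adjust(out["p"])
    out["significant"] = out["p_fdr"] < alpha
    out.attrs["dropped"] = dropped
    return out


def state_correlation(series: pd.DataFrame, min_episodes: int = 20,
                      center_within_patient: bool = True) -> pd.DataFrame:
    """Pooled episode-level Spearman correlations among theta, anxiety, mood.

    Episodes are pooled across patients (matching the all-episode design);
    within-patient centring first removes between-patient offsets so the
    pooled correlation reflects state covariation, not trait differences.
    """
    cols = {"pow_theta": "theta", "vas_anxiety": "anxiety", "vas_mood": "mood"}
    df = series[["patient_id", *cols]].rename(columns=cols).dropna()
    if len(df) < min_episodes:
        raise ValueError(f"need at least {min_episodes} pooled episodes")
    vals = df[["theta", "anxiety", "mood"]]
    if center_within_patient:
        vals = vals - vals.groupby(df["patient_id"]).transform("mean")
    pairs = [("theta", "anxiety"), ("theta", "mood"), ("anxiety", "mood")]
    rows = []
    for u, v in pairs:
        r, p = sstats.spearmanr(vals[u], vals[v])
        rows.append({"pair": f"{u}~{v}", "r": float(r), "p": float(p),
                     "n": len(vals)})
    return pd.DataFrame(rows).set_index("pair")
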