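"""Welch spectral estimation and relative band-power features.

The biomarker core: power spectral density from non-overlapping
512-sample rectangular windows (resolution fs/512, i.e. 0.977 Hz at
500 Hz), band powers summed over canonical bands θ (4–8), α (8–12),
lβ (13–20), hβ (21–35), γ (40–90 Hz), and expressed as percentages of
total 4–90 Hz power.  Relative scaling removes between-patient amplitude
differences from targeting and impedance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "SpectralProfile",
    "BandScheme",
    "DEFAULT_BANDS",
    "welch_psd",
    "relative_band_power",
    "average_regions",
    "FEATURE_COLUMNS",
    "build_feature_table",
]

NPERSEG = 512          # samples per Welch window, fixed by design
TOTAL_RANGE = (4.0, 90.0)   # Hz range defining "total power"


@dataclass
class SpectralProfile:
    """One-sided Welch PSD with its frequency grid and window count."""

    freqs: np.ndarray
    psd: np.ndarray
    resolution: float
    n_windows: int


_CANONICAL_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "lbeta": (13.0, 20.0),
    "hbeta": (21.0, 35.0),
    "gamma": (40.0, 90.0),
}


@dataclass
class BandScheme:
    """Named frequency bands (low, high) in Hz.

    A PSD bin belongs to a band iff its centre frequency f satisfies
    low <= f < high; the top band additionally includes f == high, so the
    90 Hz bin is counted in γ.  The 12–13, 20–21 and 35–40 Hz gaps stay
    unassigned, as in the canonical scheme.
    """

    bands: dict = field(default_factory=lambda: dict(_CANONICAL_BANDS))

    def bin_mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        mask = (freqs >= lo) & (freqs < hi)
        if hi >= max(h for _, h in self.bands.values()):
            mask |= np.isclose(freqs, hi)
        return mask

    @property
    def names(self):
        return list(self.bands)


DEFAULT_BANDS = BandScheme()


def _unmasked_windows(x: np.ndarray, mask: np.ndarray, nperseg: int) -> np.ndarray:
    """Stack non-overlapping nperseg windows drawn from contiguous unmasked
    runs of x. Returns array (n_windows, nperseg)."""
    wins = []
    n = len(x)
    # contiguous unmasked runs
    good = ~mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        seg = x[start:stop]
        k = len(seg) // nperseg
        if k:
            wins.append(seg[: k * nperseg].reshape(k, nperseg))
    if not wins:
        return np.empty((0, nperseg))
    return np.concatenate(wins, axis=0)


def welch_psd(rec: Recording, channel: str, nperseg: int = NPERSEG) -> SpectralProfile:
    """Welch PSD from non-overlapping rectangular windows of unmasked data.

    Windows are drawn only from contiguous artifact-free runs, then the
    per-window periodograms are averaged.  Spectral resolution is
    fs/nperseg (0.977 Hz for fs=500, nperseg=512).
    """
    x = rec.channel(channel)
    wins = _unmasked_windows(x, rec.artifact_mask, nperseg)
    if wins.shape[0] == 0:
        retained = float((~rec.artifact_mask).sum() / rec.fs)
        raise ValueError(
            f"insufficient unmasked data for a {nperseg}-sample window "
            f"(retained {retained:.1f} s)"
        )
    freqs, psd = sps.periodogram(wins, fs=rec.fs, window="boxcar",
                                 detrend=False, axis=-1)
    return SpectralProfile(
        freqs=freqs, psd=psd.mean(axis=0),
        resolution=rec.fs / nperseg, n_windows=wins.shape[0],
    )


def relative_band_power(sp: SpectralProfile, scheme: BandScheme = DEFAULT_BANDS,
                        total_range=TOTAL_RANGE) -> dict:
    """Relative band power in percent of total power over ``total_range``.

    Band power is the sum of PSD bins assigned to the band; the denominator
    is the summed PSD over the 4–90 Hz range of interest (frequencies below
    4 Hz are excluded to sidestep movement artifact and the 1/f background).
    """
    lo, hi = total_range
    in_total = (sp.freqs >= lo) & (sp.freqs <= hi)
    total = float(sp.psd[in_total].sum())
    if total <= 0:
        raise ValueError("zero total power in the 4-90 Hz range")
    return {
        name: 100.0 * float(sp.psd[scheme.bin_mask(sp.freqs, name)].sum()) / total
        for name in scheme.names
    }


def average_regions(table: pd.DataFrame, by=("patient", "region"),
                    value_cols=None) -> pd.DataFrame:
    """Average relative band powers across constituents (hemispheres or
    channels) of each (patient, region); records the constituent count.

    ``table`` is long-form with one row per constituent; rows with missing
    values are dropped per group (mean over available, n recorded).
    """
    value_cols = value_cols or [c for c in table.columns
                                if c in DEFAULT_BANDS.names]
    grouped = table.groupby(list(by), sort=True)
    out = grouped[value_cols].mean()
    out["n_constituents"] = grouped[value_cols[0]].count()
    return out.reset_index()


# Fixed feature order: 2 regions x 5 band powers + 5 coherence bands = 15.
FEATURE_COLUMNS = (
    [f"pow_bnst_{b}" for b in DEFAULT_BANDS.names]
    + [f"pow_pfc_{b}" for b in DEFAULT_BANDS.names]
    + [f"coh_{b}" for b in DEFAULT_BANDS.names]
)


def build_feature_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assemble the fixed 15-column physiological feature table.

    Expects a per-patient frame containing the 15 named feature columns
    (BNST and prefrontal band powers plus prefrontal-BNST coherence per
    band); patients missing any feature are excluded and logged in
    ``result.attrs['excluded']``.
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks feature columns {missing_cols}")
    ft = cohort.set_index("patient_id")[FEATURE_COLUMNS] \
        if "patient_id" in cohort.columns else cohort[FEATURE_COLUMNS]
    complete = ft.dropna()
    excluded = sorted(set(ft.index) - set(complete.index))
    complete = complete.sort_index()
    complete.attrs["excluded"] = excluded
    return complete
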