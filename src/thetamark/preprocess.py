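"""Deterministic conditioning of recordings.

Mirrors the perioperative/wireless LFP-EEG conditioning chain: bipolar
re-referencing against volume conduction, a zero-phase 1 Hz order-2
Butterworth high-pass, band-stop notches at the line (50 Hz) or sensing
(40 Hz) frequency and harmonics, automated amplitude/variance artifact
rejection with a 50 %-masked exclusion rule, and anti-aliased
down-sampling.  All filters are applied forward-backward (zero phase), so
oscillatory peaks are not shifted in time; this squares each filter's
magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "bipolar_rereference",
    "highpass_1hz",
    "bandstop_harmonics",
    "ArtifactPolicy",
    "reject_artifacts",
    "resample_to",
]


def bipolar_rereference(rec: Recording, pairs) -> Recording:
    """Re-reference to bipolar montage: one channel per (anode, cathode) pair.

    Each output channel is the sample-wise difference first-minus-second;
    common-mode activity (volume conduction) cancels.
    """
    out = []
    labels = []
    for a, b in pairs:
        out.append(rec.channel(a) - rec.channel(b))
        labels.append(f"{a}-{b}")
    new = rec.copy_with(samples=np.array(out), channel_labels=labels,
                        montage="bipolar")
    new.log.append(f"bipolar_rereference {labels}")
    return new


def highpass_1hz(rec: Recording, cutoff: float = 1.0, order: int = 2) -> Recording:
    """Zero-phase order-2 Butterworth high-pass (default 1 Hz); removes DC
    and slow drift below the band of interest."""
    if rec.fs <= 2 * cutoff:
        raise ValueError(f"fs={rec.fs} too low for a {cutoff} Hz high-pass")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    new = rec.copy_with(samples=filtered)
    new.log.append(f"highpass {cutoff} Hz order {order} zero-phase")
    return new


def bandstop_harmonics(rec: Recording, base: float, upper: float = None,
                       width: float = 2.0, order: int = 2) -> Recording:
    """Zero-phase band-stop at ``base`` and all harmonics below Nyquist.

    Notches of half-width ``width`` Hz (default ±2) are placed at k×base
    for every k with k×base < min(upper, fs/2).  Use base=50 for mains,
    base=40 for the wireless sensing noise.
    """
    nyq = rec.fs / 2.0
    if base >= nyq:
        raise ValueError(f"base {base} Hz is above Nyquist ({nyq} Hz)")
    top = nyq if upper is None else min(upper, nyq)
    data = rec.samples
    freqs = []
    k = 1
    while k * base < top:
        f0 = k * base
        lo, hi = f0 - width, f0 + width
        if hi >= nyq:      # clip a notch straddling Nyquist
            hi = nyq * 0.999
        sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
        freqs.append(f0)
        k += 1
    new = rec.copy_with(samples=data)
    new.log.append(f"bandstop base {base} Hz at {freqs} (±{width} Hz)")
    return new


@dataclass
class ArtifactPolicy:
    """Windowed amplitude/variance rejection thresholds.

    ``amp_mult``: a window is artifactual when its peak absolute amplitude
    exceeds ``amp_mult`` × the recording's robust (median-based) scale.
    ``var_z``: or when the log-variance of the window lies more than
    ``var_z`` robust z-units from the across-window median.
    ``window_s``: window length in seconds (non-overlapping).
    """

    amp_mult: float = 6.0
    var_z: float = 5.0
    window_s: float = 1.0


def reject_artifacts(rec: Recording, policy: ArtifactPolicy = None) -> Recording:
    """Mask artifactual windows; flag the dataset "excluded" above 50 % masked.

    Deterministic stand-in for operator-guided artifact review: windows whose
    amplitude or variance exceed the policy's robust thresholds in any channel
    are masked, and downstream epoching skips masked samples.  A recording
    with more than half its samples masked is marked ``meta["excluded"]``,
    matching the cohort rule that dropped datasets with noise exceeding 50 %.
    """
    policy = policy or ArtifactPolicy()
    n = rec.n_times
    win = max(int(round(policy.window_s * rec.fs)), 1)
    n_win = n // win
    mask = rec.artifact_mask.copy()
    for ch in rec.samples:
        scale = 1.4826 * np.median(np.abs(ch - np.median(ch))) + 1e-12
        segs = ch[: n_win * win].reshape(n_win, win)
        peak = np.max(np.abs(segs), axis=1)
        logvar = np.log(np.var(segs, axis=1) + 1e-24)
        lv_med = np.median(logvar)
        lv_scale = 1.4826 * np.median(np.abs(logvar - lv_med)) + 1e-12
        bad = (peak > policy.amp_mult * scale) | (
            np.abs(logvar - lv_med) / lv_scale > policy.var_z
        )
        mask[: n_win * win] |= np.repeat(bad, win)
    new = rec.copy_with(artifact_mask=mask)
    frac = float(mask.mean())
    new.meta["masked_fraction"] = frac
    new.meta["retained_seconds"] = float((~mask).sum() / rec.fs)
    if frac > 0.5:
        new.meta["excluded"] = True
    new.log.append(f"reject_artifacts masked {frac:.1%}")
    return new


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased rational-ratio down-sampling (polyphase).

    Up-sampling is out of contract and rejected.  Duration is preserved
    within one sample.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling {rec.fs}->{target_fs} Hz is out of contract"
        )
    if target_fs == rec.fs:
        return rec.copy_with()
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.samples, up, down, axis=1)
    # carry the artifact mask over by nearest-sample lookup
    idx = np.minimum(
        (np.arange(data.shape[1]) * down / up).astype(int), rec.n_times - 1
    )
    new = rec.copy_with(samples=data, fs=float(target_fs),
                        artifact_mask=rec.artifact_mask[idx])
    new.log.append(f"resample {rec.fs} -> {target_fs} Hz ({up}/{down})")
    return new
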