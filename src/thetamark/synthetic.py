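"""Synthetic cohorts with known ground truth.

Every input the pipeline consumes can be generated here: two-site
coupled-oscillator recordings with a planted direction of theta-band
influence, patient cohorts whose clinical improvement depends linearly on
baseline theta power, affective-task rating tables whose bias score
tracks theta, fiber/E-field phantoms with one planted "responsive" tract,
and longitudinal episode series whose theta co-varies with momentary
anxiety and drops after active stimulation.

Ground truth (coupling coefficients, effect slopes, the planted fiber
index) is returned alongside each dataset; no pipeline stage reads it —
it exists for validation only.

Randomness: one master seed is expanded per sub-generator through
``numpy.random.SeedSequence([seed, STREAM])`` with fixed stream ids
(0 recording, 1 cohort, 2 affective, 3 fibers, 4 longitudinal, 5
mediation), so the whole study regenerates bit-identically from a single
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter

from .fibers import EFieldMap, FiberSet
from .recording import Recording
from .spectral import FEATURE_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_coupled_recording",
    "gen_cohort",
    "gen_affective_ratings",
    "gen_mediation_triple",
    "gen_fiber_phantom",
    "gen_longitudinal",
]

_STREAMS = {"recording": 0, "cohort": 1, "affective": 2, "fibers": 3,
            "longitudinal": 4, "mediation": 5}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], int(extra)])
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the emulated study: 500 Hz perioperative sampling,
    5-minute resting recordings, a 6 Hz (theta) oscillator with forward
    (PFC→BNST) coupling, 1/f background noise, 17 patients, and a
    negative theta→improvement slope calibrated so the population R² of
    the univariate theta regression is 0.55.
    """

    seed: int = 0
    fs: float = 500.0
    duration: float = 300.0
    oscillator_freq: float = 6.0
    osc_radius: float = 0.97          # pole radius of the AR(2) oscillator
    coupling_coeff: float = 0.4       # AR cross-term c
    coupling_direction: str = "forward"   # forward | backward | none
    noise_sd: float = 0.5             # 1/f background amplitude (signal units)
    one_over_f_exponent: float = 1.0
    line_noise_freq: float = None
    n_patients: int = 17
    # cohort effect model: improvement = intercept + slope*theta + noise
    effect_intercept: float = 0.9
    effect_slope: float = -0.06       # improvement units per % theta
    effect_noise_sd: float = 0.1357   # calibrated: population R² = 0.55
    theta_mean: float = 8.0           # % relative theta power
    theta_sd: float = 2.5
    # behavioural bias model: bias = b0 + b1*theta + noise
    bias_intercept: float = 0.9
    bias_slope: float = -0.08
    bias_noise_sd: float = 0.33

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_patients < 3:
            raise ValueError("n_patients must be at least 3")
        if self.effect_noise_sd < 0:
            raise ValueError("effect_noise_sd must be nonnegative")
        if self.coupling_direction not in ("forward", "backward", "none"):
            raise ValueError(f"bad coupling_direction {self.coupling_direction!r}")

    def var_coefficients(self):
        """The generating bivariate VAR(2): (A, sigma), driver = channel 0.

        Each channel is an AR(2) oscillator with poles at radius r and
        angle 2π f0/fs; the receiver additionally carries the lag-1 cross
        term c from the driver.
        """
        w = 2 * np.pi * self.oscillator_freq / self.fs
        a1 = 2 * self.osc_radius * np.cos(w)
        a2 = -self.osc_radius**2
        c = 0.0 if self.coupling_direction == "none" else self.coupling_coeff
        A = np.zeros((2, 2, 2))
        A[0] = [[a1, 0.0], [c, a1]]
        A[1] = [[a2, 0.0], [0.0, a2]]
        return A, np.eye(2)


def _one_over_f(n: int, fs: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-sd noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / (x.std() + 1e-30)


def gen_coupled_recording(config: SimConfig, seed: int = None,
                          extra: int = 0) -> Recording:
    """Two-channel recording ("PFC", "BNST") from a stable bivariate AR
    process superposed on 1/f background noise.

    With ``coupling_direction="forward"`` the PFC channel drives BNST at
    the oscillator frequency via the lag-1 cross term; "backward" swaps
    the roles; "none" leaves the channels independent.  The generating
    coefficients are recorded in ``meta``.
    """
    from .var_theory import spectral_radius

    A, sigma = config.var_coefficients()
    rad = spectral_radius(A)
    if rad >= 1.0:
        raise ValueError(
            f"requested VAR is unstable: companion spectral radius {rad:.4f}"
        )
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "recording", extra)
    n = int(round(config.fs * config.duration))
    burn = int(round(2.0 * config.fs))
    a1, a2 = A[0, 0, 0], A[1, 0, 0]
    c = A[0, 1, 0]
    den = [1.0, -a1, -a2]
    e = rng.standard_normal((2, n + burn))
    drv = sps.lfilter([1.0], den, e[0])
    rcv = sps.lfilter([0.0, c], den, drv) + sps.lfilter([1.0], den, e[1])
    drv, rcv = drv[burn:], rcv[burn:]
    drv = drv / (drv.std() + 1e-30)
    rcv = rcv / (rcv.std() + 1e-30)
    if config.noise_sd > 0:
        drv = drv + config.noise_sd * _one_over_f(
            n, config.fs, config.one_over_f_exponent, rng)
        rcv = rcv + config.noise_sd * _one_over_f(
            n, config.fs, config.one_over_f_exponent, rng)
    if config.line_noise_freq:
        t = np.arange(n) / config.fs
        line = 0.5 * np.sin(2 * np.pi * config.line_noise_freq * t)
        drv = drv + line
        rcv = rcv + line
    if config.coupling_direction == "backward":
        pfc, bnst = rcv, drv
    else:
        pfc, bnst = drv, rcv
    return Recording(
        samples=np.vstack([pfc, bnst]), fs=config.fs,
        channel_labels=["PFC", "BNST"],
        meta={"A": A, "sigma": sigma, "direction": config.coupling_direction,
              "oscillator_freq": config.oscillator_freq, "seed": seed},
        log=["gen_coupled_recording"],
    )


def theta_calibrated_recording(theta_pct: float, fs: float = 500.0,
                               duration: float = 60.0, seed: int = 0,
                               extra: int = 0,
                               one_over_f_exponent: float = 1.0) -> Recording:
    """Single-channel recording whose relative theta power matches a target.

    A 6 Hz AR(2) oscillator is mixed with 1/f background at the amplitude
    that makes the *measured* theta share of 4–90 Hz power (Welch,
    512-sample rectangular windows — leakage included) equal ``theta_pct``;
    the amplitude is found by bisection against that measurement.  Targets
    below the background's own theta share are reached by attenuating the
    background's sub-8 Hz spectral content instead.
    """
    rng = _rng(seed, "recording", 7919 + extra)
    n = int(round(fs * duration))
    r_pole, f0 = 0.95, 6.0
    a1 = 2 * r_pole * np.cos(2 * np.pi * f0 / fs)
    a2 = -r_pole**2
    osc = sps.lfilter([1.0], [1.0, -a1, -a2],
                      rng.standard_normal(n + 1000))[1000:]
    osc /= osc.std()
    bg = _one_over_f(n, fs, one_over_f_exponent, rng)

    def measured_share(x):
        f, p = sps.welch(x, fs=fs, window="boxcar", nperseg=512, noverlap=0,
                         detrend=False)
        tot = p[(f >= 4) & (f <= 90)].sum()
        return 100.0 * p[(f >= 4) & (f < 8)].sum() / tot

    spec_bg = np.fft.rfft(bg)
    freqs_full = np.fft.rfftfreq(n, 1 / fs)
    low_band = freqs_full < 8.0

    def attenuated_bg(g):
        spec = spec_bg.copy()
        spec[low_band] *= g
        return np.fft.irfft(spec, n)

    if measured_share(bg) <= theta_pct:
        # raise theta: bisect the oscillator mixing amplitude
        lo, hi = 0.0, 1.0
        while measured_share(hi * osc + bg) < theta_pct and hi < 1e4:
            hi *= 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if measured_share(mid * osc + bg) < theta_pct:
                lo = mid
            else:
                hi = mid
        mix = 0.5 * (lo + hi)
        x = mix * osc + bg
    else:
        # lower theta: bisect an attenuation of the background's <8 Hz
        # content (the sub-4 Hz 1/f mass leaks into theta through the
        # rectangular Welch windows, so it must shrink along with theta)
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if measured_share(attenuated_bg(mid)) < theta_pct:
                lo = mid
            else:
                hi = mid
        x = attenuated_bg(0.5 * (lo + hi))
        mix = 0.0
    return Recording(samples=x[None, :], fs=fs, channel_labels=["BNST"],
                     meta={"theta_target_pct": theta_pct, "mix": mix},
                     log=["theta_calibrated_recording"])


@dataclass
class GroundTruth:
    """What the generator planted; read only by tests and reports."""

    seed: int
    theta: np.ndarray = None                # per-patient true theta (%)
    improvement_true: dict = field(default_factory=dict)  # horizon -> array
    effect_slope: float = None
    effect_noise_sd: float = None
    bias_slope: float = None
    bias: np.ndarray = None
    a_true: float = None                    # X->M path (mediation scale)
    b_true: float = None                    # M->Y path
    indirect_true: float = None
    planted_fiber: int = None
    fiber_weights_true: np.ndarray = None
    anxiety_theta_slope: float = None
    active_theta_drop: float = None


_SCALES = {
    # name: (baseline mean, baseline sd, instrument range, higher_is_worse)
    "hamd": (24.0, 3.5, (0, 52), True),
    "madrs": (30.0, 4.0, (0, 60), True),
    "hama": (22.0, 4.0, (0, 56), True),
    "dars": (40.0, 6.0, (17, 85), False),
}
HORIZONS = ("3m", "6m", "12m")


def gen_cohort(config: SimConfig, with_recordings: bool = False):
    """Per-patient feature/score/bias table with one informative feature.

    The BNST theta column carries the planted effect: improvement =
    intercept + slope×theta + noise.  The other 14 physiological features
    are nuisance draws with zero true effect.  Baseline and follow-up
    clinical scores are derived from the improvement fractions and clipped
    to instrument ranges.  With ``with_recordings=True`` each patient also
    receives a BNST recording whose measured relative theta power matches
    the drawn value (column ``recording``).

    Returns ``(cohort, truth)``.
    """
    rng = _rng(config.seed, "cohort")
    n = config.n_patients
    theta = np.clip(rng.normal(config.theta_mean, config.theta_sd, n), 1.0, 30.0)
    cohort = pd.DataFrame({"patient_id": [f"P{i+1:02d}" for i in range(n)]})
    nuisance_means = {"theta": 8, "alpha": 10, "lbeta": 12, "hbeta": 15,
                      "gamma": 20}
    for col in FEATURE_COLUMNS:
        band = col.rsplit("_", 1)[-1]
        if col == "pow_bnst_theta":
            cohort[col] = theta
        elif col.startswith("coh_"):
            cohort[col] = np.clip(rng.normal(30, 6, n), 2, 95)
        else:
            m = nuisance_means[band]
            cohort[col] = np.clip(rng.normal(m, m / 4, n), 0.5, 60)

    improvement_true = {}
    for k, horizon in enumerate(HORIZONS):
        lin = config.effect_intercept + config.effect_slope * theta
        noise_sd = config.effect_noise_sd * (1.0 + 0.15 * k)
        imp = lin + rng.normal(0, noise_sd, n)
        improvement_true[horizon] = lin
        for scale, (mu, sd, (lo, hi), worse) in _SCALES.items():
            if k == 0:
                base = np.clip(np.round(rng.normal(mu, sd, n)), lo, hi)
                cohort[f"{scale}_baseline"] = base
            base = cohort[f"{scale}_baseline"].to_numpy()
            if worse:
                post = base * (1.0 - imp)
            else:      # DARS rises when the patient improves
                post = base * (1.0 + 0.5 * imp)
            cohort[f"{scale}_{horizon}"] = np.clip(np.round(post), lo, hi)

    bias = (config.bias_intercept + config.bias_slope * theta
            + rng.normal(0, config.bias_noise_sd, n))
    cohort["negative_bias"] = bias

    if with_recordings:
        cohort["recording"] = [
            theta_calibrated_recording(t, fs=config.fs,
                                       duration=min(config.duration, 60.0),
                                       seed=config.seed, extra=i)
            for i, t in enumerate(theta)
        ]

    var_theta = config.theta_sd**2
    a_true = (config.bias_slope * var_theta
              / (config.bias_slope**2 * var_theta + config.bias_noise_sd**2))
    truth = GroundTruth(
        seed=config.seed, theta=theta, improvement_true=improvement_true,
        effect_slope=config.effect_slope, effect_noise_sd=config.effect_noise_sd,
        bias_slope=config.bias_slope, bias=bias,
        a_true=a_true, b_true=config.effect_slope,
        indirect_true=a_true * config.effect_slope,
    )
    return cohort, truth


def gen_affective_ratings(bias: float, seed: int = 0, extra: int = 0,
                          n_per_cell: int = 5, rating_sd: float = 5.0
                          ) -> pd.DataFrame:
    """Trial-level VAS rating table realising a given arousal-bias score.

    Ten images per condition, half rated for valence and half for arousal
    (``n_per_cell`` each).  Cell means are set so that
    (positive − negative)/neutral arousal equals ``bias`` exactly; trial
    noise is re-centred within each cell to preserve the means.
    """
    rng = _rng(seed, "affective", extra)
    neutral = 50.0
    means = {
        ("positive", "arousal"): neutral + neutral * bias / 2,
        ("negative", "arousal"): neutral - neutral * bias / 2,
        ("neutral", "arousal"): neutral,
        ("positive", "valence"): 70.0,
        ("neutral", "valence"): 50.0,
        ("negative", "valence"): 30.0,
    }
    rows = []
    for (cond, dim), m in means.items():
        vals = m + rng.normal(0, rating_sd, n_per_cell)
        vals = vals - vals.mean() + m       # exact cell mean
        vals = np.clip(vals, 0, 100)
        rows += [(cond, dim, float(v)) for v in vals]
    return pd.DataFrame(rows, columns=["condition", "dimension", "rating"])


def gen_mediation_triple(n: int = 17, a_true: float = -0.5,
                         b_true: float = -0.6, c_true: float = 0.0,
                         noise_sd: float = 0.6, seed: int = 0):
    """Standardised mediation triple X → M → Y with known paths.

    X ~ N(0,1); M = a·X + e_m; Y = c′·X + b·M + e_y with independent
    N(0, noise_sd²) errors.  Returns ``(X, M, Y, truth)``.
    """
    rng = _rng(seed, "mediation")
    X = rng.standard_normal(n)
    M = a_true * X + rng.normal(0, noise_sd, n)
    Y = c_true * X + b_true * M + rng.normal(0, noise_sd, n)
    truth = GroundTruth(seed=seed, a_true=a_true, b_true=b_true,
                        indirect_true=a_true * b_true)
    return X, M, Y, truth


def gen_fiber_phantom(n_fibers: int = 50, n_patients: int = 17, seed: int = 0,
                      theta: np.ndarray = None, weight_noise_sd: float = 0.05,
                      grid_shape=(40, 40, 40), voxel_mm: float = 2.0):
    """Fiber/E-field phantom with one planted theta-responsive tract.

    Fibers are 3-D polylines on a ``grid_shape`` voxel grid at
    ``voxel_mm`` resolution.  Each patient's field is a smooth positive
    random background plus a Gaussian blob centred on the planted fiber
    whose amplitude is a monotone (linear) function of that patient's
    theta value plus noise; every other fiber keeps a safety distance from
    the blob, so its maximal field engagement is independent of theta.

    Returns ``(FiberSet, [EFieldMap per patient], truth)``.
    """
    if n_fibers < 2:
        raise ValueError("need at least 2 fibers")
    rng = _rng(seed, "fibers")
    extent = np.array(grid_shape) * voxel_mm
    center = extent / 2.0
    if theta is None:
        theta = np.clip(rng.normal(8.0, 2.5, n_patients), 1.0, 30.0)
    theta = np.asarray(theta, float)

    planted_idx = int(rng.integers(n_fibers))
    fibers = []
    for i in range(n_fibers):
        if i == planted_idx:
            z = np.linspace(2.0, extent[2] - 2.0, 25)
            wiggle = 2.0 * np.sin(np.linspace(0, 2 * np.pi, 25))
            pts = np.column_stack([center[0] + wiggle, np.full(25, center[1]), z])
        else:
            while True:
                c = rng.uniform(6.0, extent - 6.0)
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                ts = np.linspace(-20.0, 20.0, 11)
                pts = np.clip(c + np.outer(ts, d), 1.0, extent - 1.0)
                # keep the whole polyline clear of the planted blob
                if np.linalg.norm(pts - center, axis=1).min() > 16.0:
                    break
        fibers.append(pts)
    fiber_set = FiberSet(fibers=fibers)

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    idx = np.indices(grid_shape).reshape(3, -1).T
    mm = (idx + 0.5) * voxel_mm
    d2 = ((mm - center) ** 2).sum(axis=1).reshape(grid_shape)
    blob = np.exp(-d2 / (2 * 5.0**2))

    amp_true = 1.0 + 0.3 * (theta - theta.min())
    amp = amp_true + rng.normal(0, weight_noise_sd, n_patients)
    carve = d2 < 10.0**2     # background-free zone so the planted weight
    fields = []              # equals the blob amplitude exactly
    for p in range(n_patients):
        bg = np.abs(gaussian_filter(rng.standard_normal(grid_shape), 2.0))
        bg *= 0.3 / (bg.max() + 1e-30)
        bg[carve] = 0.0
        fields.append(EFieldMap(data=bg + amp[p] * blob, affine=affine.copy()))

    truth = GroundTruth(seed=seed, theta=theta, planted_fiber=planted_idx,
                        fiber_weights_true=amp)
    return fiber_set, fields, truth


_PHASES = ("pre-sham", "post-sham", "washout", "pre-active", "post-active")
_LONG_BANDS = {"theta": 9.0, "alpha": 10.0, "lbeta": 12.0, "hbeta": 15.0,
               "gamma": 20.0}


def gen_longitudinal(n_patients: int = 10, episodes_per_patient: int = 11,
                     seed: int = 0, anxiety_theta_slope: float = 0.5,
                     active_theta_drop: float = 2.0,
                     with_recordings: bool = False):
    """Crossover-phase episode series tracking theta against VAS ratings.

    Per episode: phase label, day index, VAS mood/anxiety in [0, 100] and
    relative band powers (%), where theta co-varies with the anxiety
    z-score at ``anxiety_theta_slope`` (% per z) and drops by
    ``active_theta_drop`` (%) in post-active episodes.  Mood shares a
    common factor with anxiety but carries no theta effect.  10 patients ×
    11 episodes reproduces the 110-episode structure.

    Returns ``(episodes, truth)``; with ``with_recordings=True`` an extra
    ``recording`` column holds a 415 Hz theta-calibrated snippet.
    """
    if not (8 <= episodes_per_patient <= 17):
        raise ValueError("episodes_per_patient must lie in 8-17")
    rng = _rng(seed, "longitudinal")
    rows = []
    for p in range(n_patients):
        base_theta = rng.normal(9.0, 1.5)
        order = _PHASES if p % 2 == 0 else tuple(reversed(_PHASES))
        phases = [order[int(i * len(order) / episodes_per_patient)]
                  for i in range(episodes_per_patient)]
        for ep, phase in enumerate(phases):
            anx = float(np.clip(rng.normal(55, 15), 0, 100))
            z = (anx - 55.0) / 15.0
            mood = float(np.clip(55 + 6 * z + rng.normal(0, 13), 0, 100))
            th = (base_theta + anxiety_theta_slope * z
                  - active_theta_drop * (phase == "post-active")
                  + rng.normal(0, 1.0))
            row = {
                "patient_id": f"P{p+1:02d}", "day": ep + 1, "phase": phase,
                "vas_anxiety": anx, "vas_mood": mood,
                "pow_theta": max(th, 0.1),
            }
            for band, mu in _LONG_BANDS.items():
                if band != "theta":
                    row[f"pow_{band}"] = max(mu + rng.normal(0, 1.0), 0.1)
            rows.append(row)
    episodes = pd.DataFrame(rows)
    if with_recordings:
        episodes["recording"] = [
            theta_calibrated_recording(t, fs=415.0, duration=10.0,
                                       seed=seed, extra=i)
            for i, t in enumerate(episodes["pow_theta"])
        ]
    truth = GroundTruth(seed=seed, anxiety_theta_slope=anxiety_theta_slope,
                        active_theta_drop=active_theta_drop)
    return episodes, truth
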