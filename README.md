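# thetamark

Theta-band intracranial biomarker pipeline for deep-brain-stimulation (DBS)
outcome prediction.

## The problem

In DBS trials for treatment-resistant depression targeting the bed nucleus of
the stria terminalis (BNST) and nucleus accumbens, a practical question is
whether baseline electrophysiology predicts who will respond to chronic
stimulation. The candidate biomarkers are spectral: relative band power of
BNST local field potentials and prefrontal EEG, their coherence, and the
direction of their theta-band interaction. `thetamark` implements the full
analysis chain from raw two-site recordings and clinical score tables to
predictive statistics, behavioural predictors, mediation, fiber scoring and
longitudinal tracking — together with a synthetic-cohort generator with known
ground truth, so that every stage is testable without access-restricted
patient data.

The pipeline computes, per patient:

- **Relative band power** — Welch PSD from non-overlapping 512-sample
  rectangular windows (0.977 Hz resolution at 500 Hz); band power in
  θ (4–8), α (8–12), lβ (13–20), hβ (21–35), γ (40–90 Hz) as a percentage of
  total 4–90 Hz power, which removes amplitude-scale differences from
  targeting and impedance.
- **Magnitude-squared coherence** — per 10-s epoch (50 % overlap) from
  512-sample Hann blocks at 50 % block overlap, averaged over epochs, in %.
- **Spectral Granger causality (GC)** — a bivariate MVAR model fitted by
  least squares pooled over 4-s windows, order chosen by BIC, stability
  checked; Geweke's frequency-domain causality
  `gc(f) = ln(S_rr / (S_rr − σ²_cond |H̃(f)|²/fs))` in both directions, with
  window re-pairing permutation tests and a time-reversal control (true
  causal direction flips under time reversal; SNR artifacts do not).
- **Outcome statistics** — improvement (pre − post)/pre per scale and
  horizon, responder (≥50 % HAMD decrease) and remission (HAMD-17 < 8)
  labels, Spearman correlation matrices with Benjamini–Hochberg FDR, a ridge
  regression over the 15 spectral features (2 regions × 5 band powers + 5
  coherence bands) with permutation feature importance (3-fold CV penalty
  selection, 10 000 iterations, importance = held-out R² drop on shuffling a
  column), univariate regressions, and forward stepwise selection.
- **Behaviour and mediation** — negative emotional arousal bias
  `(mean positive − mean negative)/mean neutral` from 0–100 VAS ratings of
  affective images; bootstrap mediation bias → theta → improvement with a
  rank-based inverse normal transform of the bias and a bias-corrected
  5000-sample bootstrap CI for the indirect effect a×b.
- **Fiber scoring** — each tractography streamline weighted by the maximal
  stimulation E-field magnitude it traverses (exact voxel traversal), per
  fiber a Spearman R against baseline physiology, significance at unadjusted
  p < 0.05, and weighted fiber density on a 2-mm grid.
- **Longitudinal tracking** — daily alignment of wireless theta with HAMD
  (washout averaged, within-patient z-scoring), post-sham vs post-active
  band contrasts (Wilcoxon + FDR across bands), and pooled episode-level
  state correlations of theta with momentary anxiety and mood.

## Worked example

Everything below runs on a synthetic 17-patient cohort in which lower BNST
theta is planted to predict larger clinical improvement:

```python
from thetamark import synthetic, spectral, outcomes, connectivity, mediation

cfg = synthetic.SimConfig(seed=7)          # study conditions, one seed
cohort, truth = synthetic.gen_cohort(cfg)
feats = spectral.build_feature_table(cohort)       # 17 x 15 features
imp = outcomes.improvement_table(cohort)

outcomes.univariate_r2(feats["pow_bnst_theta"], imp["hamd_improvement_3m"])
# (0.52, 0.0011, -1)      -- R², two-sided p, negative slope

res = outcomes.ridge_permutation_importance(
    feats, imp["hamd_improvement_3m"], n_iter=1000, seed=0)
res.importances_mean.sort_values(ascending=False).head(3)
# pow_bnst_theta    0.2278     <- planted informative feature ranks first
# pow_pfc_gamma     0.1101
# coh_alpha         0.0361

rec = synthetic.gen_coupled_recording(synthetic.SimConfig(seed=7, duration=60.0))
gc = connectivity.gc_pipeline(rec.channel("PFC"), rec.channel("BNST"), 500.0)
(gc.theta_fwd, gc.theta_rev)
# (3.031, 0.163)           -- top-down theta influence dominates
rev = connectivity.time_reverse_control(rec.channel("PFC"), rec.channel("BNST"), 500.0)
(rev.theta_fwd, rev.theta_rev)
# (0.375, 2.247)           -- and flips under time reversal, as it must

med = mediation.mediate(cohort["negative_bias"], cohort["pow_bnst_theta"],
                        imp["hama_improvement_3m"], n_boot=5000, seed=0,
                        apply_int=True)
(med.indirect, med.ci_lower, med.ci_upper)
# (0.074, 0.025, 0.185)    -- indirect effect via theta, CI excludes zero
```

The univariate R² of 0.52 sits near the generator's population calibration
(0.55); 3.03 vs 0.16 says the prefrontal→BNST direction carries essentially
all theta-band predictive influence in this recording, and the mediation CI
excluding zero indicates the behavioural bias acts on improvement through
theta rather than directly.

## Command line

```bash
thetamark synthesize --out study/ --seed 1      # miniature study directory
thetamark preprocess --in rec.txt --out clean.txt --line 50
thetamark features --in clean.txt
thetamark connectivity --in clean.txt --pair PFC:BNST
thetamark predict --cohort study/cohort.csv --horizon 3m
thetamark mediate --cohort study/cohort.csv
thetamark fibers --trk study/fibers.trk --fields 'study/efield_*.nii.gz' --target target.csv
thetamark track --episodes study/episodes.csv
thetamark run-all --seed 1 --out report/       # end-to-end, deterministic
```

## Layout

| module | contents |
|---|---|
| `synthetic` | ground-truth generators (recordings, cohorts, ratings, phantoms, episodes) |
| `recording`, `preprocess` | containers, I/O, filtering, artifact rejection, resampling |
| `spectral` | Welch PSD, band powers, feature table |
| `connectivity` | coherence, MVAR/BIC, spectral GC, permutation, time reversal |
| `var_theory` | closed-form spectra/GC of known VAR models (ground-truth route) |
| `outcomes` | improvements, labels, correlation/FDR, ridge importance, stepwise, Wilcoxon |
| `affective`, `mediation` | bias scores; INT + bootstrap mediation |
| `fibers` | E-field weights, fiber R-values, density maps, TRK/NIfTI I/O |
| `longitudinal` | daily alignment, phase contrasts, state correlations |
| `pipeline`, `cli` | config-driven end-to-end runs and the `thetamark` command |

See `docs/methods.md` for the models, parameter choices and limitations.
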