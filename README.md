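# cardioresp

Analysis pipeline for studying how **respiratory phase transitions** and
**RR-interval (RRI) velocity** modulate reaction times (RTs) in a delayed
matching-to-sample (DMTS) short-term memory task.

During quiet breathing the heart slows on exhalation and quickens on
inhalation (respiratory sinus arrhythmia, RSA). When a test cue appears at a
random point of the respiratory cycle, the retrieval interval — from cue
onset to button press — may contain an exhalation-to-inhalation transition
(EI, inspiratory onset), an inhalation-to-exhalation transition (IE), both,
or neither. This package implements, end to end and with a fully synthetic
cohort standing in for human recordings:

1. **Simulation** (`cardioresp.synthetic`) — 36 subjects × 30 blocks ×
   (4 sample cues, 10–13 s delay, 3 test cues); gamma-distributed breathing
   cycles (mean rate 0.278 Hz, CV ≈ 27 %), half-sine flow, IPFM heartbeats
   with RSA, lognormal RTs with injectable effects, ground-truth labels.
2. **Signal processing** (`cardioresp.signals`) — respiratory transition
   onsets as baseline zero crossings validated against a ±2 SD noise band;
   zero-phase 0.5–40 Hz ECG filtering; derivative-energy (Pan–Tompkins
   style) R-wave detection; RRI series with half-open interval lookup.
3. **Trial classification** (`cardioresp.classify`) — condition labels
   (INH/EXH pooled as NOt, IEt, EIt, double), 1st/2nd-half transition
   timing, RRI velocity ΔRRI = RRI(press) − RRI(cue) with per-subject
   high/low × positive/negative binning, and robust-z RT standardisation
   ((RT − median)/IQR over each subject's correct trials).
4. **Group statistics** (`cardioresp.stats`) — Shapiro–Wilk/Mauchly-driven
   branching between repeated-measures ANOVA (Greenhouse–Geisser) and
   Friedman tests, Wilcoxon/paired-t post hocs with Bonferroni correction,
   trial-level two-way ANOVA and Kruskal–Wallis analyses, and the
   frequency analyses linking velocity bins to transition timing.
5. **Multilevel models** (`cardioresp.mlm`) — per-2-block aggregation
   (15 windows/subject), grand normalisation + within-subject centring, and
   REML random-intercept models:

   Model 1: RT<sub>ij</sub> = b<sub>0j</sub> + b₁·EIt2nd<sub>ij</sub> + b₂·ΔRRI<sub>ij</sub> + b₃·Accuracy<sub>ij</sub> + r<sub>ij</sub>, b<sub>0j</sub> ~ N(β₀₀, u²)

   Model 2 replaces the EIt-2nd rate with the IEt-2nd rate.

The `analysis/` scripts narrate the full sequence; `cardioresp.pipeline`
and the `cardioresp` CLI run it as one reproducible pass.

## Worked example

```bash
python analysis/02_detect_and_classify.py --seed 7   # simulate + detect + classify
python analysis/04_multilevel_models.py  --seed 7    # windowed mixed models
```

The second step prints (seed 7, 36 subjects, detection-based labels):

```
## Model 1 (random intercept, REML; n=540 windows, 36 subjects)

| predictor | coefficient (SE) | p-value |
|---|---|---|
| EIt-2nd rate | 0.194 (0.0345) | 2.05e-08 |
| RRI velocity | 0.210 (0.0333) | 2.93e-10 |
| Accuracy | -0.077 (0.0282) | 0.00643 |
```

Read: windows in which more trials contained a late (2nd-half) inspiratory
onset had longer mean RTs; windows with rising RRI (cardiac deceleration)
likewise; windows with better accuracy had shorter RTs — all on the
normalised (z) scale, with subject baselines absorbed by the random
intercept. Model 2 shows the IEt-2nd rate carrying no comparable effect,
the signature that the two RT-prolonging mechanisms are distinct. The
group-level script (`03_group_stats.py`) shows the complementary pattern:
EIt-2nd is the largest half-condition robust-z RT, the high-positive
velocity bin the largest velocity bin, and high-positive velocities
concentrate in IEt trials while late EI transitions concentrate in the
high-negative bin — the temporal mismatch between the two effects.

`05_parameter_recovery.py` refits Model 1 on cohorts simulated with known
coefficients (0.21, 0.145, −0.118) and reports per-coefficient ±2 SE
recovery rates and null type-I error.

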