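# Methods

## The synthetic cohort

The generator emulates a cardiorespiratory DMTS experiment closely enough
that every downstream stage can be validated against exact ground truth.

**Respiration.** Cycle periods are i.i.d. gamma with mean `1/resp_rate_hz`
(default 0.278 Hz → 3.60 s) and coefficient of variation `resp_cv`
(default 0.268). The gamma family is chosen for positive support and
because only the mean and CV of the cycle distribution are constrained;
`resp_cv = 0` degenerates to exactly periodic breathing, which several
tests exploit. Each cycle opens with an EI transition (inspiratory onset);
inhalation occupies `insp_fraction` (default 0.4) of the cycle. Flow is a
positive half-sine during inhalation and a negative half-sine during
exhalation (amplitude 1, inhalation-positive; the convention is recorded in
trace metadata so detection is convention-agnostic), plus white Gaussian
noise (`noise_sd_flow = 0.07` ≈ 20 dB SNR against the 0.71 rms of the
half-sine train). A 12 s lead-in of pure baseline noise precedes breathing,
emulating the room-pressure baseline recording and providing the quiet
window for noise-SD estimation.

**Heartbeats.** Beat times come from integral pulse frequency modulation:
the instantaneous RR-interval target is `rri_base_s − rsa_amp_s` during
inhalation and `rri_base_s + rsa_amp_s` during exhalation (defaults 0.85 s
and 0.05 s), ramped linearly over `rsa_ramp_s = 0.4 s` at each transition;
beats fall where the integral of the instantaneous rate crosses successive
integers (random initial phase). This yields RRIs that shorten during
inhalation and lengthen during exhalation with an exhalation-minus-
inhalation contrast close to `2·rsa_amp_s` for phase-contained intervals
(the ramp shaves a few per cent; the test allows 20 %). The optional ECG
waveform is a sum of five-Gaussian PQRST templates (R amplitude 1 mV,
σ = 8 ms) centred at beat times plus Gaussian noise
(`noise_sd_ecg = 0.049` ≈ 10 dB SNR against the 0.156 mV signal rms).

**Task and behaviour.** Each of 30 blocks holds 4 sample cues (1 s on,
0.5 s gap), a uniform 10–13 s delay, and 3 test trials separated by 2 s
gaps; 90 test trials per subject, exactly 45 match/45 nonmatch, stimulus
identities drawn from the 6×6×6×6 (=1296) feature space. Base RTs are
lognormal with subject-specific mean (`rt_base_s = 1.0 s`,
`rt_base_sd_s = 0.15 s` between subjects, shape 0.25 within), clipped to
[0.2, 4] s. Two effects are injected in a single adjustment pass:

1. `beta_eit2nd_s` (default 0.25 s) is added when an EI transition falls in
   the second half of the base-RT window;
2. `beta_drri` (default 1.0 s/s) times the realized ΔRRI at the adjusted
   press time is then added.

Because the EI-in-2nd-half label depends on the final RT, the ground-truth
labels are recomputed from the final press time and stored; the injected
and realized labels can differ for marginal trials, which is intended — it
is exactly the circularity the adjustment-pass design resolves.
Correctness is Bernoulli with base 0.92 and a 0.05 decrement on trials
containing an EI transition (EIt and double), giving ≈ 90 % overall. A
latent attentional state (one standard-normal draw per block) adds
`attn_rt_s = 0.1 s` per SD to RTs and subtracts `attn_acc = 0.05` per SD
from the correctness probability, producing the within-subject
RT/accuracy covariation that the window-level models attribute to the
accuracy term; without it that coefficient would be pure noise, since mean
RT is computed over correct trials only and correctness is drawn after RT.

The effect-size defaults were fixed once, by requiring the generator to
reproduce the qualitative pattern the pipeline is meant to detect — the
EIt-2nd condition carrying the largest robust-z RT while the high-positive
velocity bin is simultaneously the largest bin. The two injections compete
through the physiology: EI transitions sit where RRIs start falling, so the
EIt effect leaks into the high-negative velocity bin, and IE transitions
sit where RRIs rise, so the velocity effect leaks into the IEt conditions.
At `beta_eit2nd_s = 0.25, beta_drri = 1.0` both orderings hold in
essentially every 36-subject cohort; materially weaker velocity effects
flip the bin ordering, materially stronger ones promote IEt-1st above
EIt-2nd.

**What the generator does not emulate** — sighs, breathing-rate drift,
movement and electrode artifacts, ectopic beats, asymmetric or variable
QRS morphology, RT sequential effects, learning/fatigue trends beyond the
block-level attentional state. Passing tests therefore demonstrate
correctness of the pipeline's logic and its detection margins under
white-noise conditions, not robustness to pathological recordings.

## Detection

**Respiratory transitions.** The flow trace is baseline-subtracted; the
noise SD is estimated from the task-free lead-in window. A candidate onset
is a zero crossing whose following excursion exceeds 2 SD of the baseline
noise before re-crossing zero (hysteresis); sub-threshold wiggles are
discarded. On noisy traces the crossing structure is read from a zero-phase
4th-order 5 Hz low-pass of the trace — an order of magnitude above the
respiratory band, so onsets move by only a few ms, while 1 kHz noise
chatter (which otherwise fragments every crossing) is suppressed; the
threshold still refers to the raw noise SD, and noise-free traces are used
as-is, preserving sample-exact recovery in the deterministic case. Strict
EI/IE alternation is enforced by dropping a repeated-type onset, and a
same-type onset within `min_phase_s = 0.5 s` marks a spurious micro-cycle
that is dropped whole (together with the intervening opposite onset).
Applying the debounce across opposite-type onsets would instead delete
genuine short inhalations, which the gamma cycle distribution produces at
the ~1 % level. Crossing times are refined by linear interpolation.

**R waves.** The ECG is band-passed 0.5–40 Hz with a zero-phase Butterworth
filter (no timing shift). Detection follows the classic derivative-energy
recipe: an internal 5–25 Hz band-pass (QRS energy band), derivative,
squaring, 150 ms moving-window integration, peak picking with a ≥ 200 ms
refractory period and an adaptive threshold anchored at 0.4 × the 90th
percentile of peak heights — the upper tail, because inter-beat noise peaks
outnumber QRS peaks at 1 kHz and would drag a median-anchored threshold
down. Detections are refined to the local maximum of the band-passed ECG.
A QC pass flags RRIs more than 3 subject-SDs from the subject mean, the
automated stand-in for manual beat review.

Measured on the default cohort (36 subjects): 99.9 % of transitions within
±30 ms at 20 dB flow SNR; R-wave sensitivity and precision 100.0 % at
10 dB ECG SNR (±5 ms).

## Classification conventions

* Only transitions strictly inside the open interval (cue, press) count; a
  transition exactly at cue or press belongs to neither trial side.
* The phase is undefined before the first detected transition (such trials
  are excluded and logged); after the last transition the trailing phase
  continues, so a press beyond it is classifiable.
* Half labels use the first transition of each type; a transition exactly
  at the RT midpoint counts as 2nd-half.
* An RRI owns the half-open interval (R<sub>n−1</sub>, R<sub>n</sub>]: an
  event coincident with an R wave belongs to the interval it terminates.
* ΔRRI = RRI(press interval) − RRI(cue interval); zero when both events
  share an interval; missing outside R-wave coverage. The before-cue
  variant subtracts the last RRI ending at or before the cue.
* Velocity bins are per subject and per sign: ratio r = |ΔRRI| / max
  |ΔRRI| of that sign, high bin at r ≥ c with c = 0.5 by default. The
  descriptive percentage labels sometimes attached to such bins ("30–100 %")
  conflict with the log-space boundary log₁₀(0.5) ⇒ 50 %; the formulaic
  boundary is authoritative here and c is configurable. ΔRRI = 0 goes to
  low_pos; the boundary ratio goes high; the maxima are taken over all
  trials with valid ΔRRI (binning is a physiological, not behavioural,
  partition).
* Robust z uses correct trials only — the analyses it feeds are
  correct-trial analyses — so median(z) = 0 and IQR(z) = 1 hold exactly
  within each subject's correct trials; subjects with IQR = 0 or fewer
  than 4 correct trials are flagged and excluded.
* A selection effect is inherent in the taxonomy: longer trials are more
  likely to straddle a transition, so transition conditions have elevated
  mean z even with no injected effects. Null-case tests therefore compare
  conditions with each other, never with zero.

## Group statistics

Shapiro–Wilk (per condition) decides the branch: repeated-measures ANOVA
with Greenhouse–Geisser correction when Mauchly rejects sphericity, and
paired-t post hocs, on normal-looking data; Friedman with Wilcoxon
signed-rank post hocs otherwise. The Bonferroni family is all k(k−1)/2
pairwise comparisons within one omnibus. Double-condition trials are
analysed trial-level in a 2×2 (IEt-half × EIt-half) fixed-effects ANOVA
with pooled-SD t post hocs; the first-test-trial restriction is analysed
trial-level by Kruskal–Wallis with exact rank-sum pairwise comparisons.
Omnibus tests are skipped with a warning below 3 complete subjects.

## Windowed multilevel models

Windows pool 2 consecutive blocks (6 test trials): mean RT over the
window's correct trials (an all-trials switch exists), accuracy and the
EIt-2nd/IEt-2nd occurrence rates over all trials (transition occurrence
does not depend on response correctness), mean ΔRRI over valid trials.
Windows without a correct trial lose their mean RT and drop from the fit.
Every variable is z-scored over all subject-windows; predictors are then
centred per subject (mean 0 within subject to numerical precision), while
RT is deliberately **not** subject-centred — a subject-centred response
would make the random intercept degenerate, so the intercept absorbs the
between-subject RT level instead; a `center_rt` flag provides the fully
centred variant for comparison. Estimation is REML via `statsmodels`
MixedLM with fixed slopes and a Gaussian random intercept per subject.
Fixed-effect p-values use the large-sample normal approximation; the df
method is recorded in the fit diagnostics. With 540 windows the normal
approximation is mild (±2 SE intervals cover the truth for 90–95 % of
replicates in the recovery study rather than the nominal 95.4 %); a test
cross-checks the REML point estimates against the R reference
implementation (lme4) to 10⁻⁵.

## Problem sizes and numerical choices

Simulation-based checks use: one 36-subject rendered cohort for detection
fidelity; 10⁴ randomised instances per brute-force-oracle comparison; 100
label-level cohorts for the effect-ordering rates; 100 recovery plus 200
null replicates (36 × 15 windows) for the model calibration — sizes chosen
so each check is statistically decisive while the whole suite runs in a
few minutes. Label-level simulation skips waveform rendering and runs the
IPFM integrator on a 10 ms grid with linear interpolation of beat times
(sub-ms accuracy); rendered simulation uses the full 1 kHz grid. All
randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning; holding seeds fixed, every stage is bit-reproducible.

## Known limitations

* The white-noise, fixed-morphology signal model understates real
  detection difficulty; the QC hooks (outlier RRIs, excluded trials,
  coverage gaps) are the intended attachment points for real data.
* Normal-approximation p-values for the mixed models are slightly
  anti-conservative at small window counts.
* The INH condition is rare by construction (short inhalation fraction ×
  short RTs), mirroring the motivating design's pooling of INH and EXH
  into NOt; analyses of INH alone are not supported.
* Double-condition trials are few per subject; the 2×2 trial-level ANOVA
  refuses to run (with a diagnostic) when a cell is empty at small scale.
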