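# Methods

## ASRT stimulus model

A session consists of `practice_blocks` (default 2) blocks of uniformly
random positions followed by `n_blocks` (default 20) test blocks of
`trials_per_block` (default 80, a multiple of 8) trials. Test blocks
alternate pattern and random elements starting with a pattern element; the
pattern is a uniformly sampled permutation of the four positions and its
phase continues seamlessly across the ten within-block repetitions and
across blocks, which keeps triplet statistics stationary (no reset is
modelled). By default a participant keeps one pattern across their three
sessions, consistent with measuring sequence-specific retention; a config
flag switches to fresh patterns per session.

Triplet classification always uses the raw stimulus stream: trial *t* is
high-probability iff its position is the cyclic pattern successor of the
position at *t−2* (within-block indexing; the first two trials of each
block stay unclassified and are excluded later anyway). Under this
structure a classifiable trial ends a high-probability triplet with
probability 0.5·1 + 0.5·(1/4) = 62.5%: pattern-ending triplets always
follow a pattern transition, random-ending ones hit it by chance. Among
random-ending triplets, trills (x-y-x) occur with probability 3/16 and
repetitions (x-x-x) with 1/16; pattern-ending triplets can be neither
because consecutive pattern elements are distinct.

## Exclusion and aggregation

Rules apply in a fixed order — practice blocks, first two stimuli per test
block, trills, repetitions — and each removed trial is attributed to the
first rule that catches it, which makes the exclusion report unambiguous
while the retained set itself is order-independent. Expected removal per
default session: 160 + 40 + 0.25·780 = 395 of 1,760 trials (22.4%,
printed as 22%). Incorrect responses are never removed: the epoch cell's
RT is the median over *correct* responses, accuracy the mean over *all*
retained responses. Cells with no correct response keep a missing median
and are flagged, not imputed; model fitting later drops missing rows with
a logged count.

## Generative model for reaction times

The simulator mirrors the analysis model. A participant's expected median
RT in a (session, epoch, trial-type) cell is

```
mu = b0 + b_grp·active + b_s2·[s=2] + b_s3·[s=3] + b_lpt·[lpt]
     + (b_epoch + u1)·epoch + b_gs2·active·[s=2] + b_gs3·active·[s=3] + u0
```

with `(u0, u1)` bivariate normal per participant. Shipped fixed-effect
defaults are the study's estimates on the ms scale (group 18.78,
session −43.55/−57.03, lpt 7.33, epoch −12.70, group × session
−21.01/−20.57); the intercept, which is not reported, is set to 600 ms as
a realistic older-adult four-choice median RT. Epoch enters linearly
(1–4), matching the single reported slope.

Trial-level RTs are log-normal around the (shocked) cell median —
positive support and right skew, the standard RT shape — with log-scale
SD 0.20 (≈20% coefficient of variation). Each cell additionally receives
a Gaussian occasion shock (`cell_sd`, default 33 ms) shared by its trials,
representing state fluctuations; this is the dominant epoch-level
residual, since the median over ~130–210 trials contributes only ~8–11 ms
of sampling noise. Accuracy is Bernoulli at `accuracy_base` = 0.97,
independent of condition: the task runs at ceiling and accuracy is not
analysed, only checked against the >95% regime.

Variance-component defaults were calibrated analytically and confirmed by
simulation (`analysis/07_calibrate_variances.py`): the fixed effects imply
~1,085 ms² of fixed variance over the balanced design, so hitting
marginal R² ≈ 0.09 and conditional R² ≈ 0.90 requires ~9,760 ms² of
random-effect variance and ~1,200 ms² of residual. With a random epoch
slope SD of 8 ms/epoch (E[epoch²] = 7.5) that leaves a random intercept
SD of ≈96 ms. The intercept–slope correlation defaults to 0 (unreported).
Note that at n = 35 the *realized* marginal R² of a single study moves
with the luck of the group draw (roughly 0.05–0.18); the bands are a
regime, not a constant.

Blinding guesses default to (0.50, 0.40, 0.10) over Active/Sham/"I don't
know", independent of true group — successful blinding with a small
don't-know share, as observed. Adverse-event counts are Poisson per
stimulation session with equal rates across groups (tingling 13/session,
the rarer categories 0.2–0.3), matching the study's null finding.

## Mixed-model inference

Estimation is maximum likelihood (never REML), because AIC comparisons
across fixed-effect structures require it; statsmodels' `MixedLM` is the
engine. The random structure `~ 1 + epoch | participant` (unstructured
2×2 covariance) is fixed across the candidate family, and candidate
formulas are closed under marginality (an interaction brings its main
effects). AIC = −2·logLik + 2·k with k counting fixed effects, the three
covariance parameters and the residual variance. Selection takes the
minimum-AIC candidate, breaking ties by fewer parameters then input
order; likelihood-ratio χ² tests are reported for every nested pair.

Wald t confidence intervals and p values use residual-style degrees of
freedom, df = rows − fixed parameters. (For the 840-row selected model
this gives values near, but not equal to, the t(826) the study prints; no
Satterthwaite/Kenward–Roger correction is attempted, and the report
always prints its df rule.) Standardized betas come from refitting after
z-scoring the response and numeric predictors — categorical dummies stay
untouched, so their standardized betas are in response-SD units. R² is
the Nakagawa–Schielzeth decomposition with the random-effect variance
averaged over the design rows (z′Σz with z = (1, epoch)).

Optimization tries L-BFGS first, then BFGS/CG/Powell on convergence
warnings, and finally accepts a boundary (singular) fit only if
statsmodels itself reports convergence; anything else raises with
diagnostics. Rank-deficient fixed-effect matrices and single-participant
inputs are rejected outright.

Learning indices are linear contrasts of the fitted coefficients with
delta-method CIs from the fixed-effect covariance: online
sequence-specific = the lpt coefficient; online visuomotor = the epoch
slope (at reference session when an epoch × session term is present);
offline visuomotor = session contrasts at the reference epoch coding, for
sham (session terms) and active (session + group × session); group
offline gain = the group × session terms themselves. Offline indices are
deliberately *model* contrasts, not epoch-edge differences. Descriptive
scores are model-free within-participant session-mean changes.

## Trial statistics

Pearson χ² is computed as Σ(O−E)²/E without continuity correction. The
exact test on the 2×3 blinding table is the Freeman–Halton extension
computed by full enumeration of tables with the observed margins under
the multivariate hypergeometric null (counts ≤ 35 make enumeration
exact and instant); the 2×2 path reproduces the classic Fisher test.
Baseline t-tests default to the pooled-variance (Student) form with a
Welch option; degenerate zero-variance inputs fall back to an exact
equality check rather than producing NaNs. Adverse events are compared
per category with unpaired t-tests on per-session counts (a
per-participant unit is available via config); categories observed in
one group only are flagged descriptively.

## Stimulation waveforms

The active signal is `(theta_pp/2)·sin(2πf_θt)` plus one gamma burst per
theta period: `cycles_per_burst` cycles of a cosine at f_γ, centred on
the positive theta peak under a raised-cosine (Hann) envelope, scaled so
the burst's peak-to-peak maximum equals `gamma_amp_pp_max` exactly at the
peak (a rectangular envelope is selectable). Cosine phasing at the centre
makes the compound steady-state maximum (theta_pp + gamma_pp)/2 =
1.45 mA. Fades are linear over 15 s at both ends. Defaults: 6 Hz / 80 Hz,
2.0 / 0.9 mA pp, 6 cycles (75 ms burst), 20 min at 10 kHz. A
trough-coupled variant exists as a control and is flagged by the
verifier. The sham signal runs the full active waveform for two 90 s ramp
blocks (15 s fade-in, 60 s, 15 s fade-out) at the start and end, with a
continuous 85 Hz, 50 µA pp sinusoid in between; whether the real sham
ramps used theta–gamma or plain theta is unspecified, so the full
waveform is the default and configurable.

The verifier works from raw samples only: FFT peak + golden-section
refinement for the carrier frequency, least-squares sinusoid fit for
amplitude, envelope thresholding (1% of maximum, floored at 4× the
20th-percentile ripple level) with sub-period merging for burst windows,
sign-change counting with sub-sample zero-crossing interpolation for
cycles and gamma frequency, and the theta phase at burst centres for the
coupling check. Fade durations are estimated as the time to reach 95% of
the steady amplitude, un-biased for a linear ramp. Randomized round-trip
tests tolerate ±1 cycle at extreme duty cycles where the Hann tail falls
below the detection floor.

## Problem sizes and simulation scope

The shipped studies use the full trial design (184,800 trials per study).
Parameter-recovery and selection-calibration studies simulate at the
epoch level — drawing the 840-row table directly from the mixed model —
which is the exact process the analysis model assumes and therefore the
right null machine for coefficient recovery and LRT type-I calibration;
the default runs use 200 recovery and 500 selection replicates. A
30-replicate recovery through the complete trial-level pipeline verifies
that stream generation, exclusion and median aggregation do not bias the
trial-type effect. The synthetic generator does not emulate several
features of real RT data — post-error slowing, fatigue drifts within
blocks, RT–accuracy trade-offs, or any neural mechanism of tACS (group
effects are injected phenomenologically) — so passing tests demonstrate
correctness of the *machinery*, not of substantive claims about real
cohorts.

## Known limitations

- Degrees of freedom for Wald t are residual-style; small discrepancies
  with mixed-model df approximations are expected.
- The χ² on a fully specified blinding table depends on the unpublished
  cell breakdown; only the correct-guess proportion is anchored.
- The epoch-level simulator treats the epoch residual as Gaussian; the
  trial-level pipeline produces slightly heteroscedastic medians (fewer
  lpt than hpt trials per cell), which the model ignores, as does the
  analysis it mirrors.
- `verify_sham` measures ramp-block durations from the envelope and
  reports ≈89 s for a 90 s block (the first ~0.5 s of a linear fade sits
  below the carrier-level threshold).
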