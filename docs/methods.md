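# Methods

## Problem and model

The package classifies which of eight single-DOF isometric torque tasks a
participant intends — shoulder abduction/adduction (AB/AD), horizontal
abduction/adduction (HAB/HAD), external/internal rotation (ER/IR), elbow
flexion/extension (EF/EE) — from 8-channel surface EMG and a 6-DOF load
cell rigidly coupled to the casted forearm. The classes split into the two
clinically described post-stroke synergy groups: flexion (EF, AB, ER, HAB)
and extension (EE, AD, IR, HAD).

The classifier is standard LDA: each class is Gaussian with its own mean
and a covariance pooled across classes,

    Σ = Σ_k Σ_i (x_ki − μ_k)(x_ki − μ_k)ᵀ / (N − K),

regularized by λ·I with λ = 1e-6 × mean(diag Σ) by default. The ridge
exists purely for conditioning (e.g. duplicated or collinear feature
columns); on well-conditioned problems it is numerically irrelevant.
Scores are computed through a Cholesky solve, never an explicit inverse.
Priors default to uniform because the protocol balances trials across
classes. Ties in the arg-max resolve to the lowest class index, with
scores within a relative 1e-9 treated as tied so analytically exact ties
are not broken by rounding.

## Preprocessing choices

* **Notch filter.** Band-stop 58–62 Hz and harmonics (120, 180, … up to the
  450 Hz hardware band edge or Nyquist), 6th-order Butterworth each,
  applied forward–backward (zero phase) since the analysis is offline.
  Narrow stop bands ring for ~0.5 s, so mirror padding leaves audible edge
  transients (worst-case tone rejection ≈ 29 dB). The signal is therefore
  extended ~1 s at each end by Burg autoregressive (maximum-entropy)
  extrapolation — which continues narrow-band components coherently — with
  AR poles reflected into and shrunk inside the unit circle so the
  extension cannot diverge. Measured: ≥ 68 dB tone rejection at 60 Hz,
  passband and DC deviations < 1e-4 dB.
* **Joint torques.** The measured wrench is translated to the shoulder and
  elbow joint centers and rotated into the anatomical frame,
  m_joint = R(M + r_joint × F); an axis map picks the moment component and
  sign for each of the 4 torque DOFs (positive = AB, HAB, ER, EF). Two
  lever arms (shoulder, elbow) are required: elbow flexion torque is not a
  component of the shoulder moment, and a single-point moment cannot carry
  four independent DOFs.
* **MVT** is the maximum of the trailing (causal) 200 ms moving average of
  the sign-rectified primary torque; trailing alignment matches an
  online-capable convention.
* **Trial retention**: the three largest-MVT trials per direction (ties by
  acquisition order), with a flag for the protocol stop criterion (top
  three within 10 %, last trial not the greatest).
* **Segmentation** keeps samples where the *raw* primary torque strictly
  exceeds 20 % of the direction-level MVT (max over the retained trials).
  Using raw rather than smoothed torque for the comparison is a choice the
  protocol leaves open; it is flagged here rather than silently assumed.
  Windows never span gaps between supra-threshold runs.

## Feature extraction

200 ms windows, 25 ms increment, per contiguous run; partial trailing
windows are dropped. EMG features are the Hudgins time-domain set per
channel, channel-major order. The zero-crossing and slope-sign-change
deadband defaults to 0 (exposed as a parameter); sign(0) counts as
positive, so zeros alone never produce crossings. Load-cell and torque
features are signed per-channel window means. The combined set is the
bitwise concatenation of the EMG and load-cell rows.

## Cross-validation and reporting

Trial-wise leave-one-out over the three retained trials: fold *j* trains
on trials {0,1,2}\{j} of every class and tests on trial *j* of every
class. Per-class accuracy is the fold average of window accuracies;
overall accuracy is the unweighted mean of the eight class accuracies
(class-balanced convention, matching how the cohort summary row is
built). Pooled confusion counts across folds are also retained; their rows
are only rounded at display time. A class with no test windows is reported
as undefined (NaN + flag), never silently zero. Spearman correlations use
rank-Pearson with average ranks and a two-sided t-approximation p-value,
which is approximate for small cohorts.

## Synthetic cohort: what it emulates, and what not

Each trial: latent 4-DOF torque = ramp–hold–release envelope (1 s ramps,
2.5 s hold, exact plateau at 1) × a class-specific direction row (N·m),
plus Gaussian sample noise (sd 0.8 N·m). Load-cell channels are the
minimum-norm wrench reproducing that torque through the same rigid-body
map the analysis inverts, so with noise off the round trip is exact to
machine precision. EMG is band-limited (20–450 Hz) Gaussian noise whose
standard deviation tracks noise floor + activation gain × envelope, plus a
60 Hz sinusoid; amplitude-modulated filtered noise is the standard
surrogate for interference-pattern surface EMG.

Defaults encode the emulated study conditions: 5 s trials at 1 kHz, 4
trials per direction (3 retained), plateau torques of realistic
moderate-impairment magnitude (12–30 N·m primaries), per-trial plateau
jitter ±5 % so the 10 % retention rule is exercised, and per-trial
*strategy* variability on the direction row (relative sd 0.15 plus 1.2 N·m
additive) and on EMG gains (lognormal sd 0.15). The strategy variability
is the load-bearing realism choice: without trial-level variation,
trial-wise cross-validation is degenerate (every classifier saturates at
100 %); with it, torque clouds of coupled directions overlap partially, as
the recorded population's scatter shows. The default coupling is 0.5
(moderate).

`synergy_coupling` c replaces the AB and ER rows (likewise AD/IR) of both
the torque-direction and activation matrices by (1 − c/2)·own +
(c/2)·partner: c = 0 independent, c = 1 identical. Because one knob couples
torque and EMG together, the generator cannot distinguish "strategy" from
"synergy" — neither could the emulated experiment. The activation matrix
gives rotation classes weak, shared superficial-muscle patterns
(rotator-cuff muscles are not instrumented), so EMG-only accuracy
saturates around the mid-90s even in high-SNR conditions — deliberately
mirroring the montage limitation of the emulated setup.

Not modeled: force–EMG nonlinearity, motor-unit structure, fatigue,
electrode lift-off, inter-participant anthropometric variation (geometry
is shared). Clinical scores (UE-FMA uniform integer 10–45, reach fraction
uniform [0,1]) are intentionally uncorrelated with signal properties, so a
near-zero accuracy–FMA correlation is the expected (null) outcome, and
passing tests say nothing about real clinical correlations.

## Problem sizes

Unit and property tests run on single participants or small random
problems. Cohort-level properties use 2–4 participants × 8 classes × 4
trials; the acceptance script uses a 10-participant cohort spanning
coupling 0 → 1 plus a 3-participant coupling sweep. These sizes give
stable cohort means (accuracy sd across seeds ≈ 1 point) while keeping a
full run around a minute on one CPU.

## Known limitations

* The geometry's rotation/lever-arm values are nominal, not anthropometric;
  the round-trip construction makes results insensitive to the specific
  valid geometry chosen.
* Fold-averaged and pooled-count accuracies are both computed; they differ
  only when folds have unequal window counts.
* The Spearman p-value's t-approximation is inaccurate below n ≈ 10; the
  exact permutation null is not implemented.
* EMG feature windows near the segmentation threshold sit close to the
  noise floor, compressing class separation — a real phenomenon, but here
  governed by a single scalar noise floor rather than per-channel noise.
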