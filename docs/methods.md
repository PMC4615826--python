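# Methods

This note records the models, estimators, parameter choices and their
rationale, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Behavioral index

Reaction time (RT) is the elapsed time from lane-deviation onset to
response onset. RTs are right-skewed with no upper bound (a sleeping
driver simply does not respond; hundreds of seconds are possible), so
two transforms precede all statistics:

* **Normalization.** Each subject's RTs are divided by the mean of
  their fastest decile — the ⌈0.1·N⌉ smallest RTs, ties broken by
  ascending trial index. Ratios below 1 are clipped to 1: a response
  faster than the subject's own alert baseline carries no extra
  information about vigilance. The ceiling rule guarantees a nonempty
  denominator set at any N; normalization is exactly invariant to
  rescaling all RTs by a common factor.
* **Driving performance (DP).** A bounded logistic map of normalized
  RT r:
  DP(r) = −(1+e^(−1/2))/(1−e^(−1/2)) + (2+2e^(−1/2))/(1−e^(−1/2))·(1+e^(−r/2))^(−1).
  DP(1) = 1; DP is nearly linear up to r ≈ 2.5 (DP = 2.26) — the
  vigilance-transition range where sensitivity matters — reaches 3.11
  at r = 4 and saturates at (2+2e^(−1/2))/(1−e^(−1/2)) − (1+e^(−1/2))/(1−e^(−1/2)) ≈ 4.083,
  so extreme lapses compress instead of dominating. DP is **not**
  capped at 4.00: the asymptote is kept at full precision and any
  4.00 in display output is rounding. The map is a bijection from
  [1, ∞) onto [1, 4.083); a numerical inverse is provided.
* **Groups.** optimal DP < 2, sub-optimal 2 ≤ DP ≤ 3, poor DP > 3
  (both boundaries belong to sub-optimal).

## Preprocessing

* **Filter.** Windowed-sinc (Hamming) FIR band-pass, 1–50 Hz, applied
  forward–backward, which squares the magnitude response and cancels
  the group delay exactly. The default order follows the classic EEG
  toolbox heuristic 3·fs/low_cut taps (1501 at 500 Hz), rounded to
  odd for type-I linear phase; any design meeting the attenuation
  contract (≥ 40 dB at 0.5× the low edge and 1.5× the high edge,
  two-pass) is acceptable and the contract is asserted in the tests
  from the designed response. The forward–backward pass is
  implemented as a single FFT convolution with the filter's
  autocorrelation over an odd-reflection-padded signal, which is
  algebraically identical to filtering twice and orders of magnitude
  faster on long records.
* **Decimation.** Integer-factor sample picking (500 → 250 Hz keeps
  every second sample); anti-aliasing is already provided by the
  50 Hz band edge. Non-integer factors are rejected.
* **Epochs.** The analysis window of every trial is the half-open
  1-s baseline [onset − 1 s, onset): exactly epoch_len·fs samples
  ending one sample before deviation onset, 0-based indexing. No
  post-onset sample is ever read. Trials starting too close to the
  recording edge are dropped with a logged warning, never silently.
* **Time-shift screen.** For each ordered pair the source is advanced
  by one sample; if the shifted source "predicts" the sink better
  (one-sided paired sign-flip permutation test on per-trial TE
  differences, α = 0.05), the dependence is instantaneous — volume
  conduction, not lagged coupling — and the pair is rejected. Shift
  and α follow common toolbox practice; the screen's parameters are
  configurable.

## Transfer entropy

TE(Y→X) = I(x_{t+u}; y_t^m | x_t^d) with delay-embedded states
x_t^d = (x_t, x_{t−τ}, …, x_{t−(d−1)τ}) and likewise y_t^m. It is
estimated in the Kraskov–Stögbauer–Grassberger conditional-mutual-
information form: one combined neighbor search in the joint space
(algorithm-1 counting, Chebyshev norm), digamma averages over the
marginal counts. This form cancels bias between the four differential
entropies rather than estimating them independently. Internally in
nats, reported in bits.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| k (neighbors) | 4 | conventional KSG choice; variance/bias balance |
| Theiler window T | 1 sample | excludes temporally adjacent vectors from searches *and* marginal counts; suppresses autocorrelation bias |
| τ (embedding delay) | 1, or first 1/e autocorrelation crossing | the "Cao criterion" label in the literature properly selects the *dimension*; for the delay the 1/e rule is the standard companion. This interpretation is deliberate and documented. |
| d, m (dimensions) | 2, or Cao's E1 saturation (|E1−1| < 0.05, capped) | Cao's method; independent per-series selection (the joint search heuristic used in some toolboxes is not specified anywhere reproducible) |
| u (prediction time) | 1 sample at 250 Hz | "5" in the source-material convention is read as 5 ms (the candidate grid is in ms), i.e. 1 sample at 250 Hz; both readings are available via configuration |
| u search grid | 5, 10, 20, 40, 60, 80, 100 ms | converted round-half-up with a 1-sample floor (→ 1, 3, 5, 10, 15, 20, 25 samples at 250 Hz); ties break toward the smallest u |

Both series are z-scored per segment before embedding, so the
Chebyshev metric weighs source and sink comparably and the estimate
is exactly invariant under separate affine rescaling of either
series.

**Per-trial vs pooled estimation.** 250-sample baseline epochs are
marginal for a kNN estimator; per-trial estimates are allowed (and are
what the DP-sorted statistics consume) but carry small-sample bias. A
pooled mode concatenates embedded state vectors across trials, with
per-trial time offsets so the Theiler window never spans a trial
boundary (cross-trial neighbors are admissible; they are temporally
independent).

**Effective TE.** The per-trial KSG bias depends on the signals'
autocorrelation, which itself varies with vigilance — a confound for
any profile sorted by performance. The pipeline therefore subtracts,
per trial, the TE computed from a random *other* trial's source
(identical marginals and autocorrelation, no coupling): the
trial-shuffle "effective transfer entropy" correction. Raw values are
kept alongside. Validation on sessions with no planted coupling shows
the corrected profile is flat at zero (see the independent-pair
checks in the test suite).

**Surrogate significance.** The null shuffles the assignment of
source trials to sink trials. Because the test statistic is the mean
per-trial TE, the full cross-trial TE matrix is computed once and
every permutation reduces to re-indexing, so hundreds of permutations
cost one matrix. p = (1 + #{null ≥ observed})/(1 + n_perm). For a
single continuous pair, either split into pseudo-trials (`n_chunks`)
or fall back to a circular-shift null (full re-estimate per
permutation).

## Reference measures

* **Granger causality.** GC(y→x) = ln(RSS_restricted/RSS_full) from
  OLS fits of the sink on its own p lags without/with the source's p
  lags; order p minimizes the BIC of the bivariate VAR over 1..p_max
  on a common effective sample. For jointly Gaussian processes
  TE = GC/2 (nats), which the tests exploit as a cross-estimator
  oracle. An asymptotic F-test accompanies the point estimate.
* **Band powers.** Rectangular-window periodogram of the 1-s epoch
  (1 Hz bins); band power is the sum of bins with lo ≤ f ≤ hi. Bands:
  delta 1–4, theta 5–7, alpha 8–12, beta 13–20 Hz — disjoint as
  printed, so the 4 Hz bin is delta's and the 5 Hz bin theta's, and
  the four bands partition 1–20 Hz exactly. Correlations against DP
  use log10 power by default (band powers are heavily right-skewed);
  linear power is a configuration switch.

## Statistics

* **Baseline normalization.** Per subject and pair, the mean TE over
  the best-decile-DP trials is subtracted ("relative TE").
* **DP windows.** Trials from all subjects are pooled and sorted by
  DP; overlapping windows of width 0.5 and step 0.1 span [1, 4] — 26
  windows, [1.0, 1.5] first. Membership is half-open [lo, hi), the
  final window closed so DP = 4 is counted. Empty windows carry a
  missing mean, never 0.
* **Tests.** Each window vs the first (alert) window by two-sided
  Wilcoxon rank-sum; windows with < 2 members get a missing p.
  Overlapping windows reuse trials across tests by construction; this
  is intrinsic to the moving-window design and is documented, not
  "corrected". BH step-up FDR adjustment is applied across the 26
  windows *within* each ordered pair by default (the profile is
  rendered per pair); a global family is a configuration option.
  Profile significance is flagged at adjusted p < 0.001.
* **Group analysis.** Per-subject × group means of relative TE;
  one-way repeated-measures ANOVA (sphericity assumed, listwise
  deletion of incomplete subjects) and pairwise two-sided Wilcoxon
  signed-rank tests for (optimal, sub-optimal), (sub-optimal, poor),
  (optimal, poor) with pairwise deletion and BH adjustment across the
  three contrasts (marks at adjusted p < 0.05 and < 0.01).
* **Degenerate conventions.** Zero error variance in the ANOVA →
  p = 1 with a warning (F = 0) unless a genuine condition effect
  exists with zero error, which reports p = 0; all-zero signed-rank
  differences → p = 1; identical rank-sum samples → p = 1.

## Synthetic data

Two tiers, all draws from one seeded generator per call (identical
seeds ⇒ bit-identical output):

* **Coupled pairs.** AR(1) pairs with strictly unidirectional linear
  (x_t = a·x_{t−1} + c·y_{t−lag} + ε) or quadratic
  (c·y²_{t−lag}) coupling, 500-sample burn-in. The linear pair admits
  closed-form Granger oracles; the quadratic pair has vanishing
  cross-correlation (odd Gaussian moments) but positive TE — the
  canonical "nonlinear coupling invisible to linear measures"
  fixture.
* **Sessions.** Six channels (Fz, Cz, C3, C4, Pz, Oz) at 500 Hz. A
  latent vigilance trajectory v(trial) ∈ [0, 1] (default: near-linear
  decline with a slow wobble, covering the full DP range) drives:
  * *RTs*: RT = 0.7·exp(2.2·(1−v) + 0.2·z) seconds plus a lapse
    (probability 0.08·(1−v)², RT ~ U[10, 300] s) — right-skewed with
    rare extreme lapses, median 0.7 s when alert. DP ground truth is
    computed from these RTs by the behavior module itself; there is
    exactly one definition of DP.
  * *Trial timing*: each deviation follows the previous response
    offset by U[5, 10] s.
  * *Spectra*: per channel, four AR(2)-resonator band oscillations
    (centers 2, 6, 10, 16 Hz; pole radius 0.985) mixed with
    vigilance-dependent weights — delta 0.50+1.10·(1−v), theta
    0.50+0.60·(1−v), alpha 0.95−0.65·(1−v), beta 0.70−0.50·(1−v) —
    plus a 0.35 broadband floor. The weight slopes were set so that
    per-trial band-power-vs-DP correlations reach the magnitudes
    reported for real drowsy-driving EEG (strong positive delta,
    strong negative beta); the monotone weight contract is asserted
    on these weights directly, not on FFT estimates.
  * *Couplings*: each ground-truth coupling adds
    strength_profile(DP_trial) × (source channel's intrinsic signal,
    lagged) into the sink channel; the strength envelope is
    piecewise-constant per trial, so it is constant across each
    baseline epoch. Profiles: constant; inverted-U (Gaussian bump,
    default peak DP 2.5, scale 0.5); monotone-decreasing
    strength·√((4−DP)/3). The square root is deliberate: TE grows
    roughly with the squared coupling coefficient, so this shape
    makes the *information transfer* — the observable whose monotone
    decline is being emulated — fall approximately linearly across
    the whole DP range rather than flattening into the noise floor.

**What the generator does not emulate** (and hence what passing tests
do not show about real data): EEG artifacts (blinks, EMG, electrode
noise), volume-conduction forward mixing and head geometry,
non-stationarity within a trial, spatially correlated background
activity, and 1/f spectral structure. Pipeline-recovery results on
these sessions demonstrate the correctness of the estimator and the
statistical chain under known ground truth, not the physiological
claims themselves.

## Problem sizes

The distributional checks use sizes at which each property is
expected to hold and that keep the suite quick: 200 independent pairs
of 4096 samples for calibration; 10⁵ samples for the TE–GC
equivalence; a 12-subject × 250-trial simulated study (two planted
pairs, fixed embedding d = m = 2, τ = 1, u = 5 samples at 250 Hz,
matching the planted 20 ms lag) for profile recovery. Embedding
auto-selection is exercised separately at unit-test scale.

## Known limitations

* Per-trial KSG on 250 samples is noisy; conclusions should rest on
  window/group aggregates, as the pipeline's statistics do.
* The estimator assumes within-epoch stationarity; ensemble
  estimators for non-stationary data are out of scope.
* Only bivariate TE is implemented — no conditioning on third
  channels, so indirect paths can masquerade as direct ones.
* The repeated-measures ANOVA assumes sphericity (no
  Greenhouse–Geisser correction), matching the analysis it mirrors.
* Discrete-valued inputs create distance ties that kNN estimators
  dislike; the Markov-chain oracle test adds ~1e−4 jitter, standard
  practice for KSG on discretized data.
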