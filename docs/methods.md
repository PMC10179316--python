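# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations of the `vlpoca` pipeline. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## The analysis model

Each imaged unit contributes a ΔF/F₀ trace sampled at 10 Hz; the session is
scored in 10 s epochs as AW, QW, NREM, or REM. The pipeline averages each
trace into per-epoch means (a whole number of frames per epoch; trailing
partial epochs are dropped, never padded), then averages the epochs of each
state over the whole profiling window to obtain the per-unit state means
m_AW, m_QW, m_NREM, m_REM. Classification uses only three scale-free ratios:

    r_NA = m_NREM / m_AW,   r_RA = m_REM / m_AW,   r_RN = m_REM / m_NREM.

The decision rules express a ≥25% between-state change criterion (cuts at
0.75 and 1.25 around unity, 2.0 for REM dominance) and are applied in a
fixed order — REM-active first, then nonREM-sleep-active, then wake-active,
else state-indifferent. The order matters: REM-active units typically also
carry r_NA > 1.25, so testing the nonREM rule first would absorb them.
Three deliberate rule interpretations:

* The nonREM subtype split uses **r_RN > 0.5** — "REM retains at least half
  of the NREM activity" — to separate nonREMS/REMS-max from nonREMS-max.
* Wake-active strength grades use the fold change **relative to the lower
  (sleep) mean**, i.e. m_AW/m_sleep − 1; a decline expressed as a fraction
  of the wake mean could never exceed 100%, which the strong band requires.
* The wake/REMS-max window is strict: r_RA exactly 0.75 or 2.0 falls to
  wake-max.
* QW is profiled and reported but never enters a rule.

The state-indifference band (±25% of m_AW) is AW-referenced, consistent
with the 0.75/1.25 cuts. Units lacking AW, NREM, or REM epochs have
undefined ratios and are reported as unclassifiable rather than guessed.

**Normalization scale.** The ratio rules are invariant to positive
rescaling, so the pipeline's default operates on raw ΔF/F₀. A whole-session
z-score (`zscore_trace`) is available, but a centered normalization makes
ratio thresholds and the 0.5 quality cut ill-defined (state means straddle
zero), so it is not the default classification path. The quality metric is
the mean of per-state means over states present — a unit is removed iff it
falls strictly below 0.5.

**Logistic validation.** Each threshold rule can be checked post hoc by a
maximum-likelihood logistic regression (statsmodels) of class membership on
the rule's ratio(s), fitted jointly for two-ratio rules. When membership is
computed from the very ratios being fitted the classes are perfectly
separated and the coefficients are unbounded; the fit reports a separation
flag instead of pretending convergence. Against noisy (ground-truth)
membership the fits behave classically — the suite checks the coefficient
sign, Wald p, agreement with an independent Newton solver, and a permuted-
label null.

## The nonparametric battery

All tests use mid-ranks for ties and are invariant under strictly monotone
transforms (property-tested).

* **Friedman** on within-subject ranks: χ² = [12/(nk(k+1))]ΣR_j² − 3n(k+1)
  divided by the tie correction 1 − Σ(t³−t)/(nk(k²−1)); p from χ²_{k−1}.
  Fully tied blocks return χ² = 0, p = 1.
* **SNK post hoc on rank sums**: conditions ordered by rank sum, range
  statistic q = ΔR/√(nk(k+1)/12) compared with studentized-range quantiles
  at the span's width (infinite error df); a non-significant span blocks all
  comparisons nested inside it (classic stepdown).
* **Wilcoxon signed-rank**: zero differences dropped and counted; W is the
  positive-rank sum. Exact null by dynamic programming over doubled
  mid-ranks for n ≤ 25 (matches full 2ⁿ enumeration in tests), else normal
  approximation with tie and continuity corrections.
* **Mann–Whitney**: exact by subset-sum DP for combined N ≤ 25 without
  ties, else normal approximation with tie/continuity corrections.
* **Kruskal–Wallis + Dunn**: tie-corrected H with χ²_{k−1} p; Dunn z on
  mean ranks with SE = √((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)),
  unadjusted by default (Bonferroni/Šidák optional).

Monte-Carlo calibration (2000 null replicates at n = 50 pairs / 50×4 blocks
/ 30+30 / 3×25) puts every test's empirical size in [0.04, 0.06] at
α = 0.05; the acceptance script recomputes these rates.

## Sleep scoring and delta power

The rule-based scorer is a transparent stand-in for manual scoring and is
validated only against the synthetic generator. Per 10 s epoch: EMG RMS
above 0.65 → AW; between 0.22 and 0.65 → QW; under atonia the theta/delta
band-power ratio decides REM (> 1) versus NREM. Band powers integrate the
Welch PSD (2 s Hann segments, 50% overlap) over 2–4 Hz (delta) and 6–9 Hz
(theta) by the trapezoidal rule, band edges inclusive. The recovery rebound
is 100 × mean(recovery NREM delta)/mean(baseline NREM delta), the baseline
being all baseline-segment NREM epochs.

## The synthetic session generator

The generator supplies the statistical structure the analysis assumes, plus
ground truth. None of its parameters are measured quantities; all are
configurable stand-ins chosen once to resemble a mouse light-phase
recording.

* **Hypnogram**: semi-Markov chain over {AW, QW, NREM, REM}; exponential
  bout lengths (means 90/40/180/60 s), floored at one epoch and quantized
  to whole epochs; wake enters sleep only through QW; REM only from NREM.
* **Homeostatic pressure**: dP/dt = (1−P)/τ_wake in wake and −P/τ_sleep in
  sleep (exact exponential epoch updates), τ_wake = 2 h, τ_sleep = 1 h,
  P(0) = 0.2 — a saturating two-time-constant process whose build-up over
  ~2–3 h of enforced wake produces a clearly supra-baseline drive.
* **Spiking and fluorescence**: per-frame Poisson counts at
  λ(state) × g(P); g = 1 + P for sleep-active phenotypes (gain 1.0),
  g = max(0.1, 1 − 0.5·P) for wake-active phenotypes (pressure-driven
  inhibition), g = 1 for state-indifferent units. Counts are convolved with
  a peak-normalized difference of exponentials (rise 0.2 s, decay 1.8 s,
  amplitude 2.5 in resting-fluorescence units — generic GCaMP6-class
  dynamics), placed on a unit resting baseline with Gaussian frame noise
  (SD 0.1). ΔF/F₀ divides by a running 20th-percentile baseline, computed
  block-wise on 30 s windows and linearly interpolated (an O(n) equivalent
  of a sliding percentile for tracking slow drift).
* **Firing rates** (events/s) per phenotype were chosen so the preferred
  state stays below ~0.35 events/s: with a 1.8 s decay a transient is
  visible for ~4 s, so quiet samples occupy ≥20% of any 30 s window and the
  20th-percentile baseline stays anchored at rest. Faster rates push the
  percentile into the transients and compress state means — that regime
  destroys the very ratios being classified (the REMS-active defaults were
  revised once for exactly this reason, see Limitations).
* **EEG/EMG** (100 Hz): unit-variance 2–4 Hz band noise in NREM with
  amplitude √(1 + delta_gain·P) (delta_gain = 1, so band power scales with
  1 + P), 6–9 Hz theta in REM, broadband low-amplitude wake EEG; EMG is
  white with state-dependent RMS 1.0/0.40/0.12/0.08 (atonia in sleep).
* **SD paradigm**: 1 h spontaneous baseline, 3 h enforced AW/QW during
  which only the last 10 min of each hour is flagged imaged, then 1 h
  recovery simulated with NREM bout means doubled and wake bouts halved.
  Optional one-epoch NREM "sleep attempts" occur with per-epoch probability
  0.05 × P (attempts grow with pressure) and the following epoch is forced
  awake. Traces are simulated continuously; the analysis restricts itself
  to imaged windows.

Identical (config, seed) reproduce byte-identical sessions; all randomness
flows through `numpy.random.Generator`s spawned from one `SeedSequence`.

## Problem sizes used in validation

The fixed-seed suite uses a 90 min spontaneous session with 100 units
(study-like phenotype mix) for recovery and scorer checks, and a 5 h SD
session with 46 units for the homeostatic analysis; the acceptance script
regenerates both from its seed. These sizes give stable group statistics
while keeping a full run to a few tens of seconds.

## What the synthetic data does and does not show

The generator reproduces the features the pipeline's logic depends on —
state-conditioned rates, slow indicator dynamics, pressure coupling, band-
limited EEG signatures — but not photobleaching, motion artifacts, neuropil
contamination, unit dropout, non-Poisson burstiness, or scorer-relevant
transition ambiguity (its states switch cleanly at epoch boundaries, which
is why the rule-based scorer can reach ~100% agreement; on real signals both
the scorer and its thresholds would need per-animal calibration). Passing
recovery tests therefore demonstrates internal consistency of the
pipeline, not field performance.

## Known limitations

* **Percentile-baseline compression.** The running-percentile ΔF/F₀
  baseline partially absorbs sustained elevations: dense, long activity
  (e.g. recovery NREM in sleep-active units) raises F₀ within the window
  and deflates the epoch means. Consequently pressure effects are assessed
  where they are cleanly expressed — sparse waking activity (SD hours,
  recovery wake) — and the sleep-state recovery means are reported but not
  asserted directionally. The same mechanism leaves a small positive
  context bias (~10% at these problem sizes) in the zero-gain null contrast
  between SD-hour-3 and baseline wake, because baseline wake epochs border
  high-activity sleep that lifts the local percentile; the null tolerance
  (±15%) accounts for it, and the residual is reported by the acceptance
  script as `null_sleep_active_sd_h3_over_baseline_aw_pct`.
* The instability exclusion for SD sessions (a coefficient-of-variation
  ceiling over baseline condition means, off by default) is this package's
  own operationalization of an otherwise informal "unstable units removed"
  step; treat it as a configuration choice.
* Friedman p-values are asymptotic (χ²); at very small n they are
  approximate. SNK uses infinite-df studentized-range quantiles, the
  convention for rank-sum post hocs.
* The scorer has no artifact rejection and assumes fixed thresholds per
  session.
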