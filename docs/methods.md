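# Methods

This note documents the models, conventions and numerical choices behind
`msnf`, in the spirit of a package methods appendix. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Microstate model and backfitting

EEG is modelled as a piecewise-constant sequence of K scalp topographies.
Templates are average-referenced, unit-norm maps defined up to sign; a
sample is assigned to the template with the highest **absolute** Pearson
correlation across channels (both sample and map average-referenced before
correlating — the standard microstate convention). Consequences that the
code relies on and the tests check:

* backfitting is invariant to global sign, positive scaling and reference
  shifts of a sample;
* zero-spatial-variance samples have no defined correlation and are left
  UNASSIGNED (logged); by default coverage is computed over assigned samples
  only (`coverage_denominator="all"` gives the strict convention);
* ties in the argmax resolve to the lowest state index, deterministically.

GEV uses squared spatial correlation weighted by GFP²:
`gev_k = Σ_{t: L(t)=k} GFP(t)²·corr²(x_t, T_k) / Σ_t GFP(t)²`, the published
definition behind the usual one-line description; at zero noise the per-state
values partition 1. GFP is the population SD across channels.

### Label smoothing

Offline smoothing follows the classical windowed segmentation-smoothing
update: sample t's noise-normalised misfit
`(‖x_t‖² − (x_tᵀT_k)²) / (2e(C−1))` is offset by `factor ×` the count of
same-labelled samples within ±`window//2`, and labels are reassigned to the
minimum-cost state. Updates are applied **sequentially left to right**
(iterated conditional modes on a Potts-coupled chain): each update lowers a
global objective, so the procedure provably converges, and the fixed order
makes it bit-reproducible. Defaults: window 24 samples, factor 10, at most
1000 sweeps. `factor=0` returns the input unchanged. The noise variance `e`
is estimated once from the initial labeling.

### Short-segment rejection

Runs shorter than `min_samples` (default 3) are split at their midpoint:
the left part joins the left neighbour, the right part the right neighbour,
and the middle sample of an odd run joins the side whose template correlates
better with it. Runs touching a sequence boundary are exempt (no neighbour
on that side). The implementation fixes one run at a time and re-derives the
run list, because each fix merges runs and can change downstream boundaries;
the run count strictly decreases, so termination is guaranteed.

The online path (calibration epochs and real-time windows) applies **no**
smoothing and **no** short-segment rejection.

## Preprocessing

* Band-pass: Butterworth, order 8 per pass, applied forward and backward
  (`sosfiltfilt`) — effective order 16, zero phase.
* Notch: 49–51 Hz. Online dialect: zero-phase IIR band-stop (order 4
  per pass). Offline dialect: Hamming-window FIR with 0.5 Hz transitions,
  tap count from the standard transition-width rule (logged), applied
  centred so the net filter is zero phase. All sampling-rate-dependent
  parameters are expressed in samples with the rate explicit.
* Bridged electrodes: intrinsic-Hjorth electrical distance (temporal
  variance of channel differences). Real bridges collapse this distance by
  orders of magnitude, so the cutoff is adaptive: the widest gap (> 1
  decade) in the log-distance distribution below the median, with a fixed
  `median/16` fallback when no separated low cluster exists.
* A virtual channel is created at the normalised chord midpoint of each
  bridged pair (undefined, hence an error, for antipodal pairs); its signal
  starts as the pair average, the originals are marked bad and then
  re-estimated by interpolation.
* Bad channels are re-estimated by spherical-spline interpolation
  (Legendre series `g(cosθ) = Σ (2ℓ+1)/(ℓ(ℓ+1))^m P_ℓ /4π`, stiffness m=4,
  50 terms, ridge 1e-5, constrained spline coefficients plus free
  constant). Rows of the interpolation operator sum to 1, so constant
  topographies are reproduced exactly and the operation is idempotent.
* ICA: only the *application* of a stored mixing/unmixing pair is in
  scope. Cleaning subtracts the rejected components' contribution,
  `X − M_rej(U_rej X)`, leaving signal outside the modelled subspace
  untouched; rejecting nothing is exactly the identity.
* Epochs are half-open sample windows, step = length − overlap, trailing
  partial windows discarded; windows overlapping annotated bad segments are
  dropped and logged (not trimmed). 0-based sample indexing throughout.

## Calibration and the feedback loop

Thresholds are `μ ± σ` of per-epoch target coverage; σ is the **population**
SD (ddof=0), because the calibration epochs are the complete population the
gauge is scaled to (ddof configurable). Fewer than two epochs, or a
zero-variance coverage distribution, raise explicit errors.

Engine conventions, where the protocol leaves the loop underdetermined:

* warm-up — scores are emitted only once a full window of samples exists;
  smoothing uses however many (≤ n_smooth) scores have accumulated;
* the smoothing history is reset at each block start, so no score mixes
  data from both sides of a break (flagged as a deviation risk: the original
  system's behaviour between blocks is unstated);
* each window is filtered independently (no filter state across
  iterations), matching per-iteration processing;
* feedback is clipped to [−1, 1] by default (a display gauge cannot
  over-fill); the unclipped value is available for analysis;
* the up/down direction never changes the computed value — participants
  are blind to the computation — it only tags the trace;
* time is simulated sample count over the sampling rate, so behaviour is
  independent of wall-clock speed and a deterministic stream yields a
  bit-identical trace. With the default 3 s window, 250 ms cadence and
  10-score smoothing, the oldest sample influencing a score is
  `window + (n_smooth−1)·step = 5.25 s` old; quoted larger figures for live
  systems additionally include acquisition/processing latency.
* mastoids (M1, M2) are dropped by name before any scoring.

## The synthetic generator and the virtual subject

The generator emulates exactly the features the method consumes: Markovian
state dynamics (geometric dwell times; default `p_stay=0.94` at 250 Hz ≈
67 ms mean dwell, a typical resting value), per-segment log-normal amplitude
(mean 10 µV, CV 0.3 — GFP-scale amplitudes; constant within a segment so
segments stay coherent), per-segment polarity flips, and i.i.d. Gaussian
sensor noise (default 5 µV → 4:1 per-channel signal-to-noise power ratio).
Template maps are random low-order spherical-harmonic fields,
orthonormalised, on a deterministic quasi-uniform spherical cap carrying
10-10 names (positions are synthetic, not measured montage coordinates —
only unit-sphere geometry matters to any algorithm here).

It does **not** emulate: 1/f spectra, alpha rhythms, volume-conducted
artifacts, non-stationary noise, electrode drift, or real microstate
syntax (non-uniform transition structure is supported but not default).
Passing tests therefore demonstrate correctness of the *computations* under
a controlled ground truth, not robustness to real-world artifacts.

The responsive subject couples feedback to the chain: after each emission,
`p_stay(target) += learning_gain · feedback` (negated for down-regulation),
clamped to `[p_floor, p_ceil]`. The floor defaults to the baseline
self-transition: a participant attempting regulation does not fall below
their own resting dynamics. This choice is what makes the coupling
well-posed — without a floor the rule is an unstable fixed point (early
random feedback can push the chain into a self-reinforcing downward spiral
as easily as upward), whereas with it up-regulation becomes a ratchet
(successful excursions are reinforced, unsuccessful ones bounded) and
down-regulation saturates at baseline, reproducing the asymmetry actually
observed in this kind of training: consistent positive block trends under
up-regulation, attenuated/absent trends under down-regulation.
`learning_gain` defaults to 0.002 per iteration — slow enough that learning
needs most of a session, fast enough to be visible within one.

## Statistics

* Paired Cohen's d defaults to `mean(diff) / sqrt((s₁² + s₂²)/2)` (the
  estimation-statistics convention; the protocol's source never defines its
  d, so the convention is flagged); `d_z = mean(diff)/sd(diff)` is provided.
* BCa: bias constant from the bootstrap CDF at the observed statistic
  (ties at half weight), acceleration from jackknife skewness, percentile
  fallback (logged) when the bias is infinite. Rows of the data matrix are
  resampled jointly so paired statistics resample subjects. Known
  limitation, shared with every percentile-family interval: for the mean at
  n≈20 true coverage of a nominal 95% interval is ≈ 91–93%, an O(1/n)
  effect the coverage tests are sensitive to at their own MC scale.
* Permutation test: sign-flip of paired differences, statistic = d_z,
  add-one correction `(1+hits)/(1+B)` so p > 0; exhaustive enumeration
  (exact p = hits/2ⁿ, identity flip included) replaces Monte Carlo whenever
  `2ⁿ ≤ n_perm`.
* Repeated-measures correlation: within-subject centring, common slope,
  `r = sign(slope)·√(SS_m/(SS_m+SS_e))`, `df = N − k − 1`, two-sided t
  p-value. Cross-checked against an independent implementation in the tests.
* Power: exact noncentral-t, `ncp = d√n`, df = n−1; one-sided by default
  (the convention under which the protocol's printed planning numbers are
  internally consistent; sidedness is always explicit in outputs).
  `required_n` solves the continuous root of `power(n) = target` — the
  quantity power software reports — and rounds to the nearest integer by
  default; `rounding="ceil"` guarantees the returned integer itself attains
  the target power (the two differ by at most 1). The post-hoc power
  statements are reproduced at their inferred inputs (d=0.595/n=12 and
  d=0.304/n=15, one-sided); the n=15 inference reflects listwise pair
  drop-out from the N=16 up-regulation sample.

## Problem sizes in the test suite

Simulation-heavy tests run at reduced scale chosen as the package's own
trade-off between statistical resolution and turnaround: chain oracles at
n=10⁵ samples, parameter recovery on 60 s at 250 Hz, closed-loop runs as
6 × 24 s blocks at 125 Hz over 20 seeds, permutation calibration over 1000
null runs, bootstrap coverage over 500 replications (B=999). Each tolerance
in the tests is the analytic 3-standard-error band of its own Monte-Carlo
design, not a tuned constant.

## Known limitations

* No real acquisition layer (LSL/hardware) — streams are replayed files or
  simulations behind a pull-based protocol.
* ICA decomposition itself and artifact-component classification are out of
  scope; only stored solutions are applied.
* EDF export is not provided (the FIF container plus CSV/TSV/JSON cover
  interchange); recordings load from FIF via mne.
* Clinical-scale conclusions (effect sizes on real participants) are not
  reproducible here by construction: the generator shares the method's
  state-sequence model, so it validates machinery, not physiology.
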