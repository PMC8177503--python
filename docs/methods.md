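# Methods

## Generative model and estimator

The observation model is an autoregressive calcium process with
instantaneous spike rises: fluorescence y_t = c_t + ε_t with ε_t i.i.d.
Gaussian, and c_t = γ·c_{t−1} + z_t with z_t ≥ 0, a spike wherever
z_t > 0.  Spike inference solves the penalized changepoint problem

    min_{c}  ½ Σ_{t=1..T} (y_t − c_t)²  +  λ·#{t ≥ 2 : c_t ≠ γ·c_{t−1}}
    s.t.     c_t ≥ γ·c_{t−1},

with c₁ free and unpenalized.  The problem is non-convex but admits an
exact dynamic program over the calcium value: Cost_t(c), the optimal
objective of the first t observations given c_t = c, is a continuous
piecewise-quadratic function updated by

    Cost_t(c) = ½(y_t − c)² + min( Cost_{t−1}(c/γ),
                                   λ + min_{c′ ≤ c/γ} Cost_{t−1}(c′) ).

The implementation (`calspike._l0core`, numba) stores each cost function
as explicit quadratic pieces.  Exact pruning: wherever
Cost exceeds its own running minimum plus λ, a spike-restart is at least
as good, so the function is truncated there; this changes neither the
running minimum nor the two-branch minimum and bounds the stored piece
count (empirically a few tens of pieces).  Ties between the two branches
resolve to the spike branch so traceback through truncation-induced tie
regions remains exact; jumps below 1e−10 are then discarded as spikes
(the optimizer's strict-positivity criterion needs a numerical
tolerance).  Traceback recovers the calcium path; within spike-free runs
the path is re-propagated forward so it decays by exactly γ per step.
Global optimality is validated in the test suite against exhaustive
enumeration of all changepoint subsets on short traces, each subset
scored by bound-constrained least squares that honours the upward-jump
constraint across segment boundaries (the cross-segment constraint is why
a plain segment recursion would not be exact).

## Parameter selection

**Decay rate γ.**  Given ground-truth spike indices, the trace between
consecutive spikes is segmented from its argmax (peak) to its argmin
(trough), ties toward the earlier index; segments whose trough−peak span
exceeds K = 10 timesteps are kept (intervals whose minimum precedes their
maximum contain no decaying stretch and are dropped).  A single γ is fit
jointly: per segment the initial amplitude has the closed form
c₀* = Σ y_t γ^(t−a) / Σ γ^(2(t−a)), and the profiled residual sum of
squares is minimized over γ ∈ (0.5, 0.9999) by a 200-point grid followed
by bounded refinement in the best cell (tolerance 1e−6); the grid guards
against local minima although the objective is smooth in practice.  Per
neuron, recording-level estimates are averaged; the group value is the
median across neurons.  Rates transfer between sampling frequencies via
the linear map γ_to = 1 − (f_from/f_to)(1 − γ_from); the in vivo presets
at 60 Hz are 0.970 (GCaMP6f 37 °C) and 0.984 (GCaMP6m 37 °C).  Note the
GCaMP6f preset is shipped as the published value even though applying the
linear map to the 66.67 Hz median 0.975 gives 0.972.  Half-life is
ln 2 / (f · (−ln γ)).

The fit assumes segments decay toward zero.  On preprocessed traces a
small residual offset (from baseline normalization under ongoing tonic
firing) biases γ̂ slightly low; count-calibrated λ absorbs this, and the
sweep test below confirms the inference is insensitive to γ errors of
this size.  The headline accuracy claim (recovery within ±0.005 at
noise SD 0.05) is therefore measured on offset-free simulated segments.

**Penalty λ.**  λ is chosen by binary search on the (empirically
monotone, non-increasing) inferred spike count: the bracket doubles from
1 until the count falls strictly below the target, then up to 60
bisections (stopping at relative bracket width 1e−9), tracking the best
|count − target| seen with ties resolved toward larger λ (fewer spikes).
Targets: the number of timestep bins containing ≥1 ground-truth spike
(in vitro mode) or target rate × duration (in vivo mode, default 6 Hz).
Binary-search optimality is audited against a dense λ grid in the tests.

**Spike-time shift.**  Inferred indices are shifted 4 timesteps late-ward
when converted to seconds (≈0.06 s at 66.67 Hz), compensating the
indicator's finite rise time.  The shift is applied at every sampling
rate by default and is overridable.

## Preprocessing

Fixed order, each stage deliberately simple and individually testable:

1. Neuropil correction F_corr = F_raw − Υ·F_annulus (presets Υ = 1.0
   in vitro, 0.58 in vivo).
2. ΔF/F with a trailing-window baseline: the 8th percentile (linear
   interpolation between order statistics) of the past 60 s; at the start
   of the recording all available samples are used rather than discarding
   the head.  Lossy (absolute scale discarded).  Matches a brute-force
   per-index oracle bit-for-bit.
3. Robust detrend: linear regression of ΔF/F on time with two-component
   Gaussian-mixture errors fit by EM — both components share the line and
   differ in variance, so the low-variance component down-weights
   transients; initialized from ordinary least squares, 200 iterations or
   relative log-likelihood change < 1e−8.  Residuals are shifted by their
   1st percentile and scaled by the (80th − 1st) difference, pinning those
   percentiles to 0 and 1.  The mixture variant (component count, what is
   re-weighted) is this package's documented choice.
4. Fourier resampling to exactly 2N samples (33.33 → 66.67 Hz or
   30 → 60 Hz), so two spikes can occupy one original frame.  Edge
   ringing is accepted and excluded from accuracy checks.

## Validation metrics

The van Rossum distance uses the causal exponential kernel and the exact
pairwise closed form
d² = ½[Σ e^(−|uᵢ−uᵢ′|/τ) + Σ e^(−|vⱼ−vⱼ′|/τ) − 2Σ e^(−|uᵢ−vⱼ|/τ)]
over the infinite horizon (no truncation at the recording end).
Arguments are ordered canonically before summation so symmetry holds to
the last bit.  τ has no default: at sub-second τ the metric scores spike
placement; at τ of a second or more it is dominated by rate structure
(including burst clustering, which a count-matched but unclustered train
cannot reproduce).  The test suite accordingly uses τ = 0.5 s for timing
comparisons against random trains and τ = 1 s for the rate-matching sweep
property (the distance across a λ sweep is minimized, within one grid
step, where the inferred rate matches the true rate on ≥8/10 seeds).

Bursts are maximal runs of ≥3 spikes with inter-spike intervals ≤100 ms
(inclusive boundary); recordings with <10 % of spikes in bursts are
classified pacemaker-like (kept at exactly 10 %).

## Event analysis

PSTHs use 1 ms bins over ±4 s, spike times rounded to the nearest
millisecond, rate = count/(trials × 1 ms), smoothed with a unit-sum
Gaussian kernel of 40 ms SD truncated to a 200 ms support and
renormalized (peak weight ≈0.0101, so a single spike on a single trial
peaks at ≈10.1 Hz).  Windowed responses use raw counts, not the smoothed
PSTH: reward 0–600 ms, cue 150–650 ms post-cue (a 0–500 ms variant is
exposed), omission 0–1300 ms, each minus the 1 s pre-event baseline.
Peak height is the window maximum of the smoothed PSTH; full duration at
half maximum interpolates linearly between the 1 ms bins flanking the
half-max crossings, scanning outward from the peak; a crossing that
leaves the window bounds the width and flags the result; an all-zero
window reports missing values, not zero.  Omission pauses: paired t-test
across trials on (1 s pre-cue baseline, 1.3 s post-omission) rates,
significant at p < 0.05 only when the mean difference is negative;
zero-variance differences classify as not significant with a warning.

## Ramp analysis

Rates by position divide spike counts by occupancy time in 10 cm bins
with edges −30…290 cm (bin centers as regressor); unvisited bins are
missing, never zero.  Spikes are assigned to positions by nearest-time
lookup in the track.  The linear ramp magnitude is the OLS slope times
290 cm — the published convention, although the track spans 320 cm.  The
GLM classifies ramps from per-timestep spike indicators (a timestep with
≥1 spike codes 1; lossless since the solver emits at most one jump per
timestep): logistic regression on position with reference-coded trial
indicators (first trial reference), up/down by the sign of the position
coefficient when its p-value < 0.01, otherwise none; separation or
non-convergence yields none with a warning.

## Synthetic data

The simulator produces the statistical structure the analyses assume, not
imaging physics.  Tonic firing is a gamma-renewal process (shape 2 by
default — DA neurons fire more regularly than Poisson; shape 1 recovers
Poisson), rate 6 Hz by default (the in vivo target-rate convention), and
is warped through the cumulative intensity of an optional rate profile
(time rescaling) for event-locked or ramping rates.  Bursts overlay the
tonic process at exponential onset times (0.2 bursts/s default), 3–6
spikes with uniform 20–80 ms intra-burst intervals — matching the ≥3
spikes / ≤100 ms burst definition and giving default burst fractions
around 30–40 %, well clear of the 10 % pacemaker cutoff.  Fluorescence
follows the AR(1) model at 33.33 Hz (in vitro) or 30 Hz (in vivo) with
per-frame decay 0.95 by default (≈0.975 per step after upsampling to
66.67 Hz, the fast-indicator regime), gamma-distributed spike amplitudes
(CV 0.2), Gaussian noise (SD 0.05 per unit amplitude), baseline 1.0 with
a 0.1-amplitude 60 s sinusoidal drift and a 0.001/s linear trend to
exercise the baseline and detrending stages.  Spikes landing in one frame
sum their amplitudes into a single jump.  All randomness flows from one
seed through named per-operation streams.

Pavlovian sessions follow the published design: 64 trials (50 standard
cue→reward with a 2 s delay, 7 unexpected reward, 7 omission; first five
trials standard, first two non-standard trials unexpected-reward),
exponential inter-trial intervals with mean 40 s.  Responses are Gaussian
rate bumps (cue +10 Hz peak, reward +16 Hz peak by default) and a
90 %-depth, 1.3 s pause after omission; parameters that would drive the
rate negative are rejected.  VR sessions traverse −30→290 cm at 20–30
cm/s with sinusoidal speed modulation; firing ramps linearly in
within-trial time at a configurable Hz/s slope, floored at zero.

What the simulator does *not* emulate: imaging noise statistics of real
sensors (photon shot noise, motion residuals), indicator nonlinearity and
finite rise time, photobleaching beyond the linear trend, or any
population structure.  Passing tests therefore demonstrate correctness of
the estimators under the model's assumptions and realistic SNR, not
performance on any particular real dataset.

## Problem sizes and numerical choices

Test and acceptance runs use 40–60 s recordings (T ≈ 4000 at 66.67 Hz),
100-seed simulation batches for calibration error, 50-seed batches for
GLM power (40 trials) and type-I error (20 trials, α = 0.01), 10 seeds ×
13-point λ sweeps for the distance property, and 60–200 short traces
(T ≤ 12) for enumeration checks — sizes chosen so each suite finishes in
minutes while keeping Monte-Carlo margins far from the asserted
thresholds.  Feasibility of returned calcium paths is enforced to 1e−12;
solver-oracle agreement to 1e−8 on the objective; the trailing-percentile
oracle matches exactly because both sides use linearly interpolated
percentiles.

## Known limitations

* The solver is exact but single-trace and single-threaded; very long
  recordings (hours at 60 Hz) take minutes per λ evaluation, and λ
  calibration multiplies that by ~40 solves.
* γ estimation requires ground-truth spike times by design; there is no
  spike-free γ estimator.
* The van Rossum O(n²) pairwise form is quadratic in spike count; fine
  up to a few thousand spikes per train.
* The GLM assumes independent per-timestep indicators; bursting induces
  mild overdispersion, which empirically leaves the α = 0.01 false-positive
  rate near nominal (~1 %) but is not corrected for.
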