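# Methods

This note documents the models implemented in channelkit, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the known limitations. Units are fixed package-wide: time in s,
rates in 1/s, concentrations in μM (Mg²⁺ in mM), current in pA (inward
negative), potential in mV, temperature 298.15 K for any thermodynamic
constant.

## Kinetic core

### Model and assumptions

Channel gating at saturating glutamate is a linear four-state Markov chain

    D ⇌(k_r, k_d) R ⇌(k_o, k_c) O ⇌(k_u, k_b·[MK]) B

with occupancies obeying the master equation dp/dt = A(c)·p. Agonist
binding/unbinding is not modelled: at 1 mM glutamate the receptor is
essentially always doubly liganded, so the chain starts with all occupancy
in the closed state R at glutamate onset, and the current is defined as zero
before onset. Glutamate, once bound, is treated as a gate only (the scheme
has no unliganded states); protocols analyzed by this package keep agonist
present throughout the modelled window.

The only time-dependence in A is the effective MK-801 concentration c(t),
which relaxes first-order toward each epoch's nominal value with the
protocol's solution-exchange time constant (default 12 ms, the measured
whole-cell exchange rate; `exchange_tau = 0` gives instantaneous steps).

### Integration

Because the generator is constant on (filtered) sub-intervals, the primary
integrator is exact: within constant-concentration stretches, occupancies
are propagated in closed form via the eigendecomposition of A (with a
stepwise `expm` fallback if the eigenvector matrix is ill-conditioned, which
can occur for degenerate rate sets); through exchange transients, one
matrix-exponential step per sample interval is taken using the exact
time-average of c(t) over the interval (A is affine in c, so this is
second-order accurate in the step and exact once c has settled). A transient
is considered settled after 21 exchange time constants (relative residual
< 1e-9).

An adaptive ODE path (LSODA, rtol 1e-9/atol 1e-12) integrates the same
time-dependent master equation directly; it serves as an independent
cross-check (agreement with the propagator is pinned below 1e-6 in the test
suite) and as the fast path inside iterative fits, where per-sample matrix
exponentials would dominate the run time. Occupancy conservation (Σp = 1
within 1e-8) is asserted on every public simulation.

### Steady states

The chain satisfies detailed balance, so stationary occupancies follow from
the products of rate ratios along the chain; for mk801 = 0,
p_O = (k_o/k_c)/(1 + k_d/k_r + k_o/k_c). With MK-801 present and k_u = 0 the
blocked state is absorbing and the point mass on B is returned with a flag.
k_c = 0, or k_r = 0 with k_d > 0, has no stationary distribution and raises.

## Two-step open-probability estimate

**Step 1 (desensitization).** The peak is the extremum of the
median-filtered current (1 ms kernel) within the first 500 ms of the
glutamate epoch; the steady state is the mean over the final 10% of the
epoch (at least 200 ms). These window choices are this package's defaults —
standard practice, but not prescribed by any convention — and are exposed as
estimator parameters. τ_d comes from a decaying single exponential fitted
from the peak sample to the epoch end with the offset fixed at I_SS and the
amplitude free. Cells with |I_P| < 5 pA raise a no-response error;
I_SS > I_P clips D at 0 with a warning. Traces with D ≤ 0.02 are reported as
non-desensitizing (τ_d undefined, k_d = 0, k_r = NaN): with so little decay
the exponential fit is unconstrained and rate analysis is meaningless.

**Step 2 (MK-801 block).** With (k_d, k_r) fixed from step 1, k_c = 200 s⁻¹
and k_b = 25 μM⁻¹s⁻¹, the model current −scale·p_O(t) is fitted to the
current during the MK-801 epoch. Initial occupancies are the steady state of
the three-state sub-scheme (the cell has been in glutamate long enough to
equilibrate). k_c is deliberately arbitrary: in the slow-block regime the
data constrain only k_o/(k_o + k_c), so the reported quantity is P_o, not
k_o. The optimizer is bounded nonlinear least squares on log-parameterized
rates; the scale and k_o are first coarsely located by scanning k_o over
{0.1, 1, 10, 100} s⁻¹ with the scale solved in closed form, then refined
from the best start. `scale_mode="pinned"` instead ties the scale to the
pre-MK steady-state current; on noiseless data the two agree within 1% and
both are exposed because the original procedure's normalization is not
standardized. A fit is flagged non-converged when the refined residual does
not improve on its start or when the current does not decay measurably under
MK-801 (k_o unidentifiable). The k_u-free variant adds the unblocking rate
(log-bounded at [1e-6, 100] s⁻¹, start 1e-4) for receptors where block is
measurably reversible; hitting the upper bound raises a boundary warning.

**Accuracy.** On noiseless synthetic traces the composed two-step estimate
carries a small systematic deficit: step 1 sees the effective onset rate
k_d·k_c/(k_o + k_c) rather than k_d (openings protect against
desensitization), and solution exchange attenuates the observed peak. At
wild-type-like parameters this biases recovered P_o by ≈ 0.2 percentage
points out of 12.2 — well inside the reported between-cell spread — and the
bias vanishes as the open fraction shrinks. Rate-recovery checks for step 1
alone therefore use the fast-gating regime (k_o = 2 s⁻¹, k_c = 2000 s⁻¹,
instantaneous exchange), where the correction is ~0.1% and recovered
(k_d, k_r) match the generating values to better than 2%.

## Hill dose–response

Both modes fit on log-dose (the logistic is better conditioned there),
reporting linear-scale EC50 and h plus logEC50 for group comparisons.
Agonist mode fixes the asymptote at 1 and expects responses normalized to
the saturating response (`normalize="max"` divides by the highest-dose
response). Standard errors come from the fit covariance (delta method for
EC50). Degenerate inputs raise: fewer than 3 distinct doses, or responses
with no dose dependence; non-monotonicity beyond 3× the residual RMS and
narrow dose spans warn. Per-cell fitting followed by aggregation of the
parameters is the intended workflow for grouped data (the batch pipeline
emits one row per input table); pooled fits are possible but conflate
between-cell variance with curve shape.

## Woodhull Mg²⁺ block

Stage 1 fits the Mg²⁺-free I–V with a line, fixing g0 and V_rev and
normalizing both curves to unit slope; stage 2 fits (a, δ) to the normalized
blocked curve with V_rev held fixed — refloating V_rev in stage 2 would let
the block parameters absorb reversal-potential error, so it is not done. The
fitted constant a is K_d at 0 mV, hence K_d(V) = a·e^{bV} with
b = 2δF/(RT) stored in V⁻¹ (F = 96485 C/mol, R = 8.314 J mol⁻¹ K⁻¹,
T = 298.15 K by default; at δ = 0.45, b ≈ 35 V⁻¹). When the blocked curve is
indistinguishable from the unblocked one (maximum block fraction < 0.05),
the fit is returned but flagged unreliable — with no measurable block, a and
δ trade off freely.

## Synaptic-like deactivation and steroid summary

Deactivation is fitted from the post-pulse extremum with one or two decaying
exponentials (offset 0; components ordered τ1 ≤ τ2; weighted
τ_w = (A1τ1 + A2τ2)/(A1 + A2) reported for double fits). `"auto"` keeps the
second component when the nested F-test improves the residual at α = 0.05.
Decays truncated before 3τ warn; non-decaying traces raise.

The steroid summary uses fitted peaks, not raw samples, for the
potentiation percentage — a single noisy sample at the peak would otherwise
propagate directly into the charge-transfer factor. The charge-transfer
factor (1 + potentiation/100) × deceleration equals the ratio of the
integrals of the fitted model responses (for single exponentials, area =
peak × τ exactly); the test suite verifies this against numerical
integration. Steroid pre-application is a protocol annotation only; steroid
binding kinetics are not modelled.

## Single-channel analysis

Idealization is 50% threshold crossing between baseline and open level.
When levels are not supplied they are estimated by 2-means clustering of the
all-points amplitude distribution, taking the more occupied cluster as
baseline. Openings briefer than the dead time are removed and merged into
flanking closed time; the dead time is the fixed constant 446 μs (2.5× the
rise time of the 2 kHz analysis filter) rather than a value recomputed from
filter settings, because the filter realization here is digital and only
approximately matches an analog chain. Censoring never creates open time, a
property-tested invariant. The 3σ level-separation precondition is checked
and warned about, not enforced.

The Bessel low-pass is the scipy bilinear-transform realization of the
analog prototype with magnitude-matched corner (−3 dB at fc), applied
causally with the initial value as pad; its step rise time matches the
analog prototype within 10% (tested), which is the property that matters for
dead-time reasoning. Amplitude fits use the Gaussian maximum-likelihood
estimate (mean/SD of open-event samples); a noiseless record degenerates to
the sample mean with sd = 0 and a flag. Time-averaged open probability is
100 × open time / (record length × channel count); the channel count is a
plain divisor — NPo estimation with unknown N is out of scope, as is
dwell-time distribution fitting.

## Synthetic-data generators

All generators are pure functions of their arguments including the seed, and
always emit their ground truth with the data.

* **Whole-cell traces**: open-state occupancy from the kinetic scheme,
  normalized to its maximum, scaled to a −`scale` pA peak, plus Gaussian
  white noise. Default 10 kHz sampling.
* **Synaptic-like traces**: exchange-filtered rising phase (default rise
  time constant 1 ms — brief-pulse responses at a lifted cell exchange much
  faster than the 12 ms whole-bath estimate), 5 ms pulse, exact
  sum-of-exponentials decay. This is a phenomenological waveform, not a
  kinetic-scheme simulation: deactivation here validates the *fitting*, not
  a gating model.
* **Single-channel records**: alternating exponential dwells, one channel,
  boundaries quantized to the sampling grid before synthesis so the stored
  truth and any idealization of the noiseless trace are comparable
  sample-exactly. Default 25 kHz sampling; optional Bessel filtering.
* **I–V and dose–response tables**: direct forward evaluation of the
  Woodhull and Hill models with relative Gaussian noise.

Noise is additive (or relative, for tables) Gaussian white noise. No source
states a recording-noise magnitude, so defaults (e.g. 2% of peak for
recovery studies) are this package's choices, documented here rather than
claimed as measured. Real recordings additionally contain 1/f and line
noise, series-resistance and capacitance artifacts, drifting baselines,
multi-channel patches and liquid-junction offsets; none are emulated.
Passing recovery tests therefore demonstrates estimator correctness under
the stated model, not robustness to every rig artifact.

## Problem sizes and tolerances

Recovery studies run at the conditions the estimators target: 10 kHz
sampling, 10 s control + 30 s MK-801 epochs for the open-probability loop
(noise 2% of peak for the noisy grid, tolerance: median relative error
< 10%; noiseless published cases within 0.3 percentage points); noiseless
desensitization and curve-fit round trips at 1–2%; idealization checked for
exact event agreement on 100 short (0.8 s) records. Unit tests use reduced
sizes (2 kHz, shorter epochs) where only correctness, not the target
conditions, is at stake. Optimizer tolerances are 1e-12 (xtol/ftol/gtol) for
the block fit and scipy defaults elsewhere; fits are deterministic given the
data.

## Known limitations

* The four-state scheme omits agonist binding, Ca²⁺-dependent
  desensitization and voltage dependence of MK-801 block; P_o estimates
  inherit the scheme's assumptions (notably the arbitrary k_c anchor).
* The two-step procedure's small composed bias at high open fractions
  (above) is inherent to fixing step-1 rates in step 2.
* Woodhull fitting assumes a single impermeant blocker site; permeant-block
  models are out of scope.
* The cell-attached single-channel P_o estimator is a simple time average;
  it requires a known channel count and full-length records.
* ATF input support is a minimal two-column reader; vendor binary formats
  are not read.
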