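# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations. Units follow the field's conventions: pA and mV for
whole-cell signals, mV for field potentials, V/s for fEPSP slopes, ms
for kinetics and interpulse intervals; all times are seconds internally.

## Signal conditioning and PSC event detection

Voltage-clamp traces are low-pass filtered with a 4th-order elliptic
filter, 1000 Hz cutoff, 0.1 dB passband ripple, 40 dB stopband
attenuation, applied forward–backward (zero phase). An even-order
elliptic design sits at −ripple at DC, so the second-order sections are
renormalised to exactly unit DC gain after design; a constant trace
passes unchanged and event peak times shift by under 0.2 ms.

Detection operates on the trace oriented so events are positive
(inward events are negated). The reference level is a running median of
the preceding 10 ms. Candidate peaks must (i) exceed the threshold —
3 pA for EPSCs, 10 pA for IPSCs, the convention being a threshold of
roughly 3× the recording's RMS noise — above that reference, (ii) be
separated by a 2 ms refractory interval, (iii) stay above half their
deviation for at least 2 ms (true PSCs decay over ~10 ms; blips of
1 kHz-filtered noise decorrelate within a fraction of a millisecond),
and (iv) rise by at least the threshold above the minimum separating
them from the previous accepted event, which prevents noise wiggles on
a peak's slow shoulder from double-counting it. Amplitude is
re-measured baseline-to-peak against a short linear fit of the trace
before the event onset, extrapolated to the peak time, which
compensates the decaying tail of a preceding event to first order.

Conventions for kinetics: rise time is 10–90% of the baseline-to-peak
amplitude on the rising limb, decay time runs from the peak to the
1/amplitude·e crossing, both with linear interpolation between samples.
A decay that fails to reach 1/e before the next event's onset is
flagged unresolved and excluded from cell means — the deterministic
counterpart of an investigator discarding overlapping events. Cells
qualify for group analyses with ≥ 100 events.

Limitations: a threshold detector cannot decompose overlapping events.
Amplitudes of events whose predecessor lies within ~25 ms carry a bias
of order 0.5–1 pA from the curvature of the preceding decay (the
linear baseline extrapolation removes only the first-order term), and
events closer than the refractory interval merge. Deconvolution or
template matching would address both and is deliberately out of scope.
The measured operating point on the generator's reference conditions
(20 pA mean amplitude, 1 pA noise, 10 Hz, 60 s) is recall ≈ 0.96 and
precision ≈ 0.99.

## The model granule cell

Current-step sweeps come from an adaptive leaky integrate-and-fire
neuron with a slow sodium-availability gate:

    C dV/dt = −g_L (V − E_L) + I − w        spike when V ≥ V_th and h ≥ h_block
    dw/dt  = −w/τ_w                          on spike: V → V_reset, w → w + b, h → h − d
    dh/dt  = (h_∞(V) − h)/τ_h                h_∞(V) = 1/(1 + exp((V − V_h)/k_h))

With adaptation and the gate disabled the rheobase is the closed form
g_L·(V_th − E_L), which anchors the detector tests. The gate produces
depolarization block: repeated spiking depletes h; once h < h_block
spiking stops, the membrane settles on a depolarized plateau where
h_∞ ≈ 0, and the block is self-sustaining for the rest of the step —
the spikeless plateau seen in granule cells at strong drive. A
stereotyped spike waveform (rise to +35 mV in 0.5 ms, fall in 1.3 ms)
is painted onto the voltage trace so that downstream spike detection
(peak above 0 mV with an upstroke above 20 V/s) sees realistic events.

Defaults were chosen to reproduce granule-cell phenomenology in slice
culture: C = 30 pF, g_L = 5 nS (input resistance 200 MΩ), E_L = −80 mV
(the resting potential), V_th = −59 mV (rheobase ≈ 105 pA, deliberately
off the 10 pA step grid), b = 60 pA and τ_w = 140 ms (peak rates
saturate near 30 Hz with first/last ISI ratios well below 1),
d = 0.032, τ_h = 250 ms and h_block = 0.75 (block onset just above the
F–I peak, near 340 pA). Integration is a fixed-step explicit scheme at
dt = 0.01 ms — ten times the 10 kHz digitization, comfortably inside
the stability region for these time constants — decimated to the
output rate; a larger dt than one tenth of the fastest time constant
is rejected. The threshold comparison uses a 1e−9 mV tolerance because
the discrete solution approaches V_th asymptotically at exact rheobase
and float rounding would otherwise stall it just below threshold.
Between steps the state recovers analytically at rest for the 1 s
inter-step interval. The inner loop is jit-compiled when numba is
available, with an identical pure-Python fallback.

## Intrinsic-excitability measures

Spikes are voltage peaks above 0 mV whose upstroke dV/dt exceeds
20 V/s within the preceding millisecond (1 ms refractory) — the peak
and upstroke criteria are configurable since the underlying custom
analyses rarely state theirs. Rheobase is the smallest step current
with ≥ 1 spike; the maximum rate is count/duration maximised over
steps, ties resolved toward the lower current, and the ISI adaptation
ratio (first/last ISI, needing ≥ 3 spikes) is evaluated at that step.
Input resistance is the least-squares slope of the steady-state voltage
deflection (mean over the last 200 ms of the step, avoiding sag
transients, minus the pre-step baseline) against current over the
−100..−10 pA steps. AP prominence is topographic peak prominence
within the step window; half-width is the width at half-prominence
with linear interpolation; flat-topped (saturated) peaks are flagged
unreliable.

A step is in depolarization block when it fires but its last spike
precedes 0.9 s of the 1 s pulse. The cell-level flag considers steps at
or above the current of maximal firing rate (configurable down to
rheobase): block is a truncation of firing beyond the F–I peak, whereas
a near-rheobase train of two or three widely spaced spikes can end
before 0.9 s without any block — under a rheobase-referenced rule
essentially every continuous-onset neuron would be classified as
blocking.

## Evoked field potentials

The stimulus artifact is blanked for 1 ms. The fEPSP slope is the
steepest 0.5 ms sliding-window regression slope between the response
onset and the positive peak preceding the population-spike trough (the
fEPSP peak when no spike is present). Note the windowed estimator reads
the mean derivative near the window centre: for a fast alpha-shaped
fEPSP (τ = 2 ms) it sits ~20% below the instantaneous initial slope
A·e/τ, converging to it as the window shrinks — absolute slope values
are therefore convention-dependent (as they are across laboratories),
while ratios and group contrasts are not. The population spike is
measured by the tangent method: the vertical distance from the trough
to the line joining the two flanking positive peaks, with
trough-to-preceding-peak available as an alternative. A spike is
scored when the trough deviates from the tangent line by more than 5×
the pre-stimulus noise sd, with a prominence floor of 1% of the
response span so noiseless traces do not yield micro-dip candidates;
with several candidates the largest is used and flagged. Both
operators are DC-invariant and scale-linear. The tangent measure of a
narrow dip on a curved fEPSP background compresses small amplitudes
relative to the rendered dip depth; it does so identically for both
pulses of a pair, so paired-pulse percentages are unaffected.

Input–output analysis averages slope and spike amplitude per intensity
and reports the lowest intensity with a detected spike as the spike
onset. Paired-pulse ratios are 100·(second/first) using slopes for
facilitation and spike amplitudes for inhibition (an absent second
spike is 0%; a zero first response is undefined and flagged). LTP time
courses are expressed as percent of the mean over the 10 min before
induction — the baseline window averages to 100% by construction —
with window means over 0–10 and 50–60 min.

## Boltzmann fits and curve comparison

The sigmoid y = Top/(1 + exp((v50 − x)/k)) with the bottom pinned at
zero is fitted by trust-region bounded least squares (Top ∈ (0, 2·max y],
k ∈ (0, x-range], v50 within one span of the data). Initialisation is
deterministic — Top = max y, v50 = the half-maximum crossing of the
data, k = range/10 — with three deterministically perturbed restarts
retained as a fallback; the best solution by cost wins. R² is computed
on the fitted range only, and fits with R² ≤ 0.8 (or non-convergent
ones) are excluded from group analyses. PPI curves are fitted over
interpulse intervals up to and including 100 ms. Level crossings use
the closed-form inversion; a level at or above the fitted Top is
unattainable and reported missing rather than extrapolated (group
means then simply omit that animal). Constant-y input is rejected
(SStot = 0 leaves the parameters unidentifiable). Shared-versus-
separate fits are compared by the extra sum-of-squares F test with
df = (n − 3) − (n − 6) numerator and n − 6 denominator; nesting
guarantees SS_shared ≥ SS_separate and hence F ≥ 0.

## Statistics layer

Group differences are oriented first group minus second (WT − KO in
the reference design). Welch's t uses the Welch–Satterthwaite df and
accepts either raw samples or (mean, SEM, n) summaries — the statistic
depends on the data only through those summaries, so both routes agree
identically, which is what allows published tables to be recomputed
from printed values. The D'Agostino–Pearson K² test requires n ≥ 20
(its small-sample χ² approximation degrades below that); smaller
samples are directed to the nonparametric branch.

Mann–Whitney p values are exact for n₁+n₂ ≤ 25 without ties (shift
algorithm); tied data are enumerated exhaustively up to n₁+n₂ ≤ 16
(12 870 labelings at worst) and handled by the mid-rank normal
approximation with tie correction above that. The location estimate is
the Hodges–Lehmann median of all pairwise differences; its confidence
interval takes the (k+1)-th smallest and largest ordered pairwise
differences, where k is the largest value with P(U ≤ k) ≤ α/2 under
the exact U distribution (normal-approximate k in the approximate
branch). The exact interval matches R's `wilcox.test(conf.int = TRUE)`.

The χ² test of independence is uncorrected (no Yates continuity
correction) — the convention needed to reproduce published 2×2
statistics at these cell counts — and refuses zero margins.

The two-way repeated-measures ANOVA is the classical split-plot
decomposition (between-group factor tested against the
subject-within-group mean square; within factor and interaction against
the residual), cross-checked against pingouin's mixed ANOVA. With
missing cells the model becomes a random-subject-intercept linear mixed
model fitted by REML — a random intercept is exactly the compound-
symmetry covariance structure — with sum-coded (type III) Wald F
statistics and containment denominator df (n_subj − a for the group
factor, residual df for within and interaction). Containment was chosen
over Satterthwaite because it reproduces the repeated-measures F and df
exactly on complete balanced data, which is the documented equivalence
(verified to 1e−6); p values for unbalanced data are therefore mildly
liberal relative to Satterthwaite when subject counts are very small.
Degenerate noise-free inputs (zero residual variance) report F = 0 for
vanishing terms rather than 0/0. Post-tests are per-level Welch
comparisons with Bonferroni multiplication (p_adj = min(1, m·p)).

Calibration under null simulation (2000 replicates): Welch and the
RM-ANOVA group effect reject at 0.05 within Monte-Carlo error; the
exact Mann–Whitney is conservative (≈ 0.036 at n = 10/10) as any
discrete exact test must be.

## Synthetic data: what it emulates, what it does not

PSC traces are homogeneous Poisson event trains convolved with
peak-normalised biexponential kernels (τ_rise 1 ms, τ_decay 10 ms by
default) plus white Gaussian noise (1 pA sd by default, consistent
with a 3 pA ≈ 3×RMS detection threshold); amplitudes are lognormal
with linear-scale mean 20 pA. Real recordings add correlated (1/f and
line) noise, series-resistance filtering, rate nonstationarity and
amplitude–kinetics correlations, none of which are modelled; passing
detection benchmarks here bounds performance under ideal noise, not
under recording drift.

The field-study generator produces per-subject measurement tables — a
saturating fEPSP-slope–intensity curve, a Boltzmann population-spike
coupling with a 0.2 mV detection floor (EPSP–spike v50 2.4 V/s,
k 0.25 V/s, spike onset near 150 µA on the 30–800 µA grid), and a PPI
Boltzmann over the reference interpulse grid {1, 15, 20, 30, 35, 40,
45, 50, 60, 80, 100} ms — with multiplicative noise (CV 5%) and
subject-level variation entering only through the PPI v50 (sd 4 ms,
normal), matching a design whose single headline contrast is a v50
shift. The default two-group design is 17 vs 16 subjects with a
+4.5 ms shift in the second group's v50; under these conditions the
per-subject Welch comparison detects the shift in ≈ 85–90% of
replicates. Waveform-level rendering (alpha fEPSP with 2 ms synaptic
latency, Gaussian population spike, biphasic artifact) exists so the
measurement operators can be exercised end to end; its ground truth is
the rendered morphology, with absolute tangent amplitudes subject to
the convention effects noted above. All generators draw every random
quantity from `numpy` Generators seeded through a single
`SeedSequence`, so identical seeds give bit-identical output.

## Problem sizes used in the shipped checks

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances: 200 replicates for Boltzmann v50
recovery (median |error| ≈ 0.3 ms against a 1 ms bound), 20 one-minute
traces for the detection operating point, 2000 replicates per test for
type-I calibration (MC se ≈ 0.005), 500 replicates for the
extra-sum-of-squares null uniformity, and 100 replicate studies for
the end-to-end power estimate.
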