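# dgephys

Analysis toolkit for cellular and network electrophysiology of the
hippocampal dentate gyrus: spontaneous/miniature postsynaptic-current
(PSC) detection, intrinsic-excitability profiling of granule cells,
evoked field-potential quantification (input–output curves, paired-pulse
facilitation/inhibition, LTP time courses), Boltzmann-sigmoid modelling
of EPSP–spike coupling and paired-pulse inhibition, and the statistics
layer used to compare genotype or treatment groups. A synthetic-data
module generates every kind of sweep with known ground truth, so the
whole chain is testable without any recordings.

It is written for electrophysiologists who want a scripted, auditable
replacement for the mix of commercial detectors, spreadsheets and
custom scripts such studies usually rely on.

## The core quantities

**PSC events.** Voltage-clamp traces are zero-phase low-pass filtered
(elliptic, 1000 Hz cutoff) and events are found by local-baseline
threshold crossing — 3 pA for EPSCs, 10 pA for IPSCs — with amplitude
(baseline to peak), 10–90% rise time and peak-to-1/e decay time per
event; cells qualify for group summaries with ≥ 100 events.

**Intrinsic excitability.** From 1 s current steps (−100 to 490 pA,
10 pA increments): the F–I curve, rheobase (smallest step with a
spike), maximum firing rate, spike-frequency adaptation as the ratio
ISI₁/ISIₙ, input resistance from the hyperpolarizing steps,
action-potential prominence and width at half-prominence, and
depolarization block (a step whose last spike precedes 0.9 s of the
1 s pulse).

**Paired-pulse inhibition and EPSP–spike coupling.** Both are quantified
by the bottom-pinned Boltzmann sigmoid

    y(x) = Top / (1 + exp((v50 − x) / k)),

fitted by bounded nonlinear least squares; fits with R² ≤ 0.8 are
excluded. For PPI, x is the interpulse interval (fit up to 100 ms) and
y the second population spike as % of the first; the interpulse
intervals at which the second spike reaches 50/75/100% of the first are
obtained from the closed-form inversion x = v50 − k·ln(Top/y − 1).
Shared-versus-separate curves are compared with the extra
sum-of-squares F test.

**Statistics.** D'Agostino–Pearson normality screening; Welch's t test
with the 95% CI of the difference (from raw samples or printed
mean/SEM/n); exact Mann–Whitney with the Hodges–Lehmann median
difference and its exact CI; uncorrected χ² independence for 2×2
tables; two-way repeated-measures ANOVA with a compound-symmetry REML
mixed-model variant for incomplete data; Bonferroni post-tests.

## Worked example

`examples/ppi_study.py` runs the full paired-pulse inhibition chain on
a simulated two-genotype study (17 WT vs 16 KO animals, KO v50 shifted
+4.5 ms):

```
fitted 33 animals; 33 pass the R^2 > 0.8 gate
group comparison (difference oriented WT - KO):
          measure                 test  n_WT  n_KO   mean_WT   mean_KO  difference    ci_low   ci_high        p
     PPI v50 (ms) Welch t (two-tailed)    17    16 41.398155 44.550832   -3.152677 -6.227817 -0.077536 0.044889
 PPI 50% IPI (ms) Welch t (two-tailed)    17    16 40.416375 43.507122   -3.090748 -6.116454 -0.065041 0.045600
```

The negative v50 difference means the KO inhibition curve is
right-shifted: the second population spike needs a longer interpulse
interval to recover, i.e. network inhibition is stronger in the KO
group. The other example scripts (`psc_detection.py`, `intrinsic_fi.py`,
`evoked_field.py`) each exercise one stage against ground truth and
print what they measure.

A thin CLI covers the shell-friendly paths:
`dgephys sim psc|fi|field --seed N --out FILE` and
`dgephys run --config study.yaml`.

## Data formats

Experiments round-trip losslessly through an HDF5 container (one group
per sweep, JSON-encoded metadata) or, for single sweeps, two-column
`time_s,value` text with a JSON sidecar. A read-only Axon Binary Format
adapter (`dgephys.abf`) is available when `pyabf` is installed; nothing
in the core requires it. Event tables, fit tables and study summaries
are pandas DataFrames and export to CSV.
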