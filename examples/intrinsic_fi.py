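"""Frequency-current analysis of a model granule cell.

Integrates the adaptive integrate-and-fire cell over the full current
step protocol (-100 to 490 pA in 10 pA steps, 1 s pulses) and extracts
every intrinsic-excitability measure: rheobase, F-I curve, maximum
firing rate, depolarization block, AP shape, ISI adaptation ratio,
input resistance and resting potential.
"""

from dgephys import intrinsic, simulate

experiment, truth = simulate.simulate_fi_sweeps(seed=0)
fi = intrinsic.fi_curve(experiment)

print(f"closed-form rheobase of the model: {truth.rheobase_pA:.0f} pA")
print(f"detected rheobase:                 {fi.rheobase_pA:.0f} pA "
      "(first step on the 10 pA grid with a spike)")
print(f"resting potential: {fi.resting_potential_mV:.1f} mV")
print(f"input resistance:  {fi.input_resistance_MOhm:.1f} MOhm "
      "(linear fit over the -100..-10 pA steps)")
print(f"max firing rate:   {fi.max_rate_Hz:.0f} Hz "
      f"at {fi.current_at_max_rate_pA:.0f} pA")
print(f"ISI adaptation ratio at the max-rate step: "
      f"{fi.isi_ratio_at_max_rate:.2f} (first ISI / last ISI; <1 = adapting)")
print(f"depolarization block entered: {fi.depol_block_entered} "
      f"(lowest blocked step {fi.depol_block_current_pA:.0f} pA; a step is "
      "blocked when its last spike precedes 0.9 s)")
ap = fi.ap_features
print(f"AP at rheobase: prominence {ap.prominence_mV:.1f} mV, "
      f"half-width {ap.half_width_ms:.2f} ms")

print("\nF-I curve (suprathreshold steps):")
tbl = fi.rates()
print(tbl[tbl["n_spikes"] > 0].head(10).to_string(index=False))
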