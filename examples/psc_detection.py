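"""Detect spontaneous EPSCs in a simulated voltage-clamp recording.

Generates one minute of sEPSC activity (Poisson events, biexponential
kernels, Gaussian noise), applies the 1 kHz zero-phase elliptic filter,
detects events with the 3 pA threshold, and scores the detector against
the generator's ground truth.
"""

import numpy as np

from dgephys import events, simulate

sweep, truth = simulate.simulate_psc_trace(
    rate_Hz=10.0, amp_mean_pA=20.0, noise_sd_pA=1.0, duration_s=60.0, seed=0)

filtered = events.lowpass_filter(sweep)
detected = events.detect_events(filtered, threshold_pA=3.0, polarity="inward")
matched, missed, spurious = events.match_events(detected, truth.event_times_s)
summary = events.summarize_cell(detected, duration_s=sweep.duration_s,
                                cell_id="demo")

print(f"ground truth: {truth.event_times_s.size} events in 60 s")
print(f"detected:     {len(detected)} "
      f"(matched {len(matched)}, missed {len(missed)}, "
      f"spurious {len(spurious)})")
print(f"recall {len(matched) / truth.event_times_s.size:.3f}, "
      f"precision {len(matched) / len(detected):.3f}")
print(f"mean amplitude {summary.mean_amplitude_pA:.2f} pA, "
      f"frequency {summary.frequency_Hz:.2f} Hz")
print(f"mean 10-90% rise {summary.mean_rise_ms:.2f} ms, "
      f"mean 1/e decay {summary.mean_decay_ms:.2f} ms")
print(f"qualifies for group analysis (>=100 events): {summary.qualifies}")

# amplitude accuracy against truth on the matched events
amp_by_time = dict(zip(truth.event_times_s, truth.event_amplitudes_pA))
err = np.mean([abs(e.amplitude_pA - amp_by_time[t]) for t, e in matched])
print(f"mean |amplitude error| on matched events: {err:.2f} pA")
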