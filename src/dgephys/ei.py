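"""Evoked excitation/inhibition ratio of individual cells.

EPSCs are recorded at -60 mV and IPSCs at +10 mV holding potential in
the same cell at the same stimulation intensity (5-6 repeats each); the
E/I ratio is the magnitude of the mean EPSC peak over the magnitude of
the mean IPSC peak.  Peaks are measured per repeat and then averaged
(robust to latency jitter); averaging the traces first is available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Sweep, ValidationError


@dataclass
class EvokedPscSet:
    """Paired EPSC/IPSC peak measurements for one cell."""

    cell_id: str
    epsc_peaks_pA: Sequence[float]   # at -60 mV, typically 5-6 repeats
    ipsc_peaks_pA: Sequence[float]   # at +10 mV
    stimulation_intensity_uA: Optional[float] = None

    def __post_init__(self) -> None:
        for name, peaks in (("EPSC", self.epsc_peaks_pA),
                            ("IPSC", self.ipsc_peaks_pA)):
            if not 1 <= len(peaks) <= 10:
                raise ValidationError(f"{name}: expected 1-10 repeats, "
                                      f"got {len(peaks)}")


def peak_from_sweep(sweep: Sweep, stim_time_s: float, polarity: str,
                    blank_ms: float = 1.0, window_ms: float = 50.0) -> float:
    """Peak current (signed, pA) of one evoked response.

    Baseline-subtracted extremum of the artifact-blanked response
    window; ``polarity`` 'inward' takes the minimum, 'outward' the
    maximum.
    """
    fs = sweep.sampling_rate
    i_stim = sweep.index_of(stim_time_s)
    i0 = i_stim + int(np.ceil(blank_ms * 1e-3 * fs))
    i1 = min(sweep.n_samples, i_stim + int(round(window_ms * 1e-3 * fs)))
    base = float(np.mean(sweep.samples[max(0, i_stim - int(0.02 * fs)):i_stim]))
    seg = sweep.samples[i0:i1] - base
    if polarity == "inward":
        return float(np.min(seg))
    if polarity == "outward":
        return float(np.max(seg))
    raise ValidationError("polarity must be 'inward' or 'outward'")


def ei_ratio(psc_set: EvokedPscSet) -> float:
    """|mean EPSC peak| / |mean IPSC peak|; NaN when the IPSC mean is 0."""
    e = float(np.mean(psc_set.epsc_peaks_pA))
    i = float(np.mean(psc_set.ipsc_peaks_pA))
    if i == 0:
        return float("nan")
    return abs(e) / abs(i)
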