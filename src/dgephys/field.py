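"""Evoked field-potential quantification.

Operators for in vivo perforant-path recordings from the dentate granule
cell layer: fEPSP rising slope (steepest 0.5 ms sliding-window regression
before the population-spike onset), population-spike amplitude by the
tangent method (trough to the line joining the flanking positive peaks),
input-output curves, paired-pulse facilitation/inhibition ratios, and
baseline-normalised LTP time courses.  All operators are invariant to DC
offsets and linear in signal scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .model import Sweep, ValidationError

ARTIFACT_BLANK_MS = 1.0
SLOPE_WINDOW_MS = 0.5
RESPONSE_WINDOW_MS = 25.0
SPIKE_NOISE_CRITERION = 5.0   # trough must exceed this x baseline noise sd


class SlopeMeasurement(NamedTuple):
    value_Vps: float
    flagged: bool


class SpikeMeasurement(NamedTuple):
    amplitude_mV: float
    flagged: bool


@dataclass
class EvokedResponse:
    """Measured quantities for one stimulus."""

    stim_time_s: float
    fepsp_slope_Vps: float
    pop_spike_amplitude_mV: float
    slope_flagged: bool = False
    spike_flagged: bool = False


def _segment(sweep: Sweep, stim_time_s: float, blank_ms: float,
             window_ms: float) -> Tuple[np.ndarray, int, float]:
    fs = sweep.sampling_rate
    i0 = sweep.index_of(stim_time_s) + int(math.ceil(blank_ms * 1e-3 * fs))
    i1 = min(sweep.n_samples, sweep.index_of(stim_time_s)
             + int(round(window_ms * 1e-3 * fs)))
    if i1 - i0 < 4:
        raise ValidationError("response window too short")
    return sweep.samples[i0:i1], i0, fs


def _baseline_noise_sd(sweep: Sweep, stim_time_s: float) -> float:
    fs = sweep.sampling_rate
    i = sweep.index_of(stim_time_s)
    j = max(0, i - int(round(0.02 * fs)))
    if i - j < 5:
        return 0.0
    base = sweep.samples[j:i]
    return float(np.std(base - np.mean(base)))


def _sliding_slopes(y: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    """Least-squares slope of every ``window_ms`` segment, in V/s.

    Uses the closed-form regression weights for uniformly spaced samples,
    evaluated by convolution.
    """
    n = max(2, int(round(window_ms * 1e-3 * fs)))
    k = np.arange(n) - (n - 1) / 2.0
    w = k * 12.0 / (n * (n * n - 1.0)) * fs  # per-second slope weights
    if y.size < n:
        raise ValidationError("segment shorter than the slope window")
    return np.convolve(y, w[::-1], mode="valid") * 1e-3  # mV -> V


def measure_fepsp_slope(sweep: Sweep, stim_time_s: float,
                        blank_ms: float = ARTIFACT_BLANK_MS,
                        window_ms: float = SLOPE_WINDOW_MS,
                        response_window_ms: float = RESPONSE_WINDOW_MS,
                        ) -> SlopeMeasurement:
    """Maximal rising slope of the fEPSP (V/s).

    The steepest ``window_ms`` regression slope between the end of the
    artifact-blanking window and the population-spike onset (or the fEPSP
    peak when no spike is present).  A flat sweep (no deflection above
    5x the pre-stimulus noise) returns 0 with a flag.
    """
    y, i0, fs = _segment(sweep, stim_time_s, blank_ms, response_window_ms)
    noise = _baseline_noise_sd(sweep, stim_time_s)
    if np.max(np.abs(y - y[0])) <= SPIKE_NOISE_CRITERION * noise or np.ptp(y) == 0:
        return SlopeMeasurement(0.0, True)
    # restrict to the rising phase: up to the positive peak preceding the
    # population-spike trough if a spike is present, else the fEPSP peak
    best = _best_spike_candidate(y, noise, "tangent")
    if best is not None:
        end = int(np.argmax(y[: best[1] + 1]))
    else:
        end = int(np.argmax(y))
    end = max(end, int(round(window_ms * 1e-3 * fs)) + 1)
    slopes = _sliding_slopes(y[:end + 1], fs, window_ms)
    return SlopeMeasurement(float(np.max(slopes)), False)


def _best_spike_candidate(y: np.ndarray, noise: float, method: str):
    """Largest-by-tangent population-spike candidate in a response segment.

    Returns ``(amplitude, trough_idx, n_candidates)`` or None when no
    trough deviates from its tangent line by more than 5x the noise sd.
    A prominence floor of 1% of the segment span guards against numerical
    micro-dips on noiseless traces (where the noise estimate is ~0).
    """
    prom = max(3.0 * noise, 0.01 * float(np.ptp(y)), 1e-12)
    troughs, _ = signal.find_peaks(-y, prominence=prom)
    best = None
    n_cand = 0
    for tr in troughs:
        pre, post = y[:tr], y[tr + 1:]
        if pre.size == 0 or post.size == 0:
            continue
        p1 = int(np.argmax(pre))
        p2 = tr + 1 + int(np.argmax(post))
        if y[p1] <= y[tr] or y[p2] <= y[tr]:
            continue
        frac = (tr - p1) / (p2 - p1)
        line = y[p1] + frac * (y[p2] - y[p1])
        amp_tan = line - y[tr]
        amp = amp_tan if method == "tangent" else y[p1] - y[tr]
        if amp_tan > SPIKE_NOISE_CRITERION * noise:
            n_cand += 1
            if best is None or amp > best[0]:
                best = (float(amp), tr)
    if best is None:
        return None
    return best[0], best[1], n_cand


def measure_pop_spike(sweep: Sweep, stim_time_s: float,
                      blank_ms: float = ARTIFACT_BLANK_MS,
                      response_window_ms: float = RESPONSE_WINDOW_MS,
                      method: str = "tangent") -> SpikeMeasurement:
    """Population-spike amplitude (mV), tangent method by default.

    Tangent: vertical distance from the negative trough to the straight
    line joining the two flanking positive peaks.  ``method='trough_peak'``
    measures trough to the first (preceding) positive peak instead.
    Returns 0 when no trough deviates from the tangent line by more than
    5x the pre-stimulus noise sd.  With several candidate troughs the
    largest tangent measure is used and the result is flagged.
    """
    if method not in ("tangent", "trough_peak"):
        raise ValidationError(f"unknown method {method!r}")
    y, i0, fs = _segment(sweep, stim_time_s, blank_ms, response_window_ms)
    noise = _baseline_noise_sd(sweep, stim_time_s)
    best = _best_spike_candidate(y, noise, method)
    if best is None:
        return SpikeMeasurement(0.0, False)
    amp, _, n_cand = best
    return SpikeMeasurement(amp, n_cand > 1)


def measure_evoked(sweep: Sweep, stim_time_s: float, **kwargs) -> EvokedResponse:
    """Slope and spike amplitude for one stimulus."""
    sl = measure_fepsp_slope(sweep, stim_time_s, **kwargs)
    sp = measure_pop_spike(sweep, stim_time_s, **kwargs)
    return EvokedResponse(stim_time_s=stim_time_s, fepsp_slope_Vps=sl.value_Vps,
                          pop_spike_amplitude_mV=sp.amplitude_mV,
                          slope_flagged=sl.flagged, spike_flagged=sp.flagged)


@dataclass
class IOCurve:
    """Input-output relationship over a stimulation-intensity grid."""

    table: pd.DataFrame  # intensity_uA, fepsp_slope_Vps, pop_spike_mV (means)
    spike_onset_intensity_uA: Optional[float]


def io_analysis(responses: pd.DataFrame) -> IOCurve:
    """Summarise per-sweep measurements into an input-output curve.

    ``responses`` needs columns ``intensity_uA``, ``fepsp_slope_Vps`` and
    ``pop_spike_mV`` (one row per sweep or per subject x intensity).  The
    spike-onset intensity is the lowest intensity with a detected
    (positive) mean population spike.
    """
    tbl = (responses.groupby("intensity_uA", as_index=False)
           [["fepsp_slope_Vps", "pop_spike_mV"]].mean()
           .sort_values("intensity_uA", ignore_index=True))
    with_spike = tbl.loc[tbl["pop_spike_mV"] > 0, "intensity_uA"]
    onset = float(with_spike.iloc[0]) if not with_spike.empty else None
    return IOCurve(table=tbl, spike_onset_intensity_uA=onset)


def paired_pulse_ratio(response1: float, response2: float,
                       mode: str = "ppi_spike") -> float:
    """Second response as percent of the first.

    ``mode='ppf_slope'`` expects fEPSP slopes (facilitation);
    ``mode='ppi_spike'`` expects population-spike amplitudes (inhibition;
    an absent second spike gives 0%).  A zero first response makes the
    ratio undefined (NaN).
    """
    if mode not in ("ppf_slope", "ppi_spike"):
        raise ValidationError(f"unknown mode {mode!r}")
    if response1 == 0:
        return float("nan")
    if mode == "ppi_spike" and response2 == 0:
        return 0.0
    return 100.0 * response2 / response1


@dataclass
class PairedPulseCurve:
    ipi_ms: np.ndarray
    percent_of_first: np.ndarray
    mode: str
    intensity_regime: str = "maximal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ipi_ms": self.ipi_ms,
                             "percent_of_first": self.percent_of_first})


def paired_pulse_curve(sweeps_by_ipi: dict, mode: str = "ppi_spike",
                       intensity_regime: str = "maximal") -> PairedPulseCurve:
    """Measure a paired-pulse curve from paired-stimulus sweeps.

    ``sweeps_by_ipi`` maps interpulse interval (ms) to a field sweep
    whose metadata carries ``stim_times_s`` (two entries).
    """
    ipis = np.array(sorted(sweeps_by_ipi), dtype=float)
    pcts = np.empty(ipis.size)
    for i, ipi in enumerate(ipis):
        sw = sweeps_by_ipi[ipi]
        t1, t2 = sw.metadata["stim_times_s"][:2]
        # limit each response window to the interpulse interval
        win = min(RESPONSE_WINDOW_MS, (t2 - t1) * 1e3 - 0.5)
        if mode == "ppi_spike":
            r1 = measure_pop_spike(sw, t1, response_window_ms=win).amplitude_mV
            r2 = measure_pop_spike(sw, t2, response_window_ms=win).amplitude_mV
        else:
            r1 = measure_fepsp_slope(sw, t1, response_window_ms=win).value_Vps
            r2 = measure_fepsp_slope(sw, t2, response_window_ms=win).value_Vps
        pcts[i] = paired_pulse_ratio(r1, r2, mode=mode)
    return PairedPulseCurve(ipi_ms=ipis, percent_of_first=pcts, mode=mode,
                            intensity_regime=intensity_regime)


@dataclass
class LtpTimecourse:
    """Baseline-normalised response time course around LTP induction."""

    table: pd.DataFrame  # time_min, percent_of_baseline (per measure)
    early_mean_percent: float   # 0-10 min
    late_mean_percent: float    # 50-60 min


def ltp_timecourse(times_min: Sequence[float], values: Sequence[float],
                   induction_time_min: float = 0.0,
                   baseline_min: float = 10.0,
                   early_window_min: Tuple[float, float] = (0.0, 10.0),
                   late_window_min: Tuple[float, float] = (50.0, 60.0),
                   ) -> LtpTimecourse:
    """Normalise an evoked-response time series to its pre-induction baseline.

    Each response is expressed as percent of the mean over the
    ``baseline_min`` minutes before induction (so the baseline mean is
    100% by construction); window means are reported for the early
    (0-10 min) and late (50-60 min) post-induction phases.
    """
    t = np.asarray(times_min, dtype=float) - induction_time_min
    v = np.asarray(values, dtype=float)
    base = v[(t >= -baseline_min) & (t < 0)]
    if base.size == 0:
        raise ValidationError("no baseline data before induction")
    pct = 100.0 * v / np.mean(base)
    tbl = pd.DataFrame({"time_min": t, "percent_of_baseline": pct})
    early = pct[(t >= early_window_min[0]) & (t < early_window_min[1])]
    late = pct[(t >= late_window_min[0]) & (t <= late_window_min[1])]
    return LtpTimecourse(
        table=tbl,
        early_mean_percent=float(np.mean(early)) if early.size else float("nan"),
        late_mean_percent=float(np.mean(late)) if late.size else float("nan"))
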