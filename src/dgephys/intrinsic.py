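"""Intrinsic-excitability measures from current-clamp step protocols.

Covers the full current-clamp quantification chain: spike detection
(voltage peaks above 0 mV with a >20 V/s upstroke), the F-I curve and
rheobase, maximum firing frequency, depolarization-block classification
(last spike earlier than 0.9 s within a 1 s step), action-potential
prominence and width at half-maximal prominence, the first-to-last ISI
adaptation ratio, input resistance from the hyperpolarizing steps
(-100..-10 pA), and resting membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .model import Experiment, StepProtocol, Sweep, ValidationError

SPIKE_PEAK_THRESHOLD_MV = 0.0
SPIKE_UPSTROKE_VPS = 20.0
DEPOL_BLOCK_CRITERION_S = 0.9


@dataclass
class SpikeTrain:
    step_current_pA: float
    spike_peak_times_s: np.ndarray   # relative to step onset
    spike_peak_values_mV: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(self.spike_peak_times_s.size)


@dataclass
class APFeatures:
    prominence_mV: float
    half_width_ms: float
    unreliable: bool = False  # set for clipped (saturated) peaks


@dataclass
class FIResult:
    trains: Dict[float, SpikeTrain] = field(default_factory=dict)
    step_duration_s: float = 1.0
    rheobase_pA: Optional[float] = None
    max_rate_Hz: Optional[float] = None
    current_at_max_rate_pA: Optional[float] = None
    last_spike_time_per_step_s: Dict[float, Optional[float]] = field(default_factory=dict)
    depol_block_entered: bool = False
    depol_block_current_pA: Optional[float] = None
    isi_ratio_at_max_rate: Optional[float] = None
    input_resistance_MOhm: Optional[float] = None
    resting_potential_mV: Optional[float] = None
    ap_features: Optional[APFeatures] = None

    def rates(self) -> pd.DataFrame:
        """F-I table: one row per step current."""
        rows = [(I, tr.n_spikes, tr.n_spikes / self.step_duration_s)
                for I, tr in sorted(self.trains.items())]
        return pd.DataFrame(rows, columns=["current_pA", "n_spikes", "rate_Hz"])


def _step_window(sweep: Sweep) -> Tuple[float, float]:
    proto = sweep.protocol
    if not isinstance(proto, StepProtocol):
        raise ValidationError("sweep carries no step protocol")
    return proto.step_onset_s, proto.step_onset_s + proto.step_duration_s


def detect_spikes(sweep: Sweep, window_s: Optional[Tuple[float, float]] = None,
                  peak_threshold_mV: float = SPIKE_PEAK_THRESHOLD_MV,
                  upstroke_Vps: float = SPIKE_UPSTROKE_VPS,
                  refractory_ms: float = 1.0) -> SpikeTrain:
    """Detect action potentials within the step window.

    A spike is a voltage peak above ``peak_threshold_mV`` whose maximal
    upstroke dV/dt in the preceding millisecond exceeds ``upstroke_Vps``;
    peaks closer than ``refractory_ms`` are merged (highest wins).
    """
    if sweep.channel_kind != "current_clamp_voltage":
        raise ValidationError("spike detection expects a current-clamp sweep")
    t0, t1 = window_s if window_s is not None else _step_window(sweep)
    fs = sweep.sampling_rate
    i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), sweep.n_samples)
    v = sweep.samples[i0:i1]
    dist = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = signal.find_peaks(v, height=peak_threshold_mV, distance=dist)
    dvdt = np.gradient(v) * fs / 1e3  # V/s (mV/sample * samples/s / 1000)
    look = max(1, int(round(1e-3 * fs)))
    keep = [p for p in peaks
            if np.max(dvdt[max(0, p - look):p + 1]) > upstroke_Vps]
    keep = np.asarray(keep, dtype=int)
    I = sweep.metadata.get("step_current_pA", np.nan)
    return SpikeTrain(step_current_pA=float(I),
                      spike_peak_times_s=keep / fs,
                      spike_peak_values_mV=v[keep] if keep.size else np.empty(0))


def resting_potential(sweep: Sweep, baseline_s: Optional[Tuple[float, float]] = None,
                      ) -> float:
    """Mean membrane voltage over the pre-stimulus baseline window."""
    if baseline_s is None:
        on, _ = _step_window(sweep)
        baseline_s = (0.0, on)
    t0, t1 = baseline_s
    if t1 - t0 < 0.1:
        raise ValidationError("baseline window must be at least 100 ms")
    fs = sweep.sampling_rate
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > sweep.n_samples:
        raise ValidationError("baseline window outside the sweep")
    return float(np.mean(sweep.samples[i0:i1]))


def input_resistance(experiment: Experiment,
                     current_range_pA: Tuple[float, float] = (-100.0, -10.0),
                     steady_state_ms: float = 200.0) -> float:
    """Input resistance (MOhm) from the hyperpolarizing steps.

    Voltage deflection per step = mean over the last ``steady_state_ms``
    of the step minus the pre-step baseline mean; the resistance is the
    least-squares slope of deflection against injected current, using
    only steps inside ``current_range_pA``.
    """
    dvs, currents = [], []
    for sw in experiment:
        I = sw.metadata.get("step_current_pA")
        if I is None or not current_range_pA[0] <= I <= current_range_pA[1]:
            continue
        on, off = _step_window(sw)
        fs = sw.sampling_rate
        base = np.mean(sw.samples[: int(round(on * fs))])
        j0 = int(round((off - steady_state_ms * 1e-3) * fs))
        j1 = int(round(off * fs))
        dvs.append(float(np.mean(sw.samples[j0:j1]) - base))
        currents.append(float(I))
    if len(currents) < 3:
        raise ValidationError(
            f"need >= 3 hyperpolarizing steps in {current_range_pA}, "
            f"found {len(currents)}")
    slope = stats.linregress(currents, dvs).slope  # mV / pA == GOhm
    return float(slope * 1e3)  # MOhm


def isi_adaptation_ratio(train: SpikeTrain) -> Optional[float]:
    """First ISI divided by the last ISI; None for trains with <3 spikes."""
    t = train.spike_peak_times_s
    if t.size < 3:
        return None
    isis = np.diff(t)
    return float(isis[0] / isis[-1])


def ap_features(sweep: Sweep, spike_time_s: Optional[float] = None,
                window_ms: float = 20.0) -> APFeatures:
    """Prominence and half-width of one action potential.

    Prominence is the topographic peak prominence (peak voltage minus the
    higher of the flanking minima, evaluated within the step window);
    half-width is the peak width at half-maximal prominence with linear
    interpolation.  Saturated (flat-topped) peaks are flagged unreliable.
    """
    t0, t1 = _step_window(sweep)
    fs = sweep.sampling_rate
    i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), sweep.n_samples)
    v = sweep.samples[i0:i1]
    if spike_time_s is None:
        train = detect_spikes(sweep)
        if train.n_spikes == 0:
            raise ValidationError("no spike in sweep")
        spike_time_s = float(train.spike_peak_times_s[0])
    pk = int(round(spike_time_s * fs))
    half_win = max(1, int(round(window_ms * 1e-3 * fs)))
    lo, hi = max(0, pk - half_win), min(v.size, pk + half_win)
    seg = v[lo:hi]
    pk_rel = pk - lo
    # re-snap to the local maximum (robust to rounding of the peak time)
    lo2 = max(0, pk_rel - 3)
    pk_rel = lo2 + int(np.argmax(seg[lo2:pk_rel + 4]))
    prom = signal.peak_prominences(seg, [pk_rel])[0][0]
    widths = signal.peak_widths(seg, [pk_rel], rel_height=0.5)[0][0]
    clipped = bool(pk_rel + 1 < seg.size and seg[pk_rel] == seg[pk_rel + 1])
    return APFeatures(prominence_mV=float(prom),
                      half_width_ms=float(widths / fs * 1e3),
                      unreliable=clipped)


def fi_curve(experiment: Experiment,
             block_criterion_s: float = DEPOL_BLOCK_CRITERION_S) -> FIResult:
    """Full per-cell frequency-current analysis.

    Rheobase is the smallest step current eliciting at least one spike;
    the maximum firing frequency is the largest count/duration over
    steps, ties broken toward the lowest current; the ISI adaptation
    ratio is evaluated at that maximal-rate step.
    """
    res = FIResult()
    proto = None
    baseline_sweep = None
    for sw in experiment:
        if not isinstance(sw.protocol, StepProtocol):
            continue
        proto = sw.protocol
        I = float(sw.metadata["step_current_pA"])
        train = detect_spikes(sw)
        res.trains[I] = train
        res.last_spike_time_per_step_s[I] = (
            float(train.spike_peak_times_s[-1]) if train.n_spikes else None)
        if baseline_sweep is None:
            baseline_sweep = sw
    if proto is None:
        raise ValidationError("experiment contains no step-protocol sweeps")
    res.step_duration_s = proto.step_duration_s

    supra = sorted(I for I, tr in res.trains.items() if tr.n_spikes > 0)
    res.rheobase_pA = supra[0] if supra else None

    if supra:
        tbl = res.rates()
        imax = int(np.argmax(tbl["rate_Hz"].to_numpy()))  # first max = lowest I
        res.max_rate_Hz = float(tbl["rate_Hz"].iloc[imax])
        res.current_at_max_rate_pA = float(tbl["current_pA"].iloc[imax])
        res.isi_ratio_at_max_rate = isi_adaptation_ratio(
            res.trains[res.current_at_max_rate_pA])

    res.depol_block_entered, res.depol_block_current_pA = depolarization_block(
        res, criterion_s=block_criterion_s)

    try:
        res.input_resistance_MOhm = input_resistance(experiment)
    except ValidationError:
        res.input_resistance_MOhm = None
    res.resting_potential_mV = resting_potential(baseline_sweep)

    if res.rheobase_pA is not None:
        rheo_sweep = next(sw for sw in experiment
                          if sw.metadata.get("step_current_pA") == res.rheobase_pA)
        tr = res.trains[res.rheobase_pA]
        res.ap_features = ap_features(rheo_sweep,
                                      float(tr.spike_peak_times_s[0]))
    return res


def depolarization_block(fi: FIResult,
                         criterion_s: float = DEPOL_BLOCK_CRITERION_S,
                         from_current: str = "max_rate",
                         ) -> Tuple[bool, Optional[float]]:
    """Classify entry into depolarization block.

    A step is blocked when it elicits at least one spike but the last
    spike falls before ``criterion_s`` within the step.  The cell-level
    flag is true if any step at or above the reference current is
    blocked; ``from_current='max_rate'`` (default) references the
    current of maximal firing rate — depolarization block is a
    truncation of firing beyond the F-I peak, and sparse near-rheobase
    trains whose single late spikes happen to precede the criterion are
    not block — while ``'rheobase'`` references the rheobase.  Returns
    the flag and the lowest blocked step current.
    """
    if fi.rheobase_pA is None:
        return False, None
    ref = (fi.current_at_max_rate_pA if from_current == "max_rate"
           else fi.rheobase_pA)
    if ref is None:
        ref = fi.rheobase_pA
    blocked = sorted(
        I for I, last in fi.last_spike_time_per_step_s.items()
        if I >= ref and last is not None and last < criterion_s)
    if blocked:
        return True, blocked[0]
    return False, None


def block_contingency(flags_by_group: Dict[str, Sequence[bool]]) -> pd.DataFrame:
    """2x2 contingency table of depolarization-block entry by group.

    Rows are groups, columns ``yes``/``no``; row sums equal cohort sizes.
    """
    rows = {}
    for group, flags in flags_by_group.items():
        flags = list(flags)
        rows[group] = {"yes": int(sum(flags)),
                       "no": int(len(flags) - sum(flags))}
    return pd.DataFrame.from_dict(rows, orient="index")[["yes", "no"]]
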