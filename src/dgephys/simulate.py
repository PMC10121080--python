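"""Synthetic sweep and study generators with known ground truth.

The study this package quantifies deposited no raw recordings, so every
analysis stage is exercised against simulated data whose generative
parameters are known exactly:

* :func:`simulate_psc_trace` — postsynaptic-current sweeps: a Poisson
  event train convolved with a peak-normalised biexponential kernel plus
  white Gaussian noise.
* :func:`simulate_fi_sweeps` — current-step sweeps from an adaptive
  leaky integrate-and-fire (LIF) granule-cell model with a slow
  inactivation gate that produces depolarization block (a spikeless
  plateau once the gate falls below its threshold).  With adaptation and
  block disabled the model's rheobase is the closed form
  ``g_L * (V_th - E_L)``.
* :func:`simulate_field_experiment` — a two-group evoked field-potential
  study: saturating input-output curve, Boltzmann EPSP-spike coupling,
  and paired-pulse inhibition following a ground-truth Boltzmann of the
  interpulse interval with subject-level v50 jitter.
* :func:`simulate_two_group_samples` — calibration samples for the
  statistics layer.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams; identical seed and parameters
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_SAMPLING_RATE,
    Experiment,
    StepProtocol,
    Sweep,
    ValidationError,
)

try:  # optional jit for the LIF inner loop; pure-Python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not args or not callable(args[0]) else args[0]


@dataclass
class SyntheticTruth:
    """Ground-truth record attached to simulated data."""

    rng_seed: Optional[int] = None
    event_times_s: Optional[np.ndarray] = None
    event_amplitudes_pA: Optional[np.ndarray] = None
    spike_parameters: Optional["NeuronParams"] = None
    spike_times_per_step: Optional[dict] = None
    rheobase_pA: Optional[float] = None
    ground_truth_boltzmann: Optional[dict] = None
    group_effects: Optional[dict] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# postsynaptic-current traces

def biexp_kernel(t_s: np.ndarray, tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Biexponential synaptic kernel normalised to unit peak.

    ``k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / peak`` for t >= 0.  The
    peak normalisation makes ground-truth amplitudes directly comparable
    to measured baseline-to-peak amplitudes.
    """
    if not tau_decay_ms > tau_rise_ms > 0:
        raise ValidationError("need tau_decay > tau_rise > 0")
    tr, td = tau_rise_ms / 1e3, tau_decay_ms / 1e3
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    out = np.zeros_like(t_s, dtype=float)
    pos = t_s >= 0
    out[pos] = (np.exp(-t_s[pos] / td) - np.exp(-t_s[pos] / tr)) / peak
    return out


def simulate_psc_trace(rate_Hz: float,
                       tau_rise_ms: float = 1.0,
                       tau_decay_ms: float = 10.0,
                       amp_mean_pA: float = 20.0,
                       amp_sigma: float = 0.25,
                       noise_sd_pA: float = 2.0,
                       duration_s: float = 60.0,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE,
                       polarity: str = "inward",
                       seed: Optional[int] = None,
                       event_times_s: Optional[Sequence[float]] = None,
                       event_amplitudes_pA: Optional[Sequence[float]] = None,
                       ) -> Tuple[Sweep, SyntheticTruth]:
    """Simulate a voltage-clamp current sweep containing synaptic events.

    Event times are homogeneous Poisson at ``rate_Hz``; amplitudes are
    lognormal with the given *linear-scale* mean and log-sd ``amp_sigma``.
    Pass explicit ``event_times_s``/``event_amplitudes_pA`` to bypass the
    random draw (e.g. a single noiseless event for kernel checks).
    ``polarity='inward'`` renders events as negative (downward) current
    deflections, the EPSC convention at negative holding potentials.
    """
    if rate_Hz < 0:
        raise ValidationError("rate_Hz must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate

    if event_times_s is None:
        n_ev = rng.poisson(rate_Hz * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s, size=n_ev))
    else:
        times = np.sort(np.asarray(event_times_s, dtype=float))
        n_ev = times.size
    if event_amplitudes_pA is None:
        # lognormal parameterised by its linear-scale mean
        mu = math.log(amp_mean_pA) - 0.5 * amp_sigma ** 2
        amps = rng.lognormal(mu, amp_sigma, size=n_ev)
    else:
        amps = np.asarray(event_amplitudes_pA, dtype=float)
        if amps.size != n_ev:
            raise ValidationError("event times and amplitudes differ in length")

    trace = np.zeros(n)
    # kernel support: ~8 decay time constants
    n_k = int(round(8 * tau_decay_ms / 1e3 * sampling_rate)) + 1
    kern = biexp_kernel(np.arange(n_k) / sampling_rate, tau_rise_ms, tau_decay_ms)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * sampling_rate))
        seg = kern[: n - i0]
        trace[i0:i0 + seg.size] += a * seg
    if polarity == "inward":
        trace = -trace
    elif polarity != "outward":
        raise ValidationError("polarity must be 'inward' or 'outward'")
    if noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, noise_sd_pA, size=n)

    sweep = Sweep(samples=trace, sampling_rate=sampling_rate,
                  channel_kind="voltage_clamp_current",
                  metadata={"polarity": polarity, "synthetic": True})
    truth = SyntheticTruth(rng_seed=seed, event_times_s=times,
                           event_amplitudes_pA=amps,
                           extras={"tau_rise_ms": tau_rise_ms,
                                   "tau_decay_ms": tau_decay_ms,
                                   "noise_sd_pA": noise_sd_pA})
    return sweep, truth


# ---------------------------------------------------------------------------
# adaptive LIF with depolarization block

@dataclass
class NeuronParams:
    """Adaptive leaky integrate-and-fire granule-cell model.

    Units: capacitance pF, conductance nS, voltage mV, current pA,
    time ms (this set is internally consistent: pF*mV/ms = pA = nS*mV).

    Depolarization block is produced by a slow dimensionless gate ``h``
    (sodium-channel availability): each spike decrements ``h`` by
    ``block_spike_decrement`` and between spikes ``h`` relaxes toward a
    sigmoidal steady state ``h_inf(V)`` with time constant
    ``block_tau_ms``.  Spiking requires ``h >= h_block``; once the gate
    falls below threshold the cell sits on a spikeless depolarized
    plateau, where ``h_inf`` is near zero, so the block is sustained.
    """

    C_pF: float = 30.0
    g_L_nS: float = 5.0
    E_L_mV: float = -80.0
    V_th_mV: float = -59.0
    V_reset_mV: float = -70.0
    b_pA: float = 60.0            # adaptation increment per spike
    tau_w_ms: float = 140.0       # adaptation time constant
    refractory_ms: float = 2.0
    block_enabled: bool = True
    h_block: float = 0.75
    block_spike_decrement: float = 0.032
    block_tau_ms: float = 250.0
    block_vhalf_mV: float = -50.0
    block_slope_mV: float = 4.0
    spike_peak_mV: float = 35.0
    spike_rise_ms: float = 0.5
    spike_fall_ms: float = 1.3

    def __post_init__(self) -> None:
        if not (self.g_L_nS > 0 and self.C_pF > 0):
            raise ValidationError("g_L and C must be positive")
        if not self.V_th_mV > self.E_L_mV:
            raise ValidationError("V_th must exceed E_L")

    @property
    def rheobase_closed_form_pA(self) -> float:
        """Minimal sustained current that reaches threshold: g_L*(V_th-E_L)."""
        return self.g_L_nS * (self.V_th_mV - self.E_L_mV)

    @property
    def tau_m_ms(self) -> float:
        return self.C_pF / self.g_L_nS


@_njit(cache=False)
def _lif_step(I_pA, n, dt, C, gL, EL, Vth, Vreset, b, tauw, refr,
              block_on, h_block, h_dec, h_tau, h_vhalf, h_k,
              V0, w0, h0):  # pragma: no cover - exercised via wrapper
    V = np.empty(n)
    v, w, h = V0, w0, h0
    spikes = np.empty(n, dtype=np.int64)
    n_spk = 0
    refr_left = 0.0
    for i in range(n):
        if refr_left > 0.0:
            refr_left -= dt
            v = Vreset
        else:
            dv = (-gL * (v - EL) + I_pA - w) * dt / C
            v = v + dv
        w = w - w * dt / tauw
        if block_on:
            h_inf = 1.0 / (1.0 + math.exp((v - h_vhalf) / h_k))
            h = h + (h_inf - h) * dt / h_tau
        # 1e-9 mV crossing tolerance: the discrete solution approaches an
        # asymptote and float rounding would otherwise stall just below it
        if v >= Vth - 1e-9 and refr_left <= 0.0 and (not block_on or h >= h_block):
            spikes[n_spk] = i
            n_spk += 1
            v = Vreset
            w = w + b
            if block_on:
                h = h - h_dec
            refr_left = refr
        V[i] = v
    return V, spikes[:n_spk], w, h


def _paint_spikes(V: np.ndarray, spike_idx: np.ndarray, dt_ms: float,
                  p: NeuronParams) -> None:
    """Overlay a stereotyped action-potential waveform at each spike."""
    n_rise = max(1, int(round(p.spike_rise_ms / dt_ms)))
    n_fall = max(1, int(round(p.spike_fall_ms / dt_ms)))
    up = np.linspace(p.V_th_mV, p.spike_peak_mV, n_rise + 1)[1:]
    down = np.linspace(p.spike_peak_mV, p.V_reset_mV, n_fall + 1)[1:]
    shape = np.concatenate([up, down])
    for i in spike_idx:
        seg = shape[: V.size - i]
        V[i:i + seg.size] = seg


def simulate_fi_sweeps(params: Optional[NeuronParams] = None,
                       protocol: Optional[StepProtocol] = None,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE,
                       dt_ms: float = 0.01,
                       seed: Optional[int] = None,
                       metadata: Optional[dict] = None,
                       ) -> Tuple[Experiment, SyntheticTruth]:
    """Integrate the LIF model over a current-step protocol.

    One current-clamp voltage sweep per step (baseline, 1 s pulse, tail),
    integrated with a fixed-step explicit scheme at ``dt_ms`` (default
    0.01 ms, ten times the output digitization) and decimated to
    ``sampling_rate``.  Adaptation and gate state carry over between
    steps with analytic recovery during the inter-step interval.
    """
    p = params or NeuronParams()
    proto = protocol or StepProtocol(-100.0, 490.0, 10.0)
    if dt_ms > min(p.tau_m_ms, p.tau_w_ms, p.block_tau_ms) / 10.0:
        raise ValidationError(
            f"dt={dt_ms} ms too large for stable fixed-step integration "
            f"(membrane tau {p.tau_m_ms:g} ms)")
    stride = int(round(1.0 / (sampling_rate * dt_ms * 1e-3)))
    if stride < 1 or abs(stride - 1.0 / (sampling_rate * dt_ms * 1e-3)) > 1e-9:
        raise ValidationError("dt must divide the output sample interval")

    tail_s = 0.2
    n_base = int(round(proto.step_onset_s / (dt_ms * 1e-3)))
    n_step = int(round(proto.step_duration_s / (dt_ms * 1e-3)))
    n_tail = int(round(tail_s / (dt_ms * 1e-3)))

    sweeps = []
    spike_times: Dict[float, np.ndarray] = {}
    v, w, h = p.E_L_mV, 0.0, 1.0
    for I in proto.currents():
        V = np.empty(n_base + n_step + n_tail)
        idx_all = []
        off = 0
        for n_seg, I_seg in ((n_base, 0.0), (n_step, float(I)), (n_tail, 0.0)):
            Vseg, sidx, w, h = _lif_step(
                I_seg, n_seg, dt_ms, p.C_pF, p.g_L_nS, p.E_L_mV, p.V_th_mV,
                p.V_reset_mV, p.b_pA, p.tau_w_ms, p.refractory_ms,
                p.block_enabled, p.h_block, p.block_spike_decrement,
                p.block_tau_ms, p.block_vhalf_mV, p.block_slope_mV,
                v, w, h)
            v = Vseg[-1]
            V[off:off + n_seg] = Vseg
            idx_all.append(sidx + off)
            off += n_seg
        idx = np.concatenate(idx_all)
        _paint_spikes(V, idx, dt_ms, p)
        out = V[::stride].copy()
        step_spike_t = idx * dt_ms * 1e-3  # s from sweep start
        spike_times[float(I)] = step_spike_t
        md = {"step_current_pA": float(I), "synthetic": True}
        if metadata:
            md.update(metadata)
        sweeps.append(Sweep(samples=out, sampling_rate=sampling_rate,
                            channel_kind="current_clamp_voltage",
                            protocol=proto, metadata=md))
        # inter-step recovery at rest (analytic)
        T = proto.inter_step_s
        w *= math.exp(-T * 1e3 / p.tau_w_ms)
        h = 1.0 + (h - 1.0) * math.exp(-T * 1e3 / p.block_tau_ms)
        v = p.E_L_mV

    truth = SyntheticTruth(
        rng_seed=seed, spike_parameters=p, spike_times_per_step=spike_times,
        rheobase_pA=p.rheobase_closed_form_pA,
        extras={"step_onset_s": proto.step_onset_s,
                "step_duration_s": proto.step_duration_s})
    exp = Experiment(sweeps=sweeps, ground_truth=truth)
    return exp, truth


# ---------------------------------------------------------------------------
# evoked field-potential study

def boltzmann(x, top, v50, k):
    """Boltzmann sigmoid with bottom pinned at zero."""
    x = np.asarray(x, dtype=float)
    return top / (1.0 + np.exp((v50 - x) / k))


@dataclass
class FieldGroupTruth:
    """Generative parameters for one genotype group."""

    ppi_top: float = 110.0
    ppi_v50_ms: float = 41.3
    ppi_k_ms: float = 5.0
    es_top_mV: float = 8.0          # EPSP-spike coupling: spike vs slope
    es_v50_Vps: float = 2.4
    es_k_Vps: float = 0.25
    io_max_slope_Vps: float = 3.0   # saturating fEPSP slope vs intensity
    io_half_uA: float = 150.0
    spike_floor_mV: float = 0.2     # below this the population spike is absent


#: Paired-pulse interpulse intervals (ms) of the reference protocol.
DEFAULT_IPIS_MS = (1.0, 15.0, 20.0, 30.0, 35.0, 40.0, 45.0, 50.0,
                   60.0, 80.0, 100.0)
#: Input-output stimulation intensities (uA) of the reference protocol.
DEFAULT_INTENSITIES_UA = (30., 50., 100., 150., 175., 200., 225., 250., 275.,
                          300., 350., 400., 450., 500., 550., 600., 650.,
                          700., 750., 800.)


@dataclass
class FieldStudy:
    """Tables produced by :func:`simulate_field_experiment`."""

    io: pd.DataFrame        # subject, group, intensity_uA, slope, spike
    ppi: pd.DataFrame       # subject, group, ipi_ms, ppi_percent
    truth: SyntheticTruth


def simulate_field_experiment(
        n_subjects_per_group: Dict[str, int] = None,
        group_truth: Dict[str, FieldGroupTruth] = None,
        intensities_uA: Sequence[float] = DEFAULT_INTENSITIES_UA,
        ipis_ms: Sequence[float] = DEFAULT_IPIS_MS,
        between_subject_v50_sd_ms: float = 4.0,
        noise_cv: float = 0.05,
        seed: Optional[int] = None) -> FieldStudy:
    """Simulate a two-group in vivo field-potential study.

    Per subject: fEPSP slope saturates with stimulation intensity, the
    population spike follows a Boltzmann of the slope, and paired-pulse
    inhibition (second spike as % of the first) follows a Boltzmann of
    the interpulse interval whose v50 is jittered per subject
    (``between_subject_v50_sd_ms``).  Noise is multiplicative Gaussian
    with coefficient of variation ``noise_cv``.  Default group sizes and
    the KO v50 shift match the reference study design (17 vs 16 animals,
    +4.5 ms).
    """
    if n_subjects_per_group is None:
        n_subjects_per_group = {"WT": 17, "KO": 16}
    if group_truth is None:
        group_truth = {"WT": FieldGroupTruth(),
                       "KO": FieldGroupTruth(ppi_v50_ms=45.8)}
    intensities = np.asarray(intensities_uA, dtype=float)
    ipis = np.asarray(ipis_ms, dtype=float)
    if intensities.size == 0 or ipis.size == 0:
        raise ValidationError("intensity and IPI grids must be non-empty")
    missing = set(n_subjects_per_group) - set(group_truth)
    if missing:
        raise ValidationError(f"no ground truth specified for groups {missing}")

    root = np.random.SeedSequence(seed)
    io_rows, ppi_rows = [], []
    subject_truth = {}
    for gi, (group, n_subj) in enumerate(sorted(n_subjects_per_group.items())):
        gt = group_truth[group]
        for si in range(n_subj):
            rng = np.random.default_rng(root.spawn(1)[0])
            sid = f"{group}_{si:02d}"
            v50_s = gt.ppi_v50_ms + (
                rng.normal(0.0, between_subject_v50_sd_ms)
                if between_subject_v50_sd_ms > 0 else 0.0)
            subject_truth[sid] = {"group": group, "ppi_v50_ms": v50_s,
                                  "ppi_top": gt.ppi_top, "ppi_k_ms": gt.ppi_k_ms}
            slopes = gt.io_max_slope_Vps * intensities / (intensities + gt.io_half_uA)
            spikes = boltzmann(slopes, gt.es_top_mV, gt.es_v50_Vps, gt.es_k_Vps)
            spikes = np.where(spikes < gt.spike_floor_mV, 0.0, spikes)
            ppi = boltzmann(ipis, gt.ppi_top, v50_s, gt.ppi_k_ms)
            if noise_cv > 0:
                slopes = slopes * (1 + rng.normal(0, noise_cv, slopes.size))
                spikes = np.where(
                    spikes > 0,
                    np.maximum(spikes * (1 + rng.normal(0, noise_cv, spikes.size)), 0),
                    0.0)
                ppi = np.maximum(ppi * (1 + rng.normal(0, noise_cv, ppi.size)), 0.0)
            for I, sl, sp in zip(intensities, slopes, spikes):
                io_rows.append((sid, group, I, sl, sp))
            for ipi, pct in zip(ipis, ppi):
                ppi_rows.append((sid, group, ipi, pct))

    io = pd.DataFrame(io_rows, columns=["subject", "group", "intensity_uA",
                                        "fepsp_slope_Vps", "pop_spike_mV"])
    ppi = pd.DataFrame(ppi_rows, columns=["subject", "group", "ipi_ms",
                                          "ppi_percent"])
    truth = SyntheticTruth(
        rng_seed=seed,
        ground_truth_boltzmann={g: {"top": t.ppi_top, "v50_ms": t.ppi_v50_ms,
                                    "k_ms": t.ppi_k_ms}
                                for g, t in group_truth.items()},
        group_effects={"subjects": subject_truth},
        extras={"noise_cv": noise_cv,
                "between_subject_v50_sd_ms": between_subject_v50_sd_ms})
    return FieldStudy(io=io, ppi=ppi, truth=truth)


def synthesize_evoked_sweep(fepsp_slope_Vps: float,
                            pop_spike_mV: float = 0.0,
                            second_slope_Vps: Optional[float] = None,
                            second_spike_mV: Optional[float] = None,
                            ipi_ms: float = 40.0,
                            stim_time_s: float = 0.05,
                            tau_ms: float = 2.0,
                            fepsp_latency_ms: float = 2.0,
                            spike_latency_ms: float = 3.5,
                            spike_sigma_ms: float = 0.6,
                            duration_s: float = 0.25,
                            noise_sd_mV: float = 0.0,
                            sampling_rate: float = DEFAULT_SAMPLING_RATE,
                            seed: Optional[int] = None) -> Sweep:
    """Render an evoked field sweep from slope/spike ground truth.

    The fEPSP is an alpha function ``A (t/tau) exp(1 - t/tau)`` whose
    initial (maximal) rising slope ``A e / tau`` equals the requested
    slope; the population spike is a negative Gaussian superimposed near
    the fEPSP peak; a brief biphasic stimulus artifact marks each
    stimulus.  Pass the ``second_*`` values to render a paired-pulse
    sweep with the second stimulus ``ipi_ms`` later.
    """
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    trace = np.zeros(n)

    def add_response(t0, slope, spike):
        tau = tau_ms * 1e-3
        A = slope * tau / math.e  # V units
        onset = t0 + fepsp_latency_ms * 1e-3  # synaptic + conduction delay
        rel = t - onset
        m = rel > 0
        trace[m] += 1e3 * A * (rel[m] / tau) * np.exp(1 - rel[m] / tau)  # mV
        if spike > 0:
            ts = onset + spike_latency_ms * 1e-3
            sig = spike_sigma_ms * 1e-3
            trace[:] -= spike * np.exp(-0.5 * ((t - ts) / sig) ** 2)
        # biphasic stimulus artifact, 0.4 ms
        art = (t >= t0) & (t < t0 + 4e-4)
        trace[art] += np.where(t[art] < t0 + 2e-4, 8.0, -8.0)

    add_response(stim_time_s, fepsp_slope_Vps, pop_spike_mV)
    stims = [stim_time_s]
    if second_slope_Vps is not None or second_spike_mV is not None:
        t2 = stim_time_s + ipi_ms * 1e-3
        add_response(t2, second_slope_Vps
                     if second_slope_Vps is not None else fepsp_slope_Vps,
                     second_spike_mV or 0.0)
        stims.append(t2)
    if noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        trace += rng.normal(0, noise_sd_mV, n)
    return Sweep(samples=trace, sampling_rate=sampling_rate,
                 channel_kind="field_potential",
                 metadata={"stim_times_s": stims, "synthetic": True})


def simulate_ltp_timecourse(baseline_min: float = 10.0,
                            post_min: float = 60.0,
                            sample_interval_s: float = 30.0,
                            early_percent: float = 150.0,
                            late_percent: float = 120.0,
                            decay_tau_min: float = 25.0,
                            noise_cv: float = 0.03,
                            seed: Optional[int] = None) -> pd.DataFrame:
    """fEPSP-slope time series around an LTP induction at t = 0.

    Potentiation decays exponentially from ``early_percent`` toward
    ``late_percent`` of baseline with time constant ``decay_tau_min``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(-baseline_min * 60, post_min * 60 + 1e-9,
                  sample_interval_s) / 60.0  # minutes
    level = np.where(
        t < 0, 100.0,
        late_percent + (early_percent - late_percent) * np.exp(-t / decay_tau_min))
    if noise_cv > 0:
        level = level * (1 + rng.normal(0, noise_cv, level.size))
    return pd.DataFrame({"time_min": t, "slope_percent": level})


# ---------------------------------------------------------------------------
# two-group calibration samples

def simulate_two_group_samples(n1: int, n2: int, dist: str = "normal",
                               mean: float = 0.0, sd: float = 1.0,
                               effect: float = 0.0,
                               lognormal_sigma: float = 1.0,
                               seed: Optional[int] = None,
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Draw two independent samples; group 2 is shifted by ``effect``."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    if dist == "normal":
        a = mean + (sd * rng.standard_normal(n1) if sd > 0 else np.zeros(n1))
        b = mean + effect + (sd * rng.standard_normal(n2) if sd > 0 else np.zeros(n2))
    elif dist == "lognormal":
        a = mean + rng.lognormal(0.0, lognormal_sigma, n1)
        b = mean + effect + rng.lognormal(0.0, lognormal_sigma, n2)
    else:
        raise ValidationError(f"unknown dist {dist!r}")
    return a, b
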