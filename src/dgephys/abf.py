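"""Optional read-only Axon Binary Format adapter.

Isolated plugin: nothing in the core imports this module, and it only
works when the third-party ``pyabf`` reader is installed.  Each ABF
sweep becomes one :class:`~dgephys.model.Sweep` with channel units used
to guess the channel kind.
"""

from __future__ import annotations

from .model import Experiment, Sweep


def read_abf(path: str, channel: int = 0) -> Experiment:
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading ABF files requires the optional 'pyabf' package") from exc
    abf = pyabf.ABF(path)
    units = abf.adcUnits[channel].lower()
    kind = "voltage_clamp_current" if "a" in units else "current_clamp_voltage"
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i, channel=channel)
        sweeps.append(Sweep(samples=abf.sweepY.astype(float),
                            sampling_rate=float(abf.dataRate),
                            channel_kind=kind,
                            metadata={"abf_sweep": i, "source": path}))
    return Experiment(sweeps=sweeps)
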