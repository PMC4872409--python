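"""Startle amplitude handling and %PPI.

%PPI = 100 * (1 - mean(prepulse+pulse) / mean(pulse-alone)), the standard
startle-chamber convention, computed from per-session trial means over the
analysis window (the primary, post-NMDAr-antagonist period by default).
Mean-of-amplitudes, not mean of per-trial ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import INJECTION_NMDAR, PREPULSE_PULSE, PULSE_ALONE, Session


@dataclass
class PPIResult:
    ppi_pct: float
    mean_startle_pulse: float
    mean_startle_prepulse: float
    n_pulse_trials: int
    n_prepulse_trials: int


def startle_amplitude(trace, fs: float, pulse_onset: float, window=(0.0, 0.100)) -> float:
    """Peak rectified accelerometer response in the post-pulse window.

    Serves synthetic raw traces; real startle chambers report amplitudes
    directly.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round((pulse_onset + window[0]) * fs))
    i1 = int(round((pulse_onset + window[1]) * fs))
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise ValueError("startle window leaves the trace")
    return float(np.max(np.abs(trace[i0:i1])))


def mean_startle(pulse_amps) -> float:
    """Arithmetic mean of pulse-alone startle amplitudes."""
    pulse_amps = np.asarray(pulse_amps, dtype=float)
    if pulse_amps.size == 0:
        raise ValueError("need at least one pulse-alone trial")
    return float(pulse_amps.mean())


def percent_ppi(pulse_amps, prepulse_amps) -> PPIResult:
    """%PPI from pulse-alone and prepulse+pulse amplitude samples."""
    pulse_amps = np.asarray(pulse_amps, dtype=float)
    prepulse_amps = np.asarray(prepulse_amps, dtype=float)
    if pulse_amps.size == 0 or prepulse_amps.size == 0:
        raise ValueError("need at least one trial of each kind")
    mp = float(pulse_amps.mean())
    mpp = float(prepulse_amps.mean())
    if mp <= 0:
        raise ValueError(f"mean pulse-alone amplitude must be positive, got {mp}")
    return PPIResult(
        ppi_pct=100.0 * (1.0 - mpp / mp),
        mean_startle_pulse=mp,
        mean_startle_prepulse=mpp,
        n_pulse_trials=int(pulse_amps.size),
        n_prepulse_trials=int(prepulse_amps.size),
    )


def session_ppi(session: Session, window: tuple[float, float] | None = None) -> PPIResult:
    """%PPI of one session over an analysis window (default: primary period)."""
    if window is None:
        t0 = session.injection_time(INJECTION_NMDAR)
        window = (t0, session.recording.duration)
    trials = session.trials_in_window(*window)
    pa = [t.startle_amp for t in trials if t.kind == PULSE_ALONE]
    pp = [t.startle_amp for t in trials if t.kind == PREPULSE_PULSE]
    return percent_ppi(pa, pp)
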