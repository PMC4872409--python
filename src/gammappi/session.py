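"""Core data types for one concurrent ECoG + startle-behaviour session.

A *session* is one animal placed in the startle chamber: a continuous
multi-channel cortical recording, a schedule of acoustic events and drug
injections, and the per-trial startle amplitudes reported by the chamber.
Times are in seconds with t=0 at recording start; event onsets are stimulus
onsets. Signal values are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Event kinds
PREPULSE = "prepulse"
PULSE = "pulse"
INJECTION_PRETREAT = "injection_pretreat"
INJECTION_NMDAR = "injection_nmdar"
EVENT_KINDS = frozenset({PREPULSE, PULSE, INJECTION_PRETREAT, INJECTION_NMDAR})

# Trial kinds
PULSE_ALONE = "pulse_alone"
PREPULSE_PULSE = "prepulse_pulse"
TRIAL_KINDS = frozenset({PULSE_ALONE, PREPULSE_PULSE})


class SessionValidationError(ValueError):
    """Raised when a session component violates its invariants."""


@dataclass
class Recording:
    """Continuous multi-channel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Channel labels, e.g. ``["left", "right"]``.
    start_time : float
        Seconds; t=0 at recording start.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        self.validate()

    def validate(self) -> None:
        if not self.fs > 0:
            raise SessionValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise SessionValidationError("samples must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise SessionValidationError(
                f"{len(self.channel_ids)} channel ids for {self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs


@dataclass
class Event:
    """A point event on the session timeline (stimulus onset or injection)."""

    onset: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SessionValidationError(f"unknown event kind {self.kind!r}")


@dataclass
class TrialRecord:
    """One startle trial as reported by the chamber accelerometer."""

    index: int
    kind: str
    pulse_onset: float
    startle_amp: float

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise SessionValidationError(f"unknown trial kind {self.kind!r}")
        if self.startle_amp < 0:
            raise SessionValidationError(
                f"trial {self.index}: startle amplitude {self.startle_amp} < 0"
            )


@dataclass
class SessionDesign:
    """Timeline and stimulus parameters of the behavioural protocol.

    Defaults follow a standard rodent PPI protocol: a 15-min baseline, a
    pretreatment injection, a 25-min gap, then the NMDAr-antagonist injection
    opening the primary period (60 min for an MK-801-like compound, 30 min
    for a ketamine-like one). The 100-ms prepulse lead is onset-to-onset.
    """

    baseline_dur: float = 900.0
    gap_after_pretreat: float = 1500.0
    primary_dur: float = 3600.0
    mean_iti: float = 15.0
    iti_jitter: float = 5.0  # ITI uniform on mean +/- jitter
    pulse_level: float = 115.0
    prepulse_level: float = 78.0
    background_level: float = 70.0
    pulse_dur: float = 0.040
    prepulse_dur: float = 0.020
    prepulse_lead: float = 0.100
    fs: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("baseline_dur", "gap_after_pretreat", "primary_dur", "mean_iti"):
            if getattr(self, name) <= 0:
                raise SessionValidationError(f"{name} must be > 0")
        if self.fs < 400:
            raise SessionValidationError("fs must be >= 400 Hz (analysis ceiling 200 Hz)")

    @property
    def pretreat_time(self) -> float:
        """Pretreatment (antipsychotic) injection time, s."""
        return self.baseline_dur

    @property
    def nmdar_time(self) -> float:
        """NMDAr-antagonist injection time, s."""
        return self.baseline_dur + self.gap_after_pretreat

    @property
    def total_dur(self) -> float:
        return self.baseline_dur + self.gap_after_pretreat + self.primary_dur


@dataclass
class Session:
    """One animal-session: recording + events + trials + metadata."""

    recording: Recording
    events: list[Event]
    trials: list[TrialRecord] = field(default_factory=list)
    subject_id: str = "s0"
    condition_id: str = "unknown"
    session_order: int = 0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        self.validate()

    def validate(self) -> None:
        dur = self.recording.duration
        for ev in self.events:
            if not (0.0 <= ev.onset <= dur):
                raise SessionValidationError(
                    f"event {ev.kind!r} at onset {ev.onset} s outside recording span "
                    f"[0, {dur:.3f}] s"
                )
        n_pre = sum(e.kind == INJECTION_PRETREAT for e in self.events)
        n_nmdar = sum(e.kind == INJECTION_NMDAR for e in self.events)
        if n_pre != 1:
            raise SessionValidationError(
                f"session must contain exactly one pretreatment injection, found {n_pre}"
            )
        if n_nmdar > 1:
            raise SessionValidationError(
                f"session may contain at most one NMDAr injection, found {n_nmdar}"
            )
        pulse_onsets = {round(e.onset, 6) for e in self.events if e.kind == PULSE}
        for tr in self.trials:
            if pulse_onsets and round(tr.pulse_onset, 6) not in pulse_onsets:
                raise SessionValidationError(
                    f"trial {tr.index} pulse onset {tr.pulse_onset} has no pulse event"
                )

    def events_of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def injection_time(self, kind: str = INJECTION_NMDAR) -> float:
        evs = self.events_of_kind(kind)
        if not evs:
            raise SessionValidationError(f"session has no {kind!r} event")
        return evs[0].onset

    def prepulse_onsets(self, after: float | None = None) -> np.ndarray:
        """Prepulse onsets, optionally restricted to ``onset >= after``."""
        on = np.array([e.onset for e in self.events_of_kind(PREPULSE)])
        if after is not None:
            on = on[on >= after]
        return on

    def trials_in_window(self, t0: float, t1: float) -> list[TrialRecord]:
        return [tr for tr in self.trials if t0 <= tr.pulse_onset < t1]

    def copy(self) -> "Session":
        return replace(
            self,
            recording=replace(self.recording, samples=self.recording.samples.copy()),
            events=[replace(e, params=dict(e.params)) for e in self.events],
            trials=[replace(t) for t in self.trials],
        )


def average_channels(per_channel_values) -> np.ndarray | float:
    """Average a *derived* measure (band power, ERSP map ...) across channels.

    Channel combination happens after per-channel analysis, never on the raw
    signals. Values must live on identical grids; the result is the
    element-wise arithmetic mean and is permutation-invariant.
    """
    vals = [np.asarray(v, dtype=float) for v in per_channel_values]
    if not vals:
        raise ValueError("need at least one channel value")
    shape = vals[0].shape
    for v in vals[1:]:
        if v.shape != shape:
            raise ValueError(f"mismatched grids: {v.shape} vs {shape}")
    out = np.mean(vals, axis=0)
    return float(out) if out.ndim == 0 else out
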