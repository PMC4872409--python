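"""Synthetic ECoG + startle-behaviour session generator.

No raw recordings are deposited for this kind of rodent pharmaco-EEG study,
so every downstream stage is exercised on sessions drawn from a stated
generative model:

* background: pink (1/f) noise, independent per channel;
* ongoing gamma: 30-80 Hz band-limited filtered noise shared across channels,
  whose amplitude is multiplied by ``ongoing_gain`` after the NMDAr-antagonist
  injection with a single-exponential onset;
* evoked bursts: one Gabor atom per prepulse (centre frequency drawn per
  trial in 40-70 Hz, sigma_t = 25 ms, centred 50 ms after prepulse onset),
  scaled by ``evoked_gain``;
* optional 50 Hz mains sinusoid;
* startle amplitudes: log-normal pulse-alone draws whose prepulse+pulse
  counterparts are shrunk by the true %PPI.

Component magnitudes are chosen so the analysis pipeline can recover the
generator parameters (the ongoing-gamma process dominates the in-band
background by ~30x in power; inflated relative to physiology, and stated as
such in the package docs).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .session import (
    INJECTION_NMDAR,
    INJECTION_PRETREAT,
    PREPULSE,
    PREPULSE_PULSE,
    PULSE,
    PULSE_ALONE,
    Event,
    Recording,
    Session,
    SessionDesign,
    SessionValidationError,
    TrialRecord,
)

GAMMA_SIGMA = 55.0  # baseline ongoing-gamma process amplitude, uV RMS
BURST_AMP = 210.0  # Gabor atom peak amplitude at evoked_gain=1, uV
BURST_SIGMA_T = 0.025  # s
BURST_DELAY = 0.050  # s after prepulse onset
BURST_F_RANGE = (40.0, 70.0)  # Hz, per-trial centre frequency
PINK_EXPONENT = 1.0  # power ~ 1/f**exponent


@dataclass
class EffectSpec:
    """Generator parameters for one pharmacological condition."""

    ongoing_gain: float = 1.0  # multiplies ongoing-gamma amplitude post-injection
    rise_tau: float = 30.0  # s, exponential onset of the ongoing effect
    evoked_gain: float = 1.0  # multiplies prepulse-locked burst amplitude
    startle_mean: float = 100.0  # median pulse-alone startle, arb. units
    ppi_true: float = 60.0  # true %PPI (may be negative)
    noise_floor: float = 10.0  # pink-noise amplitude at 1 Hz, uV
    line_amp: float = 0.0  # 50 Hz mains amplitude, uV

    def __post_init__(self) -> None:
        if self.ongoing_gain < 0 or self.evoked_gain < 0:
            raise ValueError("gains must be >= 0")
        if self.startle_mean <= 0:
            raise ValueError("startle_mean must be > 0")
        if self.ppi_true > 100:
            raise ValueError("ppi_true cannot exceed 100")


@dataclass
class CohortSpec:
    """A complete within-subject cohort: every subject gets every condition."""

    conditions: dict[str, EffectSpec]
    n_subjects: int = 6
    startle_scale_sd: float = 0.4  # log-SD of per-subject startle scaling
    gamma_scale_sd: float = 0.2  # log-SD of per-subject signal-amplitude scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.conditions:
            raise ValueError("need at least one condition")


def _child_seed(*keys) -> int:
    """Stable child seed from (master seed, subject, condition, component)."""
    ints = [k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


def generate_schedule(
    design: SessionDesign, seed: int
) -> tuple[list[Event], list[tuple[int, str, float]]]:
    """Draw the pseudorandom trial schedule for one session.

    Returns the ordered event list (stimuli + the two injections) and the
    trial skeleton ``(index, kind, pulse_onset)``. Half the trials in every
    block of four are pulse-alone; ITIs are uniform on mean +/- jitter
    (onset-to-onset); prepulses lead their pulse by ``design.prepulse_lead``.
    """
    rng = np.random.default_rng(seed)
    kinds: list[str] = []
    onsets: list[float] = []
    t = 2.0 + design.prepulse_lead  # leave room for the epoch window head
    lo, hi = design.mean_iti - design.iti_jitter, design.mean_iti + design.iti_jitter
    while t < design.total_dur - 2.0:
        onsets.append(t)
        t += rng.uniform(lo, hi)
    n = len(onsets)
    for start in range(0, n, 4):
        block = [PULSE_ALONE, PULSE_ALONE, PREPULSE_PULSE, PREPULSE_PULSE]
        block = list(rng.permutation(block))
        kinds.extend(block[: n - start])
    n_primary = sum(design.nmdar_time <= on < design.total_dur for on in onsets)
    if n_primary < 2:
        raise SessionValidationError(
            f"primary period of {design.primary_dur} s holds only {n_primary} trial(s)"
        )

    events = [
        Event(design.pretreat_time, INJECTION_PRETREAT),
        Event(design.nmdar_time, INJECTION_NMDAR),
    ]
    trials: list[tuple[int, str, float]] = []
    for i, (kind, on) in enumerate(zip(kinds, onsets)):
        if kind == PREPULSE_PULSE:
            events.append(
                Event(
                    on - design.prepulse_lead,
                    PREPULSE,
                    {"level_db": design.prepulse_level, "duration_ms": design.prepulse_dur * 1e3},
                )
            )
        events.append(
            Event(on, PULSE, {"level_db": design.pulse_level, "duration_ms": design.pulse_dur * 1e3})
        )
        trials.append((i, kind, on))
    events.sort(key=lambda e: e.onset)
    return events, trials


def _pink_noise(n: int, fs: float, amp_1hz: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD amp_1hz**2 / f**PINK_EXPONENT (uV^2/Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f = np.maximum(f, 1.0)  # flatten below 1 Hz; keeps variance finite
    target_psd = amp_1hz**2 / f**PINK_EXPONENT
    # unit white noise has one-sided PSD 2/fs
    spec *= np.sqrt(target_psd * fs / 2.0)
    spec[0] = 0.0
    return np.fft.irfft(spec, n=n)


def _gamma_process(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 30-80 Hz band-limited noise (the ongoing gamma generator)."""
    sos = sps.butter(4, [30.0, 80.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_signal(
    design: SessionDesign,
    effect: EffectSpec,
    schedule: list[Event],
    fs: float | None = None,
    seed: int = 0,
    n_channels: int = 2,
) -> Recording:
    """Synthesize the multi-channel ECoG for one session.

    Oscillatory components (ongoing gamma, evoked bursts, mains) are shared
    across channels; the pink-noise background is drawn independently per
    channel, mimicking bilateral electrodes over one generator.
    """
    fs = design.fs if fs is None else fs
    if fs < 400:
        raise SessionValidationError("fs must be >= 400 Hz (analysis ceiling 200 Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(design.total_dur * fs))
    t = np.arange(n) / fs

    gamma = GAMMA_SIGMA * _gamma_process(n, fs, rng)
    nmdar = [e for e in schedule if e.kind == INJECTION_NMDAR]
    if nmdar:
        t0 = nmdar[0].onset
        env = np.ones(n)
        post = t >= t0
        env[post] = 1.0 + (effect.ongoing_gain - 1.0) * (
            1.0 - np.exp(-(t[post] - t0) / effect.rise_tau)
        )
        gamma = gamma * env

    shared = gamma
    if effect.line_amp > 0:
        shared = shared + effect.line_amp * np.sin(2 * np.pi * 50.0 * t)

    bursts = np.zeros(n)
    half = int(round(4 * BURST_SIGMA_T * fs))
    for ev in schedule:
        if ev.kind != PREPULSE:
            continue
        f_c = rng.uniform(*BURST_F_RANGE)
        phase = rng.uniform(0, 2 * np.pi)
        c = ev.onset + BURST_DELAY
        ic = int(round(c * fs))
        sl = slice(max(ic - half, 0), min(ic + half + 1, n))
        tt = t[sl] - c
        bursts[sl] += (
            BURST_AMP
            * effect.evoked_gain
            * np.cos(2 * np.pi * f_c * tt + phase)
            * np.exp(-(tt**2) / (2 * BURST_SIGMA_T**2))
        )
    shared = shared + bursts

    chans = [
        shared + _pink_noise(n, fs, effect.noise_floor, rng) for _ in range(n_channels)
    ]
    ids = ["left", "right"][:n_channels] + [f"ch{i}" for i in range(2, n_channels)]
    return Recording(samples=np.vstack(chans), fs=fs, channel_ids=ids)


def generate_behavior(
    schedule: list[tuple[int, str, float]],
    effect: EffectSpec,
    subject_scale: float = 1.0,
    seed: int = 0,
    sigma_log: float = 0.3,
) -> list[TrialRecord]:
    """Draw per-trial startle amplitudes.

    Pulse-alone amplitudes are log-normal with median
    ``startle_mean * subject_scale``; prepulse+pulse amplitudes are the same
    draw shrunk by ``1 - ppi_true/100`` (negative %PPI yields facilitation).
    """
    kinds = {k for _, k, _ in schedule}
    if kinds != {PULSE_ALONE, PREPULSE_PULSE}:
        raise ValueError("schedule must contain both trial kinds")
    rng = np.random.default_rng(seed)
    median = effect.startle_mean * subject_scale
    out = []
    for idx, kind, onset in schedule:
        amp = median * np.exp(sigma_log * rng.standard_normal())
        if kind == PREPULSE_PULSE:
            amp *= 1.0 - effect.ppi_true / 100.0
        out.append(TrialRecord(index=idx, kind=kind, pulse_onset=onset, startle_amp=amp))
    return out


def generate_session(
    design: SessionDesign,
    effect: EffectSpec,
    seed: int,
    subject_id: str = "s0",
    condition_id: str = "custom",
    session_order: int = 0,
    subject_startle_scale: float = 1.0,
    subject_gamma_scale: float = 1.0,
) -> Session:
    """One full synthetic session (signal + events + behaviour)."""
    events, trial_sched = generate_schedule(design, _child_seed(seed, "schedule"))
    rec = generate_signal(design, effect, events, seed=_child_seed(seed, "signal"))
    if subject_gamma_scale != 1.0:
        rec = replace(rec, samples=rec.samples * subject_gamma_scale)
    trials = generate_behavior(
        trial_sched, effect, subject_startle_scale, seed=_child_seed(seed, "behavior")
    )
    return Session(
        recording=rec,
        events=events,
        trials=trials,
        subject_id=subject_id,
        condition_id=condition_id,
        session_order=session_order,
    )


def generate_cohort(cohort: CohortSpec, design: SessionDesign) -> list[Session]:
    """Complete within-subject cohort: n_subjects x n_conditions sessions.

    Per-subject multiplicative random effects (startle scale, signal
    amplitude scale) apply identically to all of that subject's sessions;
    condition order is randomised per subject and recorded in
    ``session_order``. Child seeds depend only on (master seed, subject,
    condition), so adding a condition never perturbs the others.
    """
    sessions = []
    for si in range(cohort.n_subjects):
        subj = f"s{si:02d}"
        srng = np.random.default_rng(_child_seed(cohort.seed, subj, "subject-effects"))
        startle_scale = float(np.exp(cohort.startle_scale_sd * srng.standard_normal()))
        gamma_scale = float(np.exp(cohort.gamma_scale_sd * srng.standard_normal()))
        orng = np.random.default_rng(_child_seed(cohort.seed, subj, "order"))
        names = sorted(cohort.conditions)
        order = [str(c) for c in orng.permutation(names)]
        for pos, cond in enumerate(order):
            sessions.append(
                generate_session(
                    design,
                    cohort.conditions[cond],
                    seed=_child_seed(cohort.seed, subj, cond),
                    subject_id=subj,
                    condition_id=cond,
                    session_order=pos,
                    subject_startle_scale=startle_scale,
                    subject_gamma_scale=gamma_scale,
                )
            )
    return sessions


def effect_presets() -> dict[str, EffectSpec]:
    """Named per-condition presets reproducing the ordinal pharmacology.

    No measured effect magnitudes are available for this paradigm, so the
    numbers below are chosen once for ordinal fidelity: the NMDAr antagonist
    elevates ongoing gamma, suppresses prepulse-evoked gamma and abolishes
    most PPI; clozapine alone rescues evoked gamma and (partially) PPI; the
    clinical antipsychotics and LY379268 suppress the ongoing-gamma rise;
    the glycine-site compounds (NFPS, d-serine) change nothing; haloperidol
    also elevates raw startle.

    The evoked readout is a burst-to-background ratio, so a condition that
    suppresses ongoing gamma would mechanically score higher for the same
    absolute burst. The reported pharmacology is that such suppression does
    NOT restore measured evoked power (LY379268 normalises ongoing gamma
    without any evoked recovery), so the no-rescue presets carry the background
    correction: their burst gain is 0.3 * sqrt(1.10 / 3.24) ~= 0.18, keeping
    their measured evoked level at the antagonist condition's.
    """
    base = dict(rise_tau=30.0, noise_floor=10.0, line_amp=0.0)
    return {
        "vehicle_vehicle": EffectSpec(1.0, evoked_gain=1.0, startle_mean=100, ppi_true=60, **base),
        "vehicle_nmdar": EffectSpec(1.8, evoked_gain=0.3, startle_mean=100, ppi_true=10, **base),
        "clozapine_nmdar": EffectSpec(1.05, evoked_gain=0.9, startle_mean=100, ppi_true=35, **base),
        "haloperidol_nmdar": EffectSpec(1.05, evoked_gain=0.18, startle_mean=160, ppi_true=10, **base),
        "olanzapine_nmdar": EffectSpec(1.05, evoked_gain=0.18, startle_mean=100, ppi_true=10, **base),
        "ly379268_nmdar": EffectSpec(1.05, evoked_gain=0.18, startle_mean=100, ppi_true=10, **base),
        "nfps_nmdar": EffectSpec(1.8, evoked_gain=0.3, startle_mean=100, ppi_true=10, **base),
        "dserine_nmdar": EffectSpec(1.8, evoked_gain=0.3, startle_mean=100, ppi_true=10, **base),
    }


def scaled_design(primary_dur: float = 480.0, fs: float = 500.0) -> SessionDesign:
    """A desk-scale session layout preserving the protocol's proportions.

    Shrinks the 15/25/60-min timeline to 4/3/8 minutes and samples at 500 Hz
    so a full cohort runs in minutes; every analysis window scales through
    the event times, so pipeline behaviour is unchanged in kind.
    """
    return SessionDesign(
        baseline_dur=240.0, gap_after_pretreat=180.0, primary_dur=primary_dur, fs=fs
    )
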