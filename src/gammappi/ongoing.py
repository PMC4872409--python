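"""Ongoing (spontaneous) gamma-power time course.

The continuous signal is cut into 2-s epochs, each epoch gets a Welch
spectral estimate over 1-200 Hz, the 30-80 Hz band power (mean density over
band bins, uV^2/Hz) is averaged within 1-min blocks, and every block is
expressed as a percentage of the mean over the pre-injection baseline.

Welch settings inside each 2-s epoch: Hann window, 1-s segments, 50% overlap
(about 1 Hz resolution). "Band power" is the MEAN across band bins rather
than the integral; the percent normalisation makes the two conventions
equivalent downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import INJECTION_NMDAR, Session, average_channels

GAMMA_BAND = (30.0, 80.0)


@dataclass
class BandDefinition:
    lo: float = 30.0
    hi: float = 80.0

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")


@dataclass
class PowerSpectrum:
    """One-sided spectral density estimate (uV^2/Hz) on a 1-200 Hz grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")


@dataclass
class SpectralTimecourse:
    """Per-block gamma power, raw (uV^2/Hz) and as percent of baseline."""

    block_times: np.ndarray  # block start times, minutes from session start
    band_power_raw: np.ndarray
    band_power_pct: np.ndarray
    baseline_value: float
    block_counts: np.ndarray | None = None  # epochs per block


def segment_epochs(
    channel: np.ndarray, fs: float, epoch_len: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cut one channel into contiguous non-overlapping epochs.

    Returns ``(epochs, start_times)`` with shape (n_epochs, epoch_len*fs);
    a trailing partial epoch is discarded. A recording shorter than one
    epoch yields an empty result with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    spe = int(round(epoch_len * fs))
    n = channel.size // spe
    if n == 0:
        warnings.warn(f"recording shorter than one {epoch_len}-s epoch; no epochs")
        return np.empty((0, spe)), np.empty(0)
    epochs = channel[: n * spe].reshape(n, spe)
    times = np.arange(n) * epoch_len
    return epochs, times


def psd_welch(
    epochs: np.ndarray,
    fs: float,
    freq_range: tuple[float, float] | None = (1.0, 200.0),
    nperseg: float = 1.0,
) -> PowerSpectrum:
    """Welch spectral density of one epoch (or a stack of epochs).

    Hann window, ``nperseg``-second segments, 50% overlap, density scaling:
    integrating the returned density over frequency approximates the signal
    variance (Parseval). ``freq_range=None`` keeps the full 0-Nyquist grid;
    the default restricts to the 1-200 Hz analysis range.
    """
    epochs = np.asarray(epochs, dtype=float)
    if not np.all(np.isfinite(epochs)):
        raise ValueError("non-finite samples in epoch")
    nseg = int(round(nperseg * fs))
    nseg = min(nseg, epochs.shape[-1])
    freqs, pxx = sps.welch(
        epochs, fs=fs, window="hann", nperseg=nseg, noverlap=nseg // 2, detrend=False, axis=-1
    )
    if epochs.ndim > 1:
        pxx = pxx.mean(axis=tuple(range(epochs.ndim - 1)))
    if freq_range is not None:
        lo, hi = freq_range
        keep = (freqs >= lo) & (freqs <= hi)
        freqs, pxx = freqs[keep], pxx[keep]
    return PowerSpectrum(freqs=freqs, power=pxx)


def band_power(spectrum: PowerSpectrum, band: BandDefinition | tuple = GAMMA_BAND) -> float:
    """Mean spectral value over bins whose centre lies in [lo, hi] (inclusive)."""
    if not isinstance(band, BandDefinition):
        band = BandDefinition(*band)
    mask = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"no spectral bins inside [{band.lo}, {band.hi}] Hz")
    return float(spectrum.power[mask].mean())


def minute_blocks(
    epoch_values: np.ndarray,
    epoch_times: np.ndarray,
    block_len: float = 60.0,
    total_dur: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average per-epoch band powers within consecutive blocks.

    Returns ``(block_times, block_means, block_counts)``; block times are
    block starts in seconds. Blocks holding no epoch are NaN (missing), not
    zero; a partial trailing block keeps its reduced epoch count.
    """
    epoch_values = np.asarray(epoch_values, dtype=float)
    epoch_times = np.asarray(epoch_times, dtype=float)
    if epoch_values.size == 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    end = max(epoch_times.max() + 1e-9, total_dur or 0.0)
    n_blocks = int(np.ceil(end / block_len))
    idx = np.minimum((epoch_times // block_len).astype(int), n_blocks - 1)
    means = np.full(n_blocks, np.nan)
    counts = np.zeros(n_blocks, dtype=int)
    for b in range(n_blocks):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = epoch_values[sel].mean()
    return np.arange(n_blocks) * block_len, means, counts


def baseline_normalize(
    block_times: np.ndarray,
    block_means: np.ndarray,
    baseline_window: tuple[float, float],
    block_counts: np.ndarray | None = None,
) -> SpectralTimecourse:
    """Express every block as a percentage of the pre-injection baseline mean."""
    block_times = np.asarray(block_times, dtype=float)
    block_means = np.asarray(block_means, dtype=float)
    t0, t1 = baseline_window
    sel = (block_times >= t0) & (block_times < t1) & np.isfinite(block_means)
    if not sel.any():
        raise ValueError(f"no blocks inside baseline window [{t0}, {t1}] s")
    baseline = float(block_means[sel].mean())
    if baseline <= 0:
        raise ValueError(f"baseline power must be positive, got {baseline}")
    return SpectralTimecourse(
        block_times=block_times / 60.0,
        band_power_raw=block_means,
        band_power_pct=100.0 * block_means / baseline,
        baseline_value=baseline,
        block_counts=block_counts,
    )


def mean_post_injection(
    timecourse: SpectralTimecourse, injection_time: float, duration: float
) -> float:
    """Mean percent-of-baseline over [injection, injection+duration] (seconds)."""
    t = timecourse.block_times * 60.0
    sel = (t >= injection_time) & (t < injection_time + duration)
    sel &= np.isfinite(timecourse.band_power_pct)
    if not sel.any():
        raise ValueError("no blocks in the post-injection window")
    return float(timecourse.band_power_pct[sel].mean())


def session_timecourse(
    session: Session,
    band: BandDefinition | tuple = GAMMA_BAND,
    epoch_len: float = 2.0,
    block_len: float = 60.0,
    baseline_window: tuple[float, float] | None = None,
    notch_50hz: bool = False,
) -> SpectralTimecourse:
    """Full ongoing-power pipeline for one session.

    Per channel: 2-s epochs -> Welch -> band power -> 1-min blocks; block
    values are then averaged across channels and normalised to the
    pre-pretreatment baseline. The optional 50 Hz IIR notch (Q=30) is OFF by
    default (the modelled hardware removes mains noise at acquisition).
    """
    rec = session.recording
    if baseline_window is None:
        pre = session.events_of_kind("injection_pretreat")
        t1 = pre[0].onset if pre else rec.duration
        baseline_window = (0.0, t1)
    per_channel = []
    times = counts = None
    for ch in rec.samples:
        if notch_50hz:
            b, a = sps.iirnotch(50.0, Q=30.0, fs=rec.fs)
            ch = sps.filtfilt(b, a, ch)
        epochs, etimes = segment_epochs(ch, rec.fs, epoch_len)
        # vectorised: Welch every epoch in one call, band-average per epoch
        nseg = int(round(1.0 * rec.fs))
        freqs, pxx = sps.welch(
            epochs, fs=rec.fs, window="hann", nperseg=min(nseg, epochs.shape[-1]),
            noverlap=min(nseg, epochs.shape[-1]) // 2, detrend=False, axis=-1,
        )
        keep = (freqs >= 1.0) & (freqs <= 200.0)
        if not isinstance(band, BandDefinition):
            band_ = BandDefinition(*band)
        else:
            band_ = band
        bsel = (freqs >= band_.lo) & (freqs <= band_.hi) & keep
        epoch_bp = pxx[:, bsel].mean(axis=1)
        times, means, counts = minute_blocks(epoch_bp, etimes, block_len, rec.duration)
        per_channel.append(means)
    combined = average_channels(per_channel)
    return baseline_normalize(times, combined, baseline_window, counts)


def session_mean_post_injection(
    session: Session,
    duration: float | None = None,
    timecourse: SpectralTimecourse | None = None,
    **kwargs,
) -> float:
    """Mean ongoing gamma (% of baseline) over the primary period."""
    tc = timecourse if timecourse is not None else session_timecourse(session, **kwargs)
    t_inj = session.injection_time(INJECTION_NMDAR)
    if duration is None:
        duration = session.recording.duration - t_inj
    return mean_post_injection(tc, t_inj, duration)
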