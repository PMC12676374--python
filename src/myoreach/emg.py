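"""EMG envelope extraction.

The processing chain: 4th-order Butterworth band-pass (20-1000 Hz),
full-wave rectification, 4th-order Butterworth low-pass at 50 Hz
(amplitude envelope), block-average downsampling to 200 Hz, fixed-length
60-sample trial windows, and per-channel normalization to the 98th
percentile pooled across all trials.

All filters are applied zero-phase (forward-backward, ``sosfiltfilt``), so
the stated order is the design order and the effective attenuation is
doubled; trial alignment against simulated activations motivates the
zero-phase choice. Percentiles use linear interpolation between order
statistics (numpy's default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .arm import RawEMGRecording

__all__ = [
    "FilterSpec",
    "EMGEnvelope",
    "bandpass",
    "envelope",
    "block_downsample",
    "clip_align",
    "normalize_p98",
    "process_trials",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification."""

    kind: str = "bandpass"            # "bandpass" | "lowpass"
    order: int = 4
    band: tuple[float, float] = (20.0, 1000.0)  # Hz; lowpass uses band[1]

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if self.kind == "bandpass":
            lo, hi = self.band
            for edge, name in ((lo, "lower"), (hi, "upper")):
                if not 0.0 < edge < nyq:
                    raise ValueError(
                        f"{name} band edge {edge} Hz outside (0, {nyq}) Hz "
                        f"at fs = {fs} Hz"
                    )
            return _sig.butter(self.order, [lo, hi], btype="bandpass",
                               fs=fs, output="sos")
        if self.kind == "lowpass":
            cut = self.band[1]
            if not 0.0 < cut < nyq:
                raise ValueError(
                    f"cutoff {cut} Hz outside (0, {nyq}) Hz at fs = {fs} Hz"
                )
            return _sig.butter(self.order, cut, btype="lowpass",
                               fs=fs, output="sos")
        raise ValueError(f"unknown filter kind {self.kind!r}")


BANDPASS_DEFAULT = FilterSpec("bandpass", 4, (20.0, 1000.0))
LOWPASS_DEFAULT = FilterSpec("lowpass", 4, (0.0, 50.0))


@dataclass
class EMGEnvelope:
    """Trial-aligned, normalized muscle-activity envelopes.

    ``values`` has shape (n_trials, length, n_channels); after
    normalization the per-channel 98th percentile pooled over trials and
    samples equals 1, and the divisors are kept in ``norm_reference``.
    """

    rate: float                  # Hz
    length: int                  # samples per trial
    values: np.ndarray           # (n_trials, length, n_channels)
    channels: list[str]
    norm_reference: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def bandpass(signal: np.ndarray, fs: float,
             spec: FilterSpec = BANDPASS_DEFAULT) -> np.ndarray:
    """Zero-phase band-pass along axis 0; preserves length."""
    signal = np.asarray(signal, dtype=float)
    return _sig.sosfiltfilt(spec.sos(fs), signal, axis=0)


def envelope(signal: np.ndarray, fs: float,
             spec: FilterSpec = LOWPASS_DEFAULT) -> np.ndarray:
    """Full-wave rectification followed by a zero-phase 50 Hz low-pass."""
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    return _sig.sosfiltfilt(spec.sos(fs), np.abs(signal), axis=0)


def block_downsample(signal: np.ndarray, fs: float,
                     target_rate: float = 200.0) -> np.ndarray:
    """Downsample by averaging consecutive non-overlapping blocks.

    Requires an integer decimation factor (e.g. 30000/200 = 150); trailing
    samples short of a full block are dropped.
    """
    factor_f = fs / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs/target_rate = {fs}/{target_rate} is not an integer factor"
        )
    signal = np.asarray(signal, dtype=float)
    n_blocks = signal.shape[0] // factor
    trimmed = signal[: n_blocks * factor]
    shape = (n_blocks, factor) + trimmed.shape[1:]
    return trimmed.reshape(shape).mean(axis=1)


def clip_align(signal: np.ndarray, onset_index: int, length: int = 60) -> np.ndarray:
    """Extract exactly ``length`` samples starting at ``onset_index``."""
    n = signal.shape[0]
    if onset_index < 0 or onset_index + length > n:
        raise ValueError(
            f"window [{onset_index}, {onset_index + length}) exceeds "
            f"record of {n} samples"
        )
    return np.asarray(signal)[onset_index : onset_index + length]


def normalize_p98(envelopes: np.ndarray, channels: list[str] | None = None,
                  rate: float = 200.0) -> EMGEnvelope:
    """Normalize trial envelopes to the pooled per-channel 98th percentile.

    ``envelopes`` is (n_trials, length) for one channel or
    (n_trials, length, n_channels). The divisor pools all trials and
    samples per channel; an all-zero channel is rejected because its
    divisor would vanish.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim == 2:
        env = env[:, :, None]
    if env.ndim != 3 or env.shape[0] < 1:
        raise ValueError("envelopes must be (n_trials, length[, n_channels])")
    n_trials, length, n_ch = env.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    p98 = np.percentile(env.reshape(-1, n_ch), 98, axis=0)
    if np.any(p98 <= 0):
        bad = [channels[i] for i in np.nonzero(p98 <= 0)[0]]
        raise ValueError(f"channel(s) {bad} have non-positive 98th percentile")
    return EMGEnvelope(
        rate=rate, length=length, values=env / p98,
        channels=list(channels), norm_reference=p98,
    )


def process_trials(raw: RawEMGRecording, onsets: np.ndarray | None = None,
                   length: int = 60, target_rate: float = 200.0,
                   bp: FilterSpec = BANDPASS_DEFAULT,
                   lp: FilterSpec = LOWPASS_DEFAULT) -> EMGEnvelope:
    """Full chain: band-pass, rectify+low-pass, block-average, clip, normalize.

    ``onsets`` are raw-signal sample indices of the trial starts; the
    recording's own ``trial_onsets`` are used when omitted.
    """
    if onsets is None:
        onsets = raw.trial_onsets
    onsets = np.asarray(onsets, dtype=int)
    filtered = bandpass(raw.signal, raw.fs, bp)
    env = envelope(filtered, raw.fs, lp)
    down = block_downsample(env, raw.fs, target_rate)
    factor = int(round(raw.fs / target_rate))
    trials = np.stack(
        [clip_align(down, int(o) // factor, length) for o in onsets]
    )  # (n_trials, length, n_channels)
    return normalize_p98(trials, channels=raw.channels, rate=target_rate)
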