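"""Surface EMG processing: envelope extraction, MVC normalization, and
activation-timing metrics.

The processing chain is a fourth-order Butterworth high-pass at 50 Hz,
full-wave rectification, then a fourth-order Butterworth low-pass at 20 Hz.
Both filters are applied zero-phase (forward-backward), so envelope peak
times are unbiased — essential for the peak-activation-timing metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ValidationError
from .traces import TimeSeriesTrace

__all__ = ["EmgEnvelope", "process_emg", "normalize_emg", "peak_activation_timing"]


@dataclass
class EmgEnvelope:
    """A non-negative EMG envelope; ``mvc_peak`` records the normalization
    reference once :func:`normalize_emg` has been applied (None = raw units)."""

    trace: TimeSeriesTrace
    mvc_peak: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.trace.values

    @property
    def peak(self) -> float:
        return float(np.max(self.trace.values))


def _butter_sos(order: int, cutoff_hz: float, fs: float, btype: str):
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")


def process_emg(
    raw: TimeSeriesTrace,
    highpass_hz: float = 50.0,
    lowpass_hz: float = 20.0,
    order: int = 4,
) -> EmgEnvelope:
    """High-pass, rectify, low-pass; floor residual filter ringing at zero.

    Requires a sample rate comfortably above twice the high-pass cutoff
    (> 100 Hz for the 50 Hz default).
    """
    if raw.sample_rate <= 2 * highpass_hz:
        raise ValidationError(
            f"sample rate {raw.sample_rate} Hz too low for a {highpass_hz} Hz high-pass"
        )
    hp = _butter_sos(order, highpass_hz, raw.sample_rate, "highpass")
    lp = _butter_sos(order, lowpass_hz, raw.sample_rate, "lowpass")
    x = signal.sosfiltfilt(hp, raw.values)
    x = np.abs(x)
    x = signal.sosfiltfilt(lp, x)
    return EmgEnvelope(raw.with_values(np.maximum(x, 0.0)))


def normalize_emg(envelope: EmgEnvelope, mvc_envelope: EmgEnvelope) -> EmgEnvelope:
    """Normalize an envelope to the peak of an MVC envelope."""
    ref = mvc_envelope.peak
    if not (ref > 0):
        raise ValidationError("MVC envelope peak must be positive")
    out = envelope.trace.with_values(envelope.values / ref, units="MVC")
    return EmgEnvelope(out, mvc_peak=ref)


def peak_activation_timing(envelope_grid) -> float | None:
    """Timing of peak activation as percent of stance on the 101-point grid.

    Ties resolve to the earliest sample. A flat envelope has no defined
    peak and returns None (reported as missing downstream).
    """
    x = np.asarray(envelope_grid, dtype=float)
    if x.size != 101:
        raise ValidationError("expected a 101-point stance-grid envelope")
    if np.ptp(x) == 0.0:
        return None
    return float(np.argmax(x))
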