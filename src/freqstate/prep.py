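"""Preprocessing: zero-phase band-pass filtering, polyphase resampling, and
common-average re-referencing.

The band-pass is a 5th-order Butterworth applied forward-backward
(zero-phase), realized as second-order sections for numerical stability at
narrow low-frequency bands. Edge effects are handled by reflect padding of
three times the effective filter order before the forward-backward pass.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .core import BandDefinition, Recording

FILTER_ORDER = 5


def _butter_sos(band: BandDefinition, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    return signal.butter(
        FILTER_ORDER, [band.low / nyq, band.high / nyq], btype="bandpass", output="sos"
    )


def bandpass(recording: Recording, band: BandDefinition) -> Recording:
    """Zero-phase 5th-order Butterworth band-pass; tags the output band."""
    band.validate_for_rate(recording.rate)
    sos = _butter_sos(band, recording.rate)
    padlen = 3 * (2 * FILTER_ORDER + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"recording too short to filter ({recording.n_samples} samples, "
            f"need > {padlen})"
        )
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1, padtype="even",
                                  padlen=padlen)
    return recording.with_data(filtered, band=band.name)


def resample(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > recording.rate:
        raise ValueError("upsampling is not supported")
    if target_rate == recording.rate:
        return recording.with_data(recording.data.copy())
    frac = Fraction(target_rate / recording.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(recording.data, up, down, axis=1)
    return recording.with_data(data, rate=target_rate)


def average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous mean across channels at every sample."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.with_data(data)
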