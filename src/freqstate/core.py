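"""Core data containers shared across the pipeline.

A :class:`Recording` is a channels x samples potential matrix in microvolts
tagged with its sampling rate, electrode layout, subject and condition. An
:class:`ElectrodeLayout` carries channel names and 2-D positions projected
onto the unit disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CONDITIONS = ("wake", "LOC", "ROC")

#: Frequency bands used throughout the pipeline (Hz, inclusive edges).
DEFAULT_BANDS = {
    "broadband": (1.0, 45.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 45.0),
}

SUB_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Channel names plus 2-D scalp positions on the unit disk."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) < 2:
            raise ValueError("layout needs at least 2 channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("positions must lie within the unit disk")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high})")

    def validate_for_rate(self, rate: float) -> None:
        if self.high >= rate / 2.0:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist ({rate / 2} Hz)"
            )


def band_from_name(name: str, bands: Optional[dict] = None) -> BandDefinition:
    table = bands if bands is not None else DEFAULT_BANDS
    low, high = table[name]
    return BandDefinition(name, low, high)


@dataclass
class Recording:
    """Multichannel EEG segment: ``data`` is channels x samples in µV."""

    data: np.ndarray
    rate: float
    layout: ElectrodeLayout
    subject: str = ""
    condition: str = ""
    band: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data rows must match layout channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        out = replace(self, **changes)
        out.data = np.asarray(data, dtype=float)
        return out
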