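"""Multitaper spectral estimation and band-power summaries.

PSD is computed per sliding window with discrete prolate spheroidal (Slepian)
tapers, combined by eigenvalue weighting, averaged over windows, and
restricted to 1-45 Hz. Band powers average PSD bins with inclusive band
edges; wakefulness normalization is expressed in dB by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .core import BandDefinition, Recording

FMIN, FMAX = 1.0, 45.0


@dataclass
class SpectralSummary:
    freqs: np.ndarray          # (F,) Hz
    psd: np.ndarray            # (channels, F) µV²/Hz
    window_s: float
    step_s: float
    time_bandwidth: float
    n_tapers: int


def multitaper_psd(recording: Recording, window_s: float = 2.0,
                   step_s: float = 1.5, time_bandwidth: float = 3.0,
                   n_tapers: int = 5,
                   fmin: float = FMIN, fmax: float = FMAX) -> SpectralSummary:
    """Sliding-window multitaper PSD, eigenvalue-weighted over tapers and
    averaged over windows, restricted to [fmin, fmax]."""
    fs = recording.rate
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    if recording.n_samples < nwin:
        raise ValueError("recording shorter than one analysis window")
    tapers, ratios = dpss(nwin, time_bandwidth, Kmax=n_tapers,
                          return_ratios=True)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    keep = (freqs >= fmin) & (freqs <= fmax)
    n_windows = (recording.n_samples - nwin) // nstep + 1
    weights = ratios / ratios.sum()
    acc = np.zeros((recording.n_channels, keep.sum()))
    for w in range(n_windows):
        seg = recording.data[:, w * nstep:w * nstep + nwin]
        # (tapers, channels, freqs); dpss tapers are unit-energy so
        # |X|^2 / fs is a density in µV²/Hz
        spec = np.fft.rfft(tapers[:, None, :] * seg[None, :, :], axis=-1)
        power = (spec.real**2 + spec.imag**2) / fs
        # one-sided: double everything except DC and Nyquist
        power[..., 1:] *= 2.0
        if nwin % 2 == 0:
            power[..., -1] /= 2.0
        acc += np.tensordot(weights, power[..., keep], axes=(0, 0))
    psd = acc / n_windows
    return SpectralSummary(freqs=freqs[keep], psd=psd, window_s=window_s,
                           step_s=step_s, time_bandwidth=time_bandwidth,
                           n_tapers=n_tapers)


def band_power(summary: SpectralSummary, bands: list[BandDefinition],
               subject: str = "", condition: str = "") -> pd.DataFrame:
    """Tidy per-channel mean PSD within each band (inclusive edges).

    Returns columns: subject, condition, band, channel, power.
    """
    rows = []
    for band in bands:
        sel = (summary.freqs >= band.low) & (summary.freqs <= band.high)
        if not sel.any():
            raise ValueError(f"band {band.name} contains no frequency bins")
        vals = summary.psd[:, sel].mean(axis=1)
        for ch, v in enumerate(vals):
            rows.append((subject, condition, band.name, ch, float(v)))
    return pd.DataFrame(rows, columns=["subject", "condition", "band",
                                       "channel", "power"])


def band_power_integral(summary: SpectralSummary, band: BandDefinition) -> np.ndarray:
    """Band-integrated power per channel (µV²): sum of PSD bins x bin width."""
    sel = (summary.freqs >= band.low) & (summary.freqs <= band.high)
    df = 1.0 / summary.window_s
    return summary.psd[:, sel].sum(axis=1) * df


def normalize_to_baseline(table: pd.DataFrame, baseline_condition: str = "wake",
                          scale: str = "db") -> pd.DataFrame:
    """Normalize band powers to a baseline condition per subject x band x
    channel. ``scale='db'`` gives 10*log10(power / baseline); ``'ratio'``
    gives the linear ratio."""
    if scale not in ("db", "ratio"):
        raise ValueError("scale must be 'db' or 'ratio'")
    keys = ["subject", "band", "channel"]
    base = table[table["condition"] == baseline_condition]
    if base.empty:
        raise ValueError(f"no rows for baseline condition {baseline_condition!r}")
    base = base.set_index(keys)["power"]
    merged = table.set_index(keys)
    ref = base.reindex(merged.index)
    if ref.isna().any():
        raise ValueError("baseline rows missing for some subject/band/channel")
    if (ref <= 0).any():
        raise FloatingPointError("zero or negative baseline power")
    ratio = merged["power"] / ref
    out = merged.reset_index()
    out["power"] = (10.0 * np.log10(ratio.to_numpy()) if scale == "db"
                    else ratio.to_numpy())
    return out
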