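"""Welch power spectra, relative band-power contributions, and the
temporal variability of those contributions across epochs.

Band contributions express, per channel, the percentage of 0–40 Hz
power falling in each of the five canonical bands; the denominator is
the total over the five bands, so each channel's row sums to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import BandDefinition, CANONICAL_BANDS, EpochedRecording

__all__ = [
    "Spectrum",
    "BandPowerTable",
    "welch_spectrum",
    "band_contributions",
    "band_variability",
]


@dataclass
class Spectrum:
    power: np.ndarray        # channels × frequency bins, µV²/Hz
    freq_axis: np.ndarray    # Hz
    bin_width: float


@dataclass
class BandPowerTable:
    contributions: np.ndarray    # channels × bands, percent
    band_names: tuple[str, ...]
    zero_power_channels: np.ndarray  # bool per channel

    def channel_mean(self) -> np.ndarray:
        """Contribution percentages averaged over valid channels."""
        ok = ~self.zero_power_channels
        return self.contributions[ok].mean(axis=0)


def welch_spectrum(recording: EpochedRecording, bin_width: float = 0.25,
                   segment_length: float = 4.0,
                   overlap: float = 0.5) -> Spectrum:
    """Per-channel Welch average periodogram over all epochs.

    Each epoch contributes Hamming-windowed segments (default 4 s, 50%
    overlap) zero-padded so the frequency grid reaches the requested
    ``bin_width``.
    """
    if not recording.is_epoched:
        raise ValueError("welch_spectrum expects epoched data")
    fs = recording.sampling_rate
    if recording.epoch_length < 1.0 / bin_width:
        raise ValueError(
            f"epoch of {recording.epoch_length}s cannot resolve "
            f"{bin_width} Hz bins"
        )
    nperseg = int(round(segment_length * fs))
    nperseg = min(nperseg, recording.n_samples)
    nfft = int(round(fs / bin_width))
    if nfft < nperseg:
        nfft = nperseg
    freqs, psd = signal.welch(
        recording.data, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), nfft=nfft, axis=-1,
        detrend="constant",
    )
    power = psd.mean(axis=1)  # average the per-epoch periodograms
    return Spectrum(power=power, freq_axis=freqs,
                    bin_width=float(freqs[1] - freqs[0]))


def band_contributions(spectrum: Spectrum,
                       bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
                       ) -> BandPowerTable:
    """Percentage of total (0–40 Hz) power per band and channel.

    Band edges are half-open [lo, hi) so abutting bands never share a
    bin. Channels with zero total power are flagged; their rows are set
    to NaN rather than divided.
    """
    band_power = np.stack([
        spectrum.power[:, b.mask(spectrum.freq_axis)].sum(axis=1) for b in bands
    ], axis=1)
    total = band_power.sum(axis=1)
    zero = total <= 0
    contributions = np.full_like(band_power, np.nan)
    contributions[~zero] = 100.0 * band_power[~zero] / total[~zero, None]
    return BandPowerTable(
        contributions=contributions,
        band_names=tuple(b.name for b in bands),
        zero_power_channels=zero,
    )


def band_variability(recording: EpochedRecording,
                     bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                     bin_width: float = 0.25) -> np.ndarray:
    """SD across epochs of channel-averaged band contributions.

    Contributions are computed per epoch from single-epoch spectra
    (same Welch settings as the grand spectrum), averaged over channels,
    and their standard deviation across epochs returned per band.
    """
    if not recording.is_epoched or recording.n_epochs < 2:
        raise ValueError("band variability needs ≥2 epochs")
    per_epoch = []
    for e in range(recording.n_epochs):
        single = recording.copy_with(recording.data[:, e : e + 1, :])
        table = band_contributions(welch_spectrum(single, bin_width), bands)
        per_epoch.append(table.channel_mean())
    return np.asarray(per_epoch).std(axis=0, ddof=0)
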