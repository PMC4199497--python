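"""Preprocessing: band-pass filtering, epoching, artifact rejection,
channel interpolation, average referencing, and the EOG-variability
control analysis.

The canonical order, logged in provenance, is

    bandpass (0.5–45 Hz) → epoch + baseline → variance-based rejection
    → neighbour interpolation of rejected channels → average reference

Filters are zero-phase FIR: phase distortion would corrupt downstream
phase-lag connectivity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochedRecording, Montage

__all__ = [
    "bandpass",
    "epoch_and_baseline",
    "reject_by_variance",
    "average_reference",
    "eog_variability",
    "interpolate_channels",
    "preprocess_pipeline",
    "RejectionReport",
    "EogTimecourse",
]


@dataclass
class RejectionReport:
    rejected_channels: list[str] = field(default_factory=list)
    rejected_epochs: list[int] = field(default_factory=list)
    channel_z: np.ndarray | None = None
    epoch_z: np.ndarray | None = None

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_channels) + len(self.rejected_epochs)


@dataclass
class EogTimecourse:
    """Normalized per-window SD of band-limited ocular activity.

    ``values`` are 1-second-window standard deviations of the 1–3 Hz
    bipolar EOG derivations, averaged over the two derivations and
    divided by the mean over all windows (so they average to 1 unless
    the recording is degenerate). ``halves_means`` compares the first
    and second half of the session — a progressive decline would flag
    sleep onset.
    """

    values: np.ndarray
    halves_means: tuple[float, float]
    degenerate: bool = False


def _fir_kernel(lo: float, hi: float, fs: float) -> np.ndarray:
    """Symmetric (zero-phase) Hamming band-pass kernel.

    Transition width is 25% of each cutoff; kernel length follows the
    Hamming window's ~3.3/Δf rule.
    """
    nyq = fs / 2.0
    if not 0 <= lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) invalid for fs={fs}")
    trans = min(lo * 0.25 if lo > 0 else hi * 0.25, hi * 0.25)
    trans = max(trans, 0.05)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # odd → symmetric, zero phase
    if lo > 0:
        return signal.firwin(numtaps, [lo, hi], window="hamming",
                             pass_zero=False, fs=fs)
    return signal.firwin(numtaps, hi, window="hamming", fs=fs)


def _filter_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with no phase shift.

    A symmetric kernel has a purely real frequency response, so one
    centre-aligned FFT convolution pass is zero-phase.
    """
    n = data.shape[-1]
    if n < len(kernel) // 4:
        raise ValueError(
            f"signal of {n} samples is too short for a {len(kernel)}-tap "
            "filter; use longer epochs or a wider transition band"
        )
    out = signal.fftconvolve(data, kernel[None, :] if data.ndim == 2
                             else kernel, mode="full", axes=-1)
    half = (len(kernel) - 1) // 2
    return out[..., half : half + n]


def bandpass(recording: EpochedRecording, lo: float = 0.5,
             hi: float = 45.0) -> EpochedRecording:
    """Zero-phase FIR band-pass; removes DC whenever ``lo`` > 0."""
    kernel = _fir_kernel(lo, hi, recording.sampling_rate)
    data = recording.data
    shape = data.shape
    flat = data.reshape(-1, shape[-1])
    if lo > 0:
        flat = flat - flat.mean(axis=-1, keepdims=True)
    out = _filter_zero_phase(flat, kernel).reshape(shape)
    return recording.copy_with(out, note=f"bandpass:{lo}-{hi}Hz")


def epoch_and_baseline(recording: EpochedRecording, epoch_length: float = 10.0,
                       n_epochs: int = 60) -> EpochedRecording:
    """Cut the first ``n_epochs`` epochs and remove each epoch's mean.

    Exactly ``n_epochs × epoch_length`` seconds are used (600 s at the
    defaults); each epoch is baseline-corrected to zero mean per channel.
    """
    if recording.is_epoched:
        raise ValueError("recording is already epoched")
    fs = recording.sampling_rate
    samples_per_epoch = int(round(fs * epoch_length))
    needed = samples_per_epoch * n_epochs
    if recording.data.shape[1] < needed:
        raise ValueError(
            f"continuous data has {recording.data.shape[1]} samples; "
            f"{needed} required for {n_epochs} × {epoch_length}s epochs"
        )
    cut = recording.data[:, :needed]
    epoched = cut.reshape(recording.n_channels, n_epochs, samples_per_epoch)
    epoched = epoched - epoched.mean(axis=2, keepdims=True)
    out = recording.copy_with(epoched, epoch_length=epoch_length,
                              note=f"epoch:{n_epochs}x{epoch_length}s+baseline")
    return out


def reject_by_variance(recording: EpochedRecording, z_channel: float = 4.0,
                       z_epoch: float = 4.0
                       ) -> tuple[EpochedRecording, RejectionReport]:
    """Drop abnormally noisy channels and epochs by normalized variance.

    Log-variance per channel (pooled over epochs) and per epoch (pooled
    over channels) is z-scored; entries above threshold are removed.
    Rejected channels are dropped here and later refilled by
    :func:`interpolate_channels` before re-referencing.
    """
    if not recording.is_epoched:
        raise ValueError("variance rejection operates on epoched data")
    if recording.n_channels < 4 or recording.n_epochs < 4:
        raise ValueError("need ≥4 channels and ≥4 epochs for z-scores")
    var_ce = recording.data.var(axis=2)  # channels × epochs
    logv = np.log(var_ce + np.finfo(float).tiny)

    ch_score = logv.mean(axis=1)
    ch_z = (ch_score - ch_score.mean()) / (ch_score.std() or 1.0)
    bad_ch = np.where(ch_z > z_channel)[0]

    keep_ch = np.setdiff1d(np.arange(recording.n_channels), bad_ch)
    ep_score = logv[keep_ch].mean(axis=0)
    ep_z = (ep_score - ep_score.mean()) / (ep_score.std() or 1.0)
    bad_ep = np.where(ep_z > z_epoch)[0]

    if len(bad_ch) > recording.n_channels / 2 or len(bad_ep) > recording.n_epochs / 2:
        raise RuntimeError(
            f"rejection would remove {len(bad_ch)} channels and "
            f"{len(bad_ep)} epochs (>50%); aborting — check the recording"
        )
    keep_ep = np.setdiff1d(np.arange(recording.n_epochs), bad_ep)
    data = recording.data[np.ix_(keep_ch, keep_ep)]
    labels = tuple(recording.labels[i] for i in keep_ch)
    report = RejectionReport(
        rejected_channels=[recording.labels[i] for i in bad_ch],
        rejected_epochs=[int(i) for i in bad_ep],
        channel_z=ch_z, epoch_z=ep_z,
    )
    out = recording.copy_with(
        data, labels=labels,
        note=f"reject:channels={report.rejected_channels},epochs={report.rejected_epochs}",
    )
    return out, report


def interpolate_channels(recording: EpochedRecording, montage: Montage,
                         missing: list[str], k: int = 4) -> EpochedRecording:
    """Refill missing channels by inverse-distance average of k neighbours.

    A deliberate simplification of spherical-spline interpolation; the
    interpolated channels re-enter the montage order so the average
    reference and distance-based metrics see the full channel set.
    """
    if not missing:
        return recording
    have = {l: i for i, l in enumerate(recording.labels)}
    out_labels = [l for l in montage.labels if l in have or l in missing]
    n_out = len(out_labels)
    shape = (n_out,) + recording.data.shape[1:]
    data = np.empty(shape)
    for oi, lab in enumerate(out_labels):
        if lab in have:
            data[oi] = recording.data[have[lab]]
            continue
        d = montage.distances[montage.index(lab)]
        donors = sorted(
            (l for l in recording.labels), key=lambda l: d[montage.index(l)]
        )[:k]
        dist = np.array([d[montage.index(l)] for l in donors])
        w = 1.0 / np.maximum(dist, 1e-6)
        w /= w.sum()
        data[oi] = np.tensordot(
            w, recording.data[[have[l] for l in donors]], axes=(0, 0)
        )
    return recording.copy_with(data, labels=tuple(out_labels),
                               note=f"interpolate:{missing}")


def average_reference(recording: EpochedRecording) -> EpochedRecording:
    """Re-reference to the instantaneous mean of all channels."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs ≥2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data, note="average_reference")


def eog_variability(raw: EpochedRecording,
                    left_pair: tuple[str, str] = ("25", "127"),
                    right_pair: tuple[str, str] = ("8", "126"),
                    window: float = 1.0) -> EogTimecourse:
    """Ocular-activity timecourse from bipolar EOG derivations.

    The two vertical derivations (left/right channel subtractions,
    computed on the raw pre-rejection recording) are filtered to 1–3 Hz
    to isolate eye movements, their SD is taken in non-overlapping
    1-second windows, averaged over the two derivations and normalized
    by the overall mean SD.
    """
    if raw.is_epoched:
        raise ValueError("EOG derivation uses the raw continuous recording")
    idx = {}
    missing = []
    for lab in (*left_pair, *right_pair):
        try:
            idx[lab] = raw.labels.index(lab)
        except ValueError:
            missing.append(lab)
    if missing:
        raise ValueError(f"EOG channels missing from recording: {missing}")
    derivs = np.stack([
        raw.data[idx[left_pair[0]]] - raw.data[idx[left_pair[1]]],
        raw.data[idx[right_pair[0]]] - raw.data[idx[right_pair[1]]],
    ])
    kernel = _fir_kernel(1.0, 3.0, raw.sampling_rate)
    derivs = _filter_zero_phase(derivs - derivs.mean(-1, keepdims=True), kernel)
    wlen = int(round(window * raw.sampling_rate))
    n_win = derivs.shape[1] // wlen
    wins = derivs[:, : n_win * wlen].reshape(2, n_win, wlen)
    sd = wins.std(axis=2).mean(axis=0)  # averaged over the two derivations
    mean_sd = sd.mean()
    if mean_sd <= 0:
        return EogTimecourse(values=np.zeros(n_win),
                             halves_means=(0.0, 0.0), degenerate=True)
    values = sd / mean_sd
    half = n_win // 2
    return EogTimecourse(
        values=values,
        halves_means=(float(values[:half].mean()), float(values[half:].mean())),
    )


def preprocess_pipeline(raw: EpochedRecording, montage: Montage | None = None,
                        lo: float = 0.5, hi: float = 45.0,
                        epoch_length: float = 10.0, n_epochs: int = 60,
                        z_channel: float = 4.0, z_epoch: float = 4.0
                        ) -> tuple[EpochedRecording, RejectionReport]:
    """Full preprocessing chain on a continuous raw recording."""
    rec = bandpass(raw, lo, hi)
    rec = epoch_and_baseline(rec, epoch_length, n_epochs)
    rec, report = reject_by_variance(rec, z_channel, z_epoch)
    if montage is not None and report.rejected_channels:
        rec = interpolate_channels(rec, montage, report.rejected_channels)
    rec = average_reference(rec)
    return rec, report
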