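"""Core data containers shared by every analysis stage.

The pipeline operates on sensor-space EEG: a voltage tensor per subject,
an electrode montage giving scalp geometry, and a small clinical metadata
record per subject. Frequency bands are the five canonical EEG bands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Montage",
    "EpochedRecording",
    "SubjectRecord",
    "BandDefinition",
    "CANONICAL_BANDS",
    "ANALYSIS_BANDS",
]

GROUPS = ("control", "VS", "MCS")


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between rows of ``positions`` (n × 3)."""
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass(frozen=True)
class Montage:
    """Electrode layout: labels, 3D positions and normalized distances.

    ``distances`` is the symmetric matrix of pairwise Euclidean
    inter-electrode distances rescaled so the most distant pair is
    exactly 1; only these dimensionless distances are used downstream
    (e.g. by the modular-span metric), so the coordinate unit is
    irrelevant.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3)
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.labels) != positions.shape[0]:
            raise ValueError("one position required per label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        if positions.shape[0] < 2:
            raise ValueError("a montage needs at least 2 channels")
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "positions", positions)
        if self.distances is None:
            d = pairwise_distances(positions)
            dmax = d.max()
            if dmax <= 0:
                raise ValueError("all electrodes coincide; distances undefined")
            object.__setattr__(self, "distances", d / dmax)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "Montage":
        """Montage restricted to ``labels`` (distances re-normalized)."""
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])


@dataclass
class EpochedRecording:
    """EEG voltages, either continuous or segmented into epochs.

    ``data`` has shape (channels, epochs, samples) once epoched, or
    (channels, samples) while still continuous (``is_epoched`` tells
    which). Voltages are in microvolts.
    """

    data: np.ndarray
    sampling_rate: float
    labels: tuple[str, ...]
    epoch_length: float | None = None  # seconds; None while continuous
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = tuple(str(l) for l in self.labels)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} data channels vs {len(self.labels)} labels"
            )
        if self.data.ndim == 3:
            if self.epoch_length is None:
                self.epoch_length = self.data.shape[2] / self.sampling_rate
            expected = int(round(self.sampling_rate * self.epoch_length))
            if self.data.shape[2] != expected:
                raise ValueError(
                    f"epoch has {self.data.shape[2]} samples, expected "
                    f"{expected} = sampling_rate × epoch_length"
                )
        elif self.data.ndim != 2:
            raise ValueError("data must be 2-D (continuous) or 3-D (epoched)")

    @property
    def is_epoched(self) -> bool:
        return self.data.ndim == 3

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        if not self.is_epoched:
            raise ValueError("recording is continuous; no epochs")
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy_with(self, data: np.ndarray, note: str | None = None,
                  labels: tuple[str, ...] | None = None,
                  epoch_length: float | None = None) -> "EpochedRecording":
        out = EpochedRecording(
            data=np.asarray(data),
            sampling_rate=self.sampling_rate,
            labels=self.labels if labels is None else labels,
            epoch_length=(self.epoch_length if epoch_length is None
                          else epoch_length) if np.asarray(data).ndim == 3 else None,
            provenance=list(self.provenance),
        )
        if note:
            out.log(note)
        return out


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical metadata for one subject.

    ``group`` is one of ``control`` (healthy), ``VS`` (vegetative state)
    or ``MCS`` (minimally conscious state). ``crs_r`` is the Coma
    Recovery Scale–Revised total score, required for patients and absent
    for controls. ``imagery`` flags covert command-following in an fMRI
    motor-imagery task.
    """

    subject_id: str
    group: str
    crs_r: int | None = None
    imagery: bool | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.is_patient and self.crs_r is None:
            raise ValueError(f"patient {self.subject_id} is missing a CRS-R score")
        if self.crs_r is not None and not isinstance(self.crs_r, (int, np.integer)):
            raise ValueError("crs_r must be an integer score")

    @property
    def is_patient(self) -> bool:
        return self.group in ("VS", "MCS")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, exclusive

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask over a frequency axis; half-open [lo, hi)."""
        return (freqs >= self.lo) & (freqs < self.hi)


#: The five canonical EEG bands; they partition 0–40 Hz with half-open
#: [lo, hi) edges so no spectral bin is counted twice.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

#: Bands carried into connectivity/graph analysis. Beta and gamma are
#: excluded by default because scalp EMG contaminates them in patients.
ANALYSIS_BANDS: tuple[BandDefinition, ...] = CANONICAL_BANDS[:3]


def band_by_name(name: str) -> BandDefinition:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(name)
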