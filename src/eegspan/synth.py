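"""Synthetic EEG cohorts with planted spectral and network structure.

The generator emulates the two resting-state phenotypes the analysis is
designed to separate:

* **control-like** subjects carry a global posterior-dominant alpha
  rhythm plus two *long-range* fronto-parietal alpha modules — groups of
  electrodes sharing a 10 Hz source with non-zero pairwise phase lags —
  laid out identically across subjects (healthy alpha topology is
  stereotyped);
* **patient-like** subjects show slowed EEG (steeper 1/f background,
  strong delta), *short-range* delta and theta clusters placed
  idiosyncratically per subject, and a residual long-range alpha module
  whose coupling strength κ varies across patients and drives a
  synthetic CRS-R score (the planted "network quality").

Sources are amplitude-modulated sinusoids with per-epoch random phase
plus 1/f pink noise — not a biophysical model; the downstream analysis
consumes only phase statistics, so this is the simplest generator with
controllable phase-lag connectivity. Volume conduction is modelled as
instantaneous distance-decaying linear mixing (a Gaussian kernel over
normalized inter-electrode distance), reproducing the zero-lag confound
the dwPLI estimator is built to reject.
"""

from __future__ import annotations

import json
import zlib as _zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import EpochedRecording, Montage, SubjectRecord
from . import io as _io

__all__ = [
    "CouplingRegime",
    "GroupRegime",
    "CohortSpec",
    "SubjectTruth",
    "generate_montage",
    "simulate_coupled_pair",
    "simulate_subject",
    "simulate_cohort",
    "planted_partition_matrix",
]


@dataclass(frozen=True)
class CouplingRegime:
    """One planted phase-coupled module system.

    ``kappa`` is the phase-coupling consistency: each member's phase
    offset is re-jittered every epoch with SD (1 − κ)·π/2 radians, so
    κ = 1 locks the planted lags perfectly and κ = 0 decouples the
    members entirely. A (lo, hi) tuple draws κ per subject. κ controls
    *connectivity* while ``amp`` controls band *power*, keeping the two
    phenomena independent. Member lags are laid out spatially smoothly
    and strictly inside (0, π) — zero/π lags would be invisible to a
    phase-lag estimator by design.
    """

    band: str
    freq: float                 # Hz
    kappa: float | tuple[float, float]
    n_modules: int = 2
    module_size: int = 12
    spatial: str = "long"       # "long" (split anterior/posterior) or "short"
    lag_spread: float = np.pi / 2   # radians, max lag across the module
    lag_within: float = 0.3     # radians, lag spread among adjacent members
    common_layout: bool = True  # same layout for every subject in the group
    amp: float = 30.0           # source amplitude at κ=1, µV
    amp_jitter: float = 0.2     # per-epoch log-amplitude SD (nonstationarity)

    def __post_init__(self):
        k = self.kappa
        lo, hi = (k, k) if np.isscalar(k) else k
        if not (0 <= lo <= hi <= 1):
            raise ValueError("kappa must lie in [0, 1]")
        if not 0 < self.lag_spread < np.pi:
            raise ValueError("lag_spread must lie strictly inside (0, π)")
        if not 0 <= self.lag_within < np.pi / 2:
            raise ValueError("lag_within must lie in [0, π/2)")
        if self.spatial not in ("long", "short"):
            raise ValueError("spatial must be 'long' or 'short'")


@dataclass(frozen=True)
class GroupRegime:
    """Coupling regimes plus background for one subject group."""

    regimes: tuple[CouplingRegime, ...]
    noise_exponent: float = 1.0       # 1/f^β background
    noise_amplitude: float = 10.0     # µV SD per channel
    background: tuple[tuple[float, float, float, float], ...] = ()
    # background entries: (freq Hz, amplitude µV, per-epoch amp jitter,
    # κ) — ambient oscillators on every channel. κ = 0 draws a fresh
    # random phase per channel and epoch (pure band power, no
    # coupling); κ > 0 phase-locks the channels into a travelling wave
    # whose lag follows the electrode's azimuth around the cap (full
    # circle, so the wave cancels in the channel mean and is neutral
    # under average referencing), with per-epoch phase jitter of SD
    # (1 − κ)·π/2 — a broadly synchronous ambient rhythm.
    local_sync: tuple[tuple[float, float, float, float, float], ...] = ()
    # local_sync entries: (freq Hz, amplitude µV, white jitter SD rad,
    # smooth jitter SD rad, correlation length in normalized distance)
    # — a short-range synchrony field: a fixed fast-rotating lag map
    # plus per-epoch phase jitter with a spatially *smooth* component
    # (shared by neighbours) and a white per-channel component. Nearby
    # electrodes share the smooth jitter, so their non-zero lags stay
    # consistent across epochs up to the white floor — visible to a
    # phase-lag estimator but capped well below saturation; distant
    # electrodes decohere entirely. Produces spatially localised,
    # short-to-medium-range connectivity without long-range structure
    # and without extreme peak weights.


_CONTROL_DEFAULT = GroupRegime(
    regimes=(
        CouplingRegime(band="alpha", freq=10.0, kappa=0.85, n_modules=3,
                       module_size=16, spatial="long", common_layout=True,
                       amp=30.0, amp_jitter=0.4),
        # focal frontal-midline slow generators, a normal feature of
        # healthy EEG: small, consistently coupled, low amplitude
        CouplingRegime(band="delta", freq=2.5, kappa=0.75, n_modules=1,
                       module_size=5, spatial="short", common_layout=True,
                       amp=12.0, amp_jitter=0.2),
        CouplingRegime(band="theta", freq=6.0, kappa=0.75, n_modules=1,
                       module_size=5, spatial="short", common_layout=True,
                       amp=12.0, amp_jitter=0.2),
    ),
    noise_exponent=0.8,
    background=((10.0, 15.0, 0.4, 0.7),),
)

_PATIENT_DEFAULT = GroupRegime(
    regimes=(
        CouplingRegime(band="delta", freq=2.5, kappa=0.5, n_modules=5,
                       module_size=12, spatial="short", common_layout=True,
                       amp=30.0, amp_jitter=0.1),
        CouplingRegime(band="theta", freq=6.0, kappa=0.45, n_modules=4,
                       module_size=12, spatial="short", common_layout=True,
                       amp=20.0, amp_jitter=0.1),
        # spared focal occipital alpha generator, common to all
        # patients and independent of the long-range alpha quality
        # (listed first so the long-range regime below defines the
        # subject's alpha κ and ground-truth modules)
        CouplingRegime(band="alpha", freq=10.0, kappa=0.9, n_modules=1,
                       module_size=5, spatial="short", common_layout=True,
                       amp=12.0, amp_jitter=0.1),
        CouplingRegime(band="alpha", freq=10.0, kappa=(0.05, 0.6),
                       n_modules=2, module_size=18, spatial="long",
                       common_layout=True, amp=25.0, amp_jitter=0.1),
    ),
    noise_exponent=1.4,
    local_sync=((2.5, 35.0, 0.3, 1.5, 0.35), (6.0, 25.0, 0.3, 1.5, 0.35)),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_controls: int = 15
    n_patients: int = 15
    n_channels: int = 91
    sampling_rate: float = 250.0
    n_epochs: int = 60
    epoch_length: float = 10.0
    control: GroupRegime = _CONTROL_DEFAULT
    patient: GroupRegime = _PATIENT_DEFAULT
    mixing_width: float = 0.05      # Gaussian kernel σ over normalized distance
    crs_r_intercept: float = 6.5
    crs_r_slope: float = 20.0       # on the planted alpha κ
    crs_r_noise_sd: float = 1.0
    crs_r_range: tuple[int, int] = (7, 19)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_controls, self.n_patients) < 0 or self.n_channels < 2:
            raise ValueError("counts must be positive")
        if self.n_epochs < 1 or self.epoch_length <= 0 or self.sampling_rate <= 0:
            raise ValueError("invalid timing parameters")


@dataclass
class SubjectTruth:
    """Ground truth planted in one subject, for recovery tests."""

    subject_id: str
    group: str
    kappa: dict[str, float]                 # band → planted coupling strength
    modules: dict[str, np.ndarray]          # band → node assignment (0 = none)

    def asjson(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "kappa": self.kappa,
            "modules": {b: a.tolist() for b, a in self.modules.items()},
        }


# ---------------------------------------------------------------------------
# montage

def generate_montage(n_channels: int = 91, seed: int = 0,
                     cap_fraction: float = 0.6,
                     radius_cm: float = 10.0) -> Montage:
    """Quasi-uniform electrodes on a spherical cap (upper scalp).

    A Fibonacci lattice over the cap covering ``cap_fraction`` of the
    sphere's surface, with a small seeded angular jitter. Deterministic
    given the seed.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    z0 = 1.0 - 2.0 * cap_fraction
    k = np.arange(n_channels)
    z = 1.0 - (k + 0.5) / n_channels * (1.0 - z0)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = k * golden + rng.uniform(-0.02, 0.02, n_channels)
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pos = radius_cm * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{i + 1}" for i in range(n_channels))
    return Montage(labels, pos)


# ---------------------------------------------------------------------------
# elementary two-channel fixture

def simulate_coupled_pair(freq: float = 10.0, lag: float = np.pi / 2,
                          snr: float = 10.0, n_epochs: int = 60,
                          sampling_rate: float = 250.0,
                          epoch_length: float = 10.0,
                          seed: int = 0) -> EpochedRecording:
    """Two channels sharing one oscillation, the second lagged.

    Channel 2 is channel 1's sinusoid phase-shifted by ``lag``; each
    channel adds independent Gaussian noise so the oscillation-to-noise
    variance ratio equals ``snr``. The initial phase is redrawn per
    epoch. ``snr = 0`` yields two independent noise channels. ``lag`` is
    normalized into (−π, π].
    """
    nyq = sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"freq must lie in (0, {nyq})")
    lag = float(np.angle(np.exp(1j * lag)))  # wrap into (−π, π]
    rng = np.random.default_rng(seed)
    samples = int(round(sampling_rate * epoch_length))
    t = np.arange(samples) / sampling_rate
    amp = np.sqrt(2.0 * snr) if snr > 0 else 0.0  # unit noise variance
    data = np.empty((2, n_epochs, samples))
    for e in range(n_epochs):
        theta = rng.uniform(0, 2 * np.pi)
        data[0, e] = amp * np.sin(2 * np.pi * freq * t + theta)
        data[1, e] = amp * np.sin(2 * np.pi * freq * t + theta - lag)
    data += rng.standard_normal(data.shape)
    return EpochedRecording(
        data=data, sampling_rate=sampling_rate, labels=("A", "B"),
        epoch_length=epoch_length,
        provenance=[f"simulate_coupled_pair:f={freq},lag={lag:.3f},snr={snr}"],
    )


# ---------------------------------------------------------------------------
# subject-level generation

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, amplitude: float) -> np.ndarray:
    """1/f^β noise, unit-variance shaped spectrum scaled to ``amplitude``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * shaped / sd


def _layout_long(montage: Montage, size: int, which: int,
                 rng: np.random.Generator | None,
                 exclude: set[int]) -> np.ndarray:
    """A long-range module: half anterior + half posterior electrodes.

    ``which`` alternates the hemisphere (left/right/both) for the
    deterministic common layout; with an rng, candidate order is
    shuffled instead. Channels in ``exclude`` are never reused.
    """
    pos = montage.positions
    free = np.array([i for i in range(montage.n_channels) if i not in exclude],
                    dtype=int)
    if len(free) < 2:
        return free
    if rng is None:
        if which % 3 == 0:
            side = pos[free, 1] < 0
        elif which % 3 == 1:
            side = pos[free, 1] >= 0
        else:
            side = np.ones(len(free), bool)
        cand = free[side] if side.sum() >= size else free
        ant = cand[np.argsort(-pos[cand, 0], kind="stable")]
        post = cand[np.argsort(pos[cand, 0], kind="stable")]
    else:
        cand = rng.permutation(free)
        ant = cand[np.argsort(-pos[cand, 0], kind="stable")]
        post = cand[np.argsort(pos[cand, 0], kind="stable")]
    half = size // 2
    members = list(dict.fromkeys([*ant[:half], *post[: size - half]]))
    return np.asarray(members[:size])


def _layout_short(montage: Montage, size: int, rng: np.random.Generator,
                  exclude: set[int]) -> np.ndarray:
    """A compact module: a seed electrode and its nearest neighbours."""
    free = [i for i in range(montage.n_channels) if i not in exclude]
    if not free:
        return np.empty(0, dtype=int)
    seed_node = int(rng.choice(free))
    order = np.argsort(montage.distances[seed_node])
    members = [i for i in order if i not in exclude][:size]
    return np.asarray(members)


def _regime_layout(regime: CouplingRegime, montage: Montage,
                   rng: np.random.Generator) -> np.ndarray:
    """Node → module assignment (0 = background) for one regime."""
    assignment = np.zeros(montage.n_channels, dtype=np.int64)
    used: set[int] = set()
    # a common layout is derived from a fixed stream, so every subject
    # in the group plants the same module topography
    layout_rng = None if regime.common_layout else rng
    short_rng = (np.random.default_rng(_zlib.crc32(regime.band.encode()))
                 if regime.common_layout else rng)
    for m in range(regime.n_modules):
        if regime.spatial == "long":
            members = _layout_long(montage, regime.module_size, m, layout_rng,
                                   used)
        else:
            members = _layout_short(montage, regime.module_size, short_rng,
                                    used)
        assignment[members] = m + 1
        used.update(int(i) for i in members)
    return assignment


def _member_lags(regime: CouplingRegime, montage: Montage,
                 members: np.ndarray) -> np.ndarray:
    """Spatially smooth phase lags for one module's member channels.

    Long-range modules put a ``lag_spread`` offset between their
    anterior and posterior halves with a small ``lag_within`` gradient
    inside each half, so pairwise lags stay inside (0, π). Short-range
    clusters spread their lags evenly around the full circle, ranked
    radially from the seed electrode: the members' phasors then sum to
    ~zero, so a compact cluster leaves no net oscillation in the
    channel mean and survives average referencing without leaking
    consistent phase into uninvolved electrodes.
    """
    n_m = len(members)
    if n_m == 1:
        return np.zeros(1)
    pos = montage.positions[members]
    if regime.spatial == "long":
        anterior = pos[:, 0] >= np.median(pos[:, 0])
        lags = np.where(anterior, 0.0, regime.lag_spread)
        for half in (anterior, ~anterior):
            idx = np.where(half)[0]
            rank = np.argsort(np.argsort(pos[idx, 1]))
            lags[idx] += regime.lag_within * (rank + 1) / max(len(idx), 1)
    else:
        d_seed = montage.distances[members[0]][members]
        rank = np.argsort(np.argsort(d_seed))
        lags = 2.0 * np.pi * rank / n_m  # balanced: Σ exp(i·lag) = 0
    return lags


def _mixing_kernel(montage: Montage, width: float) -> np.ndarray:
    """Row-normalized Gaussian zero-lag volume-conduction kernel."""
    if width <= 0:
        return np.eye(montage.n_channels)
    g = np.exp(-((montage.distances / width) ** 2))
    return g / g.sum(axis=1, keepdims=True)


def simulate_subject(spec: CohortSpec, group: str, seed: int,
                     subject_id: str = "S0",
                     montage: Montage | None = None
                     ) -> tuple[EpochedRecording, SubjectRecord, SubjectTruth]:
    """Generate one subject's continuous recording plus metadata.

    Module sources oscillate in their regime band with spatially
    smooth member lags, phase-jittered per epoch according to the
    regime's κ; everything is passed through the zero-lag mixing kernel
    and overlaid on 1/f noise. Patient-like subjects draw the alpha κ
    per subject, and the synthetic CRS-R is a noisy linear function of
    that κ, clipped to the configured integer range.
    """
    if montage is None:
        montage = generate_montage(spec.n_channels, seed=spec.seed)
    rng = np.random.default_rng(seed)
    regime_set = spec.control if group == "control" else spec.patient
    fs = spec.sampling_rate
    samples = int(round(fs * spec.epoch_length))
    n_total = samples * spec.n_epochs
    t_epoch = np.arange(samples) / fs

    data = _pink_noise(rng, montage.n_channels, n_total,
                       regime_set.noise_exponent, regime_set.noise_amplitude)
    data = data.reshape(montage.n_channels, spec.n_epochs, samples)

    # ambient oscillators on every channel: incoherent (κ=0) or a
    # travelling wave with an azimuthal lag map (κ>0)
    lag_map = np.arctan2(montage.positions[:, 1], montage.positions[:, 0])
    for freq, amp, jitter, kap in regime_set.background:
        phase_sd = (1.0 - kap) * np.pi / 2.0
        for e in range(spec.n_epochs):
            if kap <= 0:
                phases = rng.uniform(0, 2 * np.pi, montage.n_channels)
            else:
                phases = (rng.uniform(0, 2 * np.pi) + lag_map
                          + phase_sd * rng.standard_normal(montage.n_channels))
            amps = amp * np.exp(jitter * rng.standard_normal(montage.n_channels)
                                - jitter**2 / 2)
            data[:, e] += amps[:, None] * np.sin(
                2 * np.pi * freq * t_epoch[None, :] + phases[:, None]
            )

    # short-range synchrony fields (patient-like slow-band coupling)
    for freq, amp, sd_white, sd_smooth, ell in regime_set.local_sync:
        eta = np.mod(3.0 * lag_map, 2 * np.pi)  # fixed fast-rotating lags
        k_smooth = np.exp(-((montage.distances / ell) ** 2))
        k_smooth /= np.linalg.norm(k_smooth, axis=1, keepdims=True)
        for e in range(spec.n_epochs):
            theta = rng.uniform(0, 2 * np.pi)
            delta_phase = (
                sd_smooth * (k_smooth @ rng.standard_normal(montage.n_channels))
                + sd_white * rng.standard_normal(montage.n_channels)
            )
            data[:, e] += amp * np.sin(
                2 * np.pi * freq * t_epoch[None, :]
                + (theta + eta + delta_phase)[:, None]
            )

    kappa: dict[str, float] = {}
    modules: dict[str, np.ndarray] = {}
    for regime in regime_set.regimes:
        k = regime.kappa
        k = float(k) if np.isscalar(k) else float(rng.uniform(*k))
        kappa[regime.band] = k
        assignment = _regime_layout(regime, montage, rng)
        modules[regime.band] = assignment
        if k <= 0:
            continue
        phase_sd = (1.0 - k) * np.pi / 2.0
        for m in np.unique(assignment[assignment > 0]):
            members = np.where(assignment == m)[0]
            lags = _member_lags(regime, montage, members)
            for e in range(spec.n_epochs):
                theta = rng.uniform(0, 2 * np.pi)
                a_e = regime.amp * np.exp(
                    regime.amp_jitter * rng.standard_normal()
                    - regime.amp_jitter**2 / 2
                )
                jitter = phase_sd * rng.standard_normal(len(members))
                data[members, e] += a_e * np.sin(
                    2 * np.pi * regime.freq * t_epoch[None, :]
                    + theta + (lags + jitter)[:, None]
                )

    mixed = np.einsum("ij,jes->ies", _mixing_kernel(montage, spec.mixing_width),
                      data)
    recording = EpochedRecording(
        data=mixed.reshape(montage.n_channels, n_total),
        sampling_rate=fs, labels=montage.labels,
        provenance=[f"simulate_subject:group={group},seed={seed}"],
    )

    if group == "control":
        record = SubjectRecord(subject_id=subject_id, group="control")
    else:
        k_alpha = kappa.get("alpha", 0.0)
        raw_score = (spec.crs_r_intercept + spec.crs_r_slope * k_alpha
                     + spec.crs_r_noise_sd * rng.standard_normal())
        crs = int(np.clip(round(raw_score), *spec.crs_r_range))
        grp = "VS" if crs <= 8 else "MCS"
        # imagery-positive covert awareness is more likely with a
        # better-preserved alpha network, as in the clinical cohort
        p_img = 0.15 + 0.55 * (k_alpha > 0.33)
        record = SubjectRecord(subject_id=subject_id, group=grp, crs_r=crs,
                               imagery=bool(rng.random() < p_img))
    truth = SubjectTruth(subject_id=subject_id, group=record.group,
                         kappa=kappa, modules=modules)
    return recording, record, truth


def simulate_cohort(spec: CohortSpec, out_dir: str | Path | None = None
                    ) -> tuple[Montage, list[tuple[EpochedRecording,
                                                   SubjectRecord,
                                                   SubjectTruth]]]:
    """Generate a full cohort; optionally write all artifacts to disk.

    Per-subject seeds are derived from the master seed. When ``out_dir``
    is given, writes internal-format recordings, the montage file, the
    metadata CSV and a ground-truth JSON (planted partitions and κ).
    """
    montage = generate_montage(spec.n_channels, seed=spec.seed)
    n = spec.n_controls + spec.n_patients
    seeds = np.random.SeedSequence(spec.seed).generate_state(n) % (2**31)
    subjects = []
    for i in range(n):
        group = "control" if i < spec.n_controls else "patient"
        sid = f"C{i + 1}" if group == "control" else f"P{i + 1 - spec.n_controls}"
        subjects.append(
            simulate_subject(spec, group, int(seeds[i]), sid, montage)
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _io.save_montage(montage, out_dir / "montage.txt")
        _io.write_subject_table([r for _, r, _ in subjects],
                                out_dir / "subjects.csv")
        for rec, r, _ in subjects:
            _io.write_recording(rec, out_dir / f"{r.subject_id}.h5")
        truths = {t.subject_id: t.asjson() for _, _, t in subjects}
        (out_dir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return montage, subjects


def null_cohort_spec(base: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A spec whose 'patient' group duplicates the control regime.

    Used for statistical-calibration runs where both groups are drawn
    from the same distribution.
    """
    base = base or CohortSpec()
    return replace(base, patient=base.control, **overrides)


# ---------------------------------------------------------------------------
# planted-partition benchmark (community detection recovery)

def planted_partition_matrix(n_nodes: int = 40, n_blocks: int = 4,
                             p_in: float = 0.9, p_out: float = 0.05,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic block model adjacency with equal blocks.

    Returns the symmetric 0/1 weight matrix and the ground-truth
    assignment (labels from 1).
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_blocks) + 1, int(np.ceil(n_nodes / n_blocks)))
    labels = labels[:n_nodes]
    same = labels[:, None] == labels[None, :]
    p = np.where(same, p_in, p_out)
    upper = rng.random((n_nodes, n_nodes)) < p
    adj = np.triu(upper, k=1).astype(float)
    return adj + adj.T, labels
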