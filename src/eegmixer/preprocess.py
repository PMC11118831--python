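"""EEG preprocessing: 10-20 montage validation, Butterworth band-pass
filtering, fixed-length epoching, and per-channel standardization.

The pipeline mirrors common clinical-EEG practice for pediatric ADHD
cohorts: 19 scalp channels of the International 10-20 system sampled at
128 Hz, band-passed to 4-45 Hz with a sixth-order Butterworth filter
(removing slow drift and line/EMG noise while keeping theta through
gamma-onset activity), then cut into non-overlapping 4-s epochs that serve
as classification samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import FilterError, MontageError, SegmentationError

#: Canonical ordering of the 19 scalp channels of the 10-20 montage used
#: for pediatric ADHD recordings (frontal to occipital, midline first).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fz", "Cz", "Pz", "C3", "T3", "C4", "T4", "Fp1", "Fp2", "F3",
    "F4", "F7", "F8", "P3", "P4", "T5", "T6", "O1", "O2",
)

#: Earlobe reference electrodes; carried by some files but not data channels.
REFERENCE_CHANNELS: tuple[str, ...] = ("A1", "A2")

_CANON_BY_LOWER = {c.lower(): c for c in CANONICAL_CHANNELS}
_REF_BY_LOWER = {c.lower(): c for c in REFERENCE_CHANNELS}


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    data is [channels x samples] in microvolts; label is 1 for the
    ADHD-like (positive) class, 0 for the TD-like class, None if unknown.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"data must be [channels x samples], got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FilterSpec:
    """A digital Butterworth band-pass in cascaded second-order sections."""

    order: int
    low_hz: float
    high_hz: float
    fs: float
    sos: np.ndarray = field(repr=False)

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex single-pass response at the given frequencies."""
        _, h = signal.sosfreqz(self.sos, worN=2 * np.pi * np.asarray(freqs_hz) / self.fs)
        return h


@dataclass
class EpochSet:
    """A stack of fixed-length epochs with per-epoch subject IDs and labels.

    epochs is [n_epochs x channels x samples_per_epoch].
    """

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    epoch_seconds: float
    channel_names: list[str] = field(default_factory=lambda: list(CANONICAL_CHANNELS))

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length must match n_epochs")
        # each subject carries exactly one label
        for sid in np.unique(self.subject_ids):
            if len(np.unique(self.labels[self.subject_ids == sid])) > 1:
                raise ValueError(f"subject {sid!r} has conflicting labels")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


def validate_montage(channel_names: list[str]) -> tuple[list[str], list[int], list[int]]:
    """Check channel labels against the canonical 19-channel 10-20 montage.

    Matching is case-insensitive.  Returns ``(canonical_names, permutation,
    dropped)`` where ``permutation[i]`` is the input index holding canonical
    channel ``i`` and ``dropped`` lists indices of reference electrodes
    (A1/A2) to exclude from the data tensor.

    Raises
    ------
    MontageError
        If a canonical channel is missing, a label is duplicated, or a
        label is neither canonical nor a reference electrode.
    """
    seen: dict[str, int] = {}
    dropped: list[int] = []
    for i, name in enumerate(channel_names):
        key = name.strip().lower()
        if key in _REF_BY_LOWER:
            dropped.append(i)
            continue
        if key not in _CANON_BY_LOWER:
            raise MontageError(f"unknown channel label {name!r} (not in the 10-20 montage)")
        if key in seen:
            raise MontageError(f"duplicate channel label {name!r}")
        seen[key] = i
    missing = [c for c in CANONICAL_CHANNELS if c.lower() not in seen]
    if missing:
        raise MontageError(f"missing canonical channel(s): {', '.join(missing)}")
    permutation = [seen[c.lower()] for c in CANONICAL_CHANNELS]
    return list(CANONICAL_CHANNELS), permutation, dropped


def reorder_channels(rec: Recording) -> Recording:
    """Return a copy of `rec` with channels in canonical montage order and
    reference electrodes dropped."""
    names, perm, _ = validate_montage(rec.channel_names)
    return replace(rec, data=rec.data[perm], channel_names=names)


def design_bandpass(order: int = 6, low_hz: float = 4.0, high_hz: float = 45.0,
                    fs: float = 128.0) -> FilterSpec:
    """Design a digital Butterworth band-pass filter.

    The analog prototype is mapped to the digital domain with the bilinear
    transform (frequency prewarping), factored into second-order sections
    for numerical stability.  The half-power (-3 dB) points of the
    single-pass response sit at ``low_hz`` and ``high_hz``.
    """
    if order < 2:
        raise FilterError(f"order must be >= 2, got {order}")
    if not (0 < low_hz < high_hz < fs / 2):
        raise FilterError(
            f"cutoffs must satisfy 0 < low < high < fs/2; got "
            f"low={low_hz}, high={high_hz}, fs={fs}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(order=order, low_hz=low_hz, high_hz=high_hz, fs=fs, sos=sos)


def _settle_length(spec: FilterSpec) -> int:
    """Approximate impulse-response settling length of the filter."""
    # scipy uses the same padding heuristic inside sosfiltfilt
    return 3 * (2 * spec.sos.shape[0] + 1)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply the band-pass zero-phase (forward-backward over the sections).

    Each channel is filtered independently; shape and metadata are
    preserved.  Zero-phase filtering squares the magnitude response, so the
    effective roll-off is twice the design order.
    """
    if rec.fs != spec.fs:
        raise FilterError(f"recording fs {rec.fs} != filter fs {spec.fs}")
    min_len = 3 * _settle_length(spec)
    if rec.n_samples <= min_len:
        raise FilterError(
            f"recording of {rec.n_samples} samples too short for stable "
            f"filtering (need > {min_len})"
        )
    filtered = signal.sosfiltfilt(spec.sos, rec.data, axis=1)
    return replace(rec, data=np.ascontiguousarray(filtered))


def segment(rec: Recording, epoch_seconds: float = 4.0) -> EpochSet:
    """Cut a continuous recording into non-overlapping fixed-length epochs.

    Epoch ``i`` covers samples ``[i*N, (i+1)*N)`` with
    ``N = round(fs * epoch_seconds)``; trailing samples that do not fill a
    complete epoch are dropped.  The recording's label and subject ID are
    broadcast to every epoch.
    """
    n = int(round(rec.fs * epoch_seconds))
    t = rec.n_samples
    n_epochs = t // n
    if n_epochs < 1:
        raise SegmentationError(
            f"recording of {t} samples shorter than one {epoch_seconds}-s "
            f"epoch ({n} samples)"
        )
    trimmed = rec.data[:, : n_epochs * n]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n).transpose(1, 0, 2)
    label = -1 if rec.label is None else rec.label
    return EpochSet(
        epochs=np.ascontiguousarray(epochs),
        labels=np.full(n_epochs, label, dtype=np.int64),
        subject_ids=np.full(n_epochs, rec.subject_id, dtype=object),
        fs=rec.fs,
        epoch_seconds=epoch_seconds,
        channel_names=list(rec.channel_names),
    )


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets from multiple subjects into one."""
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    fs = sets[0].fs
    secs = sets[0].epoch_seconds
    if any(s.fs != fs or s.epoch_seconds != secs for s in sets):
        raise ValueError("epoch sets disagree on fs or epoch length")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        fs=fs,
        epoch_seconds=secs,
        channel_names=list(sets[0].channel_names),
    )


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation used for z-scoring."""

    mean: np.ndarray
    sd: np.ndarray


def standardize(es: EpochSet, stats: ChannelStats | None = None,
                sd_floor: float = 1e-8) -> tuple[EpochSet, ChannelStats]:
    """Z-score every channel.

    When ``stats`` is None the mean/sd are estimated from ``es`` (training
    data) and returned for reuse on held-out data, so no test-set statistics
    leak into the transform.  Channels with (near-)zero variance are floored
    at ``sd_floor`` with a warning.
    """
    if es.n_epochs == 0:
        raise ValueError("cannot standardize an empty epoch set")
    if stats is None:
        mean = es.epochs.mean(axis=(0, 2))
        sd = es.epochs.std(axis=(0, 2))
        if np.any(sd < sd_floor):
            flat = [es.channel_names[i] for i in np.flatnonzero(sd < sd_floor)]
            warnings.warn(f"zero-variance channel(s) {flat}; sd floored at {sd_floor}")
        stats = ChannelStats(mean=mean, sd=np.maximum(sd, sd_floor))
    if stats.mean.shape != (es.epochs.shape[1],):
        raise ValueError(
            f"stats for {stats.mean.shape[0]} channels cannot standardize "
            f"{es.epochs.shape[1]}-channel epochs"
        )
    z = (es.epochs - stats.mean[None, :, None]) / stats.sd[None, :, None]
    out = replace(es, epochs=z)
    return out, stats


def preprocess_recordings(recordings: list[Recording], *, order: int = 6,
                          low_hz: float = 4.0, high_hz: float = 45.0,
                          epoch_seconds: float = 4.0) -> EpochSet:
    """Full pipeline: montage canonicalization, band-pass, epoching.

    Standardization is deliberately left out here: its statistics must come
    from training data only, so it is applied after the subject split.
    """
    if not recordings:
        raise ValueError("no recordings given")
    spec = design_bandpass(order, low_hz, high_hz, recordings[0].fs)
    sets = []
    for rec in recordings:
        rec = reorder_channels(rec)
        rec = apply_filter(rec, spec)
        sets.append(segment(rec, epoch_seconds))
    return concatenate_epochs(sets)
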