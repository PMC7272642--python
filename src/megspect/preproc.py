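"""Artifact rejection, epoching and zero-phase band-pass filtering.

Raw sensor recordings (tesla) are cleaned by excising fixed-length blocks
that contain large-amplitude artifacts, cut into non-overlapping epochs,
and band-limited with a zero-phase Butterworth filter.  The block length
of the rejection equals the epoch length so that rejection and epoching
commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .atlas import BAND_EDGES_HZ

#: Peak-amplitude rejection threshold: 10 pT.
DEFAULT_ARTIFACT_THRESHOLD_T = 10e-12
DEFAULT_EPOCH_LENGTH_S = 2.0


class NoUsableDataError(RuntimeError):
    """Raised when artifact rejection removes every block of a recording."""


@dataclass
class RawRecording:
    """Multichannel sensor time series for one subject x condition.

    ``values`` is a (channels x samples) float array in tesla.
    """

    values: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("recording values must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")


def default_bands() -> tuple[BandSpec, ...]:
    """The five analysis bands (theta1, theta2, alpha1, alpha2, beta)."""
    return tuple(BandSpec(name, lo, hi) for name, (lo, hi) in BAND_EDGES_HZ.items())


@dataclass
class RejectionReport:
    """Which fixed-length blocks were excised and how much data remains."""

    removed_blocks: list[int]
    n_blocks: int
    retained_duration: float
    threshold: float


@dataclass
class EpochSet:
    """Non-overlapping, temporally ordered epochs of a recording.

    ``epochs`` has shape (n_epochs x channels x samples_per_epoch).
    ``retained_indices`` records the position of each epoch in the cleaned
    recording for provenance.
    """

    epochs: np.ndarray
    sampling_rate: float
    epoch_length: float
    band: BandSpec | None = None
    retained_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        expected = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples_per_epoch {self.epochs.shape[2]} != "
                f"epoch_length*sampling_rate {expected}"
            )
        if len(self.retained_indices) == 0:
            self.retained_indices = np.arange(self.epochs.shape[0])

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def reject_artifacts(
    rec: RawRecording,
    threshold: float = DEFAULT_ARTIFACT_THRESHOLD_T,
    block_length: float = DEFAULT_EPOCH_LENGTH_S,
) -> tuple[RawRecording, RejectionReport]:
    """Excise fixed-length blocks containing samples above ``threshold``.

    The recording is scanned in consecutive ``block_length``-second blocks
    aligned to t=0 (the trailing partial block included); any block in which
    any channel exceeds the threshold in absolute value is removed, and the
    remaining blocks are concatenated.  Raises :class:`NoUsableDataError`
    if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    block_samples = int(round(block_length * rec.sampling_rate))
    n_blocks = int(np.ceil(rec.n_samples / block_samples))
    keep: list[np.ndarray] = []
    removed: list[int] = []
    for b in range(n_blocks):
        sl = rec.values[:, b * block_samples : (b + 1) * block_samples]
        if np.any(np.abs(sl) > threshold):
            removed.append(b)
        else:
            keep.append(sl)
    if not keep:
        raise NoUsableDataError(
            f"all {n_blocks} blocks exceed {threshold:g} T "
            f"(subject={rec.subject_id!r}, condition={rec.condition!r})"
        )
    cleaned = replace(rec, values=np.concatenate(keep, axis=1))
    report = RejectionReport(
        removed_blocks=removed,
        n_blocks=n_blocks,
        retained_duration=cleaned.duration,
        threshold=threshold,
    )
    return cleaned, report


def segment_epochs(
    rec: RawRecording, epoch_length: float = DEFAULT_EPOCH_LENGTH_S
) -> EpochSet:
    """Cut a recording into floor(duration/epoch_length) consecutive epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    samples_per_epoch = int(round(epoch_length * rec.sampling_rate))
    if abs(samples_per_epoch - epoch_length * rec.sampling_rate) > 1e-9:
        raise ValueError("epoch_length * sampling_rate must be integral")
    if rec.n_samples < samples_per_epoch:
        raise ValueError(
            f"recording ({rec.duration:g} s) shorter than one epoch "
            f"({epoch_length:g} s)"
        )
    n_epochs = rec.n_samples // samples_per_epoch
    used = rec.values[:, : n_epochs * samples_per_epoch]
    epochs = used.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    epochs = np.ascontiguousarray(np.moveaxis(epochs, 1, 0))
    return EpochSet(
        epochs=epochs,
        sampling_rate=rec.sampling_rate,
        epoch_length=epoch_length,
        subject_id=rec.subject_id,
        condition=rec.condition,
    )


def _butter_sos(band: BandSpec, sampling_rate: float) -> np.ndarray:
    if band.high >= sampling_rate / 2:
        raise ValueError(
            f"band edge {band.high} Hz not below Nyquist "
            f"({sampling_rate / 2:g} Hz)"
        )
    return signal.butter(
        4, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos"
    )


def _filtfilt(x: np.ndarray, sos: np.ndarray, sampling_rate: float) -> np.ndarray:
    # Reflection padding of up to 1 s to suppress filter edge transients.
    padlen = min(int(sampling_rate), x.shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def bandpass_filter(
    x: RawRecording | EpochSet, band: BandSpec
) -> RawRecording | EpochSet:
    """Zero-phase 4th-order Butterworth band-pass; output shape = input shape.

    Applied forward-backward so the pass band carries no phase distortion.
    Accepts a recording or an epoch set and returns the same kind.
    """
    sos = _butter_sos(band, x.sampling_rate)
    if isinstance(x, RawRecording):
        return replace(x, values=_filtfilt(x.values, sos, x.sampling_rate))
    if isinstance(x, EpochSet):
        out = replace(x, epochs=_filtfilt(x.epochs, sos, x.sampling_rate))
        out.band = band
        return out
    raise TypeError(f"expected RawRecording or EpochSet, got {type(x).__name__}")


def bandpass_array(
    values: np.ndarray, band: BandSpec, sampling_rate: float
) -> np.ndarray:
    """Band-pass a plain array along its last axis (same filter dialect)."""
    return _filtfilt(np.asarray(values, float), _butter_sos(band, sampling_rate),
                     sampling_rate)


def zero_phase_band_response(
    band: BandSpec, sampling_rate: float, n_samples: int
) -> np.ndarray:
    """|H(f)|^2 of the band filter on the rFFT grid of ``n_samples``.

    The squared magnitude response is exactly what the forward-backward
    (zero-phase) application of the filter realizes, so spectral shaping
    with this curve uses the same band edges and roll-off as
    :func:`bandpass_filter`.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    _, h = signal.sosfreqz(_butter_sos(band, sampling_rate), worN=freqs,
                           fs=sampling_rate)
    return np.abs(h) ** 2
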