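"""Raw referential EEG -> filtered, resampled, bipolar, overlapping epochs.

The preterm-EEG analysis chain operates on a fixed double-banana-style
bipolar montage derived from nine scalp electrodes recorded referentially
against Cz.  All downstream burst detection and feature extraction assume
band-passed (0.5-32 Hz), 64 Hz data, so the functions here are the single
point where sampling rate and bandwidth are normalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

#: Electrodes required for the fixed bipolar montage (all referential to Cz).
ELECTRODES = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2")

#: Bipolar derivations in canonical order (minuend, subtrahend).
BIPOLAR_PAIRS = (
    ("Fp1", "C3"),
    ("C3", "O1"),
    ("Fp1", "T3"),
    ("T3", "O1"),
    ("Fp2", "C4"),
    ("C4", "O2"),
    ("Fp2", "T4"),
    ("T4", "O2"),
)

BIPOLAR_LABELS = tuple(f"{a}-{b}" for a, b in BIPOLAR_PAIRS)

#: Target sampling rate (Hz) for all feature extraction.
TARGET_FS = 64.0


class InvalidSamplingRateError(ValueError):
    """Sampling rate incompatible with the requested operation."""


class InvalidSignalError(ValueError):
    """Signal contains non-finite samples."""


class MissingChannelError(KeyError):
    """A required electrode is absent from the recording."""


class RecordingTooShortError(ValueError):
    """Recording shorter than one analysis epoch."""


def normalize_electrode_label(label: str) -> str:
    """Map an EDF channel label onto a bare electrode name.

    Strips an optional ``EEG `` prefix and a reference suffix
    (``Fp1-Cz`` / ``Fp1-REF`` -> ``Fp1``); matching is case-insensitive.
    """
    name = label.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    for suffix in ("-CZ", "-REF", "-AVG"):
        if name.upper().endswith(suffix):
            name = name[: -len(suffix)]
    name = name.strip()
    canonical = {e.upper(): e for e in ELECTRODES}
    canonical["CZ"] = "Cz"
    return canonical.get(name.upper(), name)


@dataclass
class RecordingSet:
    """A referential multichannel EEG recording with cohort metadata.

    ``signal`` is a (n_channels, n_samples) array in microvolts, referenced
    to Cz; ``channels`` gives the electrode label for each row.  The infant
    identifier is the unit of cross-validation grouping downstream.
    """

    infant_id: str
    recording_id: str
    pma_days: int
    channels: list[str]
    fs_native: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.fs_native <= TARGET_FS:
            raise InvalidSamplingRateError(
                f"native rate {self.fs_native} Hz must exceed {TARGET_FS} Hz"
            )
        if not (150 <= self.pma_days <= 290):
            warnings.warn(
                f"pma_days={self.pma_days} outside the realistic cohort range "
                "[150, 290]",
                stacklevel=2,
            )
        missing = [e for e in ELECTRODES if e not in self.channels]
        if missing:
            raise MissingChannelError(
                f"recording {self.recording_id} lacks electrodes {missing}"
            )

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs_native

    def get(self, electrode: str) -> np.ndarray:
        return self.signal[self.channels.index(electrode)]


@dataclass
class BipolarEpoch:
    """One analysis epoch: 8 bipolar channels at 64 Hz.

    ``ref_data``/``ref_channels`` retain the referential signals over the
    same window; the low-amplitude artefact rule needs them.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    start_offset_s: float
    recording_id: str
    infant_id: str
    pma_days: int
    ref_channels: list[str] = field(default_factory=list)
    ref_data: np.ndarray | None = None
    epoch_index: int = 0

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    f_low: float = 0.5,
    f_high: float = 32.0,
    order: int = 8,
) -> np.ndarray:
    """Zero-phase band-pass filter (default 0.5-32 Hz).

    A Butterworth filter applied forward-backward (``sosfiltfilt``) so that
    burst onset/offset timestamps are not delayed by the filter group delay.
    The default order keeps passband droop below 5% out to 25 Hz while
    attenuating 0.1 Hz drift and 45 Hz interference by well over 20 dB.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * f_high:
        raise InvalidSamplingRateError(
            f"fs={fs} Hz must exceed twice the high cut-off {f_high} Hz"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains non-finite samples")
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def resample_to_64(x: np.ndarray, fs_native: float) -> tuple[np.ndarray, float]:
    """Polyphase resampling to 64 Hz; band limiting assumed already applied."""
    x = np.asarray(x, dtype=float)
    if fs_native < TARGET_FS:
        raise InvalidSamplingRateError(
            f"upsampling from {fs_native} Hz to {TARGET_FS} Hz not supported"
        )
    if fs_native == TARGET_FS:
        return x.copy(), TARGET_FS
    ratio = Fraction(TARGET_FS / fs_native).limit_denominator(10000)
    y = sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)
    return y, TARGET_FS


def bipolar_from_arrays(
    signal: np.ndarray, channels: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Referential (n_channels, n_samples) array -> 8-channel bipolar signal."""
    missing = sorted({e for pair in BIPOLAR_PAIRS for e in pair if e not in channels})
    if missing:
        raise MissingChannelError(f"missing electrodes {missing}")
    idx = {c: i for i, c in enumerate(channels)}
    data = np.stack([signal[idx[a]] - signal[idx[b]] for a, b in BIPOLAR_PAIRS])
    return data, list(BIPOLAR_LABELS)


def to_bipolar(rec: RecordingSet) -> tuple[np.ndarray, list[str]]:
    """Referential recording -> 8-channel bipolar signal in canonical order."""
    return bipolar_from_arrays(rec.signal, rec.channels)


def epoch_offsets(duration_s: float, epoch_len_s: float, step_s: float) -> np.ndarray:
    """Start offsets of fully contained epochs (75% overlap by default)."""
    if duration_s < epoch_len_s:
        raise RecordingTooShortError(
            f"duration {duration_s:.0f} s < epoch length {epoch_len_s:.0f} s"
        )
    n = int(np.floor((duration_s - epoch_len_s) / step_s)) + 1
    return np.arange(n) * step_s


def segment_epochs(
    bipolar: np.ndarray,
    fs: float,
    *,
    recording_id: str,
    infant_id: str,
    pma_days: int,
    channel_labels: list[str] | None = None,
    ref_data: np.ndarray | None = None,
    ref_channels: list[str] | None = None,
    epoch_len_s: float = 3600.0,
    step_s: float | None = None,
) -> list[BipolarEpoch]:
    """Cut the bipolar signal into overlapping epochs (default 1 h, 75%).

    Trailing partial epochs are dropped: every feature assumes a full epoch
    of context.  Raises :class:`RecordingTooShortError` when not even one
    epoch fits.
    """
    if step_s is None:
        step_s = epoch_len_s / 4.0
    duration_s = bipolar.shape[1] / fs
    offsets = epoch_offsets(duration_s, epoch_len_s, step_s)
    n_epoch = int(round(epoch_len_s * fs))
    labels = list(channel_labels) if channel_labels else list(BIPOLAR_LABELS)
    epochs = []
    for idx, off in enumerate(offsets):
        i0 = int(round(off * fs))
        sl = slice(i0, i0 + n_epoch)
        epochs.append(
            BipolarEpoch(
                channel_labels=labels,
                fs=fs,
                data=bipolar[:, sl],
                start_offset_s=float(off),
                recording_id=recording_id,
                infant_id=infant_id,
                pma_days=pma_days,
                ref_channels=list(ref_channels) if ref_channels else [],
                ref_data=ref_data[:, sl] if ref_data is not None else None,
                epoch_index=idx,
            )
        )
    return epochs


def preprocess_recording(
    rec: RecordingSet,
    epoch_len_s: float = 3600.0,
    step_s: float | None = None,
) -> list[BipolarEpoch]:
    """Full preprocessing chain: filter -> resample -> montage -> epochs.

    Filtering is applied to the referential channels before montage
    construction; both operations are linear so the order does not change
    the bipolar result, but filtering first lets the referential artefact
    rule see the same bandwidth as the bipolar channels.
    """
    filtered = bandpass_filter(rec.signal, rec.fs_native)
    resampled, fs = resample_to_64(filtered, rec.fs_native)
    ref_channels = list(rec.channels)
    bipolar, labels = bipolar_from_arrays(resampled, ref_channels)
    return segment_epochs(
        bipolar,
        fs,
        recording_id=rec.recording_id,
        infant_id=rec.infant_id,
        pma_days=rec.pma_days,
        channel_labels=labels,
        ref_data=resampled,
        ref_channels=ref_channels,
        epoch_len_s=epoch_len_s,
        step_s=step_s,
    )
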