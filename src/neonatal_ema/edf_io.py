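"""EDF input/output.

Reading goes through :mod:`mne` (``read_raw_edf``), with electrode labels
normalised to bare names (``EEG Fp1-Cz`` -> ``Fp1``) and amplitudes
converted to µV.  Writing uses a small built-in EDF writer (16-bit,
one-second data records) sufficient for the synthetic cohorts produced by
:mod:`neonatal_ema.synthetic`; round-trips are covered by tests against
the mne reader.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .preprocessing import RecordingSet, normalize_electrode_label

__all__ = ["write_edf", "read_edf_signals", "read_recording"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    fs: float,
    channel_labels: list[str],
    patient_id: str = "X",
    recording_note: str = "Startdate X",
    phys_range_uv: float = 1000.0,
) -> None:
    """Write a referential EEG array (µV) to an EDF file.

    ``fs`` must be a whole number of samples per second (one-second data
    records are used).  Samples are clipped to ``±phys_range_uv`` and
    quantised to 16 bits (~0.03 µV resolution at the default range).
    """
    signal = np.asarray(signal, dtype=float)
    ns, n_samples = signal.shape
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = n_samples // spr
    if n_records < 1:
        raise ValueError("signal shorter than one EDF data record")

    dig_min, dig_max = -32768, 32767
    pmin, pmax = -phys_range_uv, phys_range_uv
    scale = (dig_max - dig_min) / (pmax - pmin)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(recording_note, 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    header += b"".join(_pad(f"EEG {c}-Cz", 16) for c in channel_labels)
    header += b"".join(_pad("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{pmin:g}", 8) for _ in range(ns))
    header += b"".join(_pad(f"{pmax:g}", 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_pad("HP:0Hz LP:128Hz", 80) for _ in range(ns))
    header += b"".join(_pad(str(spr), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    clipped = np.clip(signal[:, : n_records * spr], pmin, pmax)
    digital = np.round((clipped - pmin) * scale + dig_min).astype("<i2")
    # record-major layout: for each record, all channels' samples in sequence
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())


def read_edf_signals(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file: (signal in µV, normalised labels, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [normalize_electrode_label(c) for c in raw.ch_names]
    data = raw.get_data(units="uV")
    return data, labels, float(raw.info["sfreq"])


def read_recording(
    path: str | Path,
    infant_id: str,
    recording_id: str,
    pma_days: int,
) -> RecordingSet:
    """Read an EDF file into a :class:`RecordingSet` with cohort metadata."""
    data, labels, fs = read_edf_signals(path)
    return RecordingSet(
        infant_id=infant_id,
        recording_id=recording_id,
        pma_days=pma_days,
        channels=labels,
        fs_native=fs,
        signal=data,
    )
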