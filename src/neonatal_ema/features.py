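"""Maturational EEG features: 23 per analysis segment, 46 per epoch.

Each accepted epoch is summarised twice — over the full epoch and over its
low-SAT% (quiet-sleep proxy) segment — by the same 23 features:

* amplitude: envelope percentiles (p50, p95); range-EEG (rEEG) percentiles
  (p5, p50, p95) of per-window peak-to-peak amplitude;
* spectral: absolute and relative band powers (delta 0-3, theta 3-8,
  alpha 8-15, beta 15-30 Hz) plus total 0-30 Hz power;
* SAT timing: SATs per hour, SAT-duration percentiles (p5, p50, p95),
  inter-SAT-interval percentiles (p5, p50, p95) and RMS;
* spatial: activation synchrony index (interhemispheric burst coincidence).

Amplitude and spectral features are estimated per bipolar channel and the
median across non-excluded channels is used; SAT-timing features come from
the per-epoch consensus annotation and the synchrony index from homologous
channel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sat_detection import mask_to_intervals, restrict_intervals

#: Frequency bands in Hz (half-open [lo, hi)).
BANDS = {
    "delta": (0.0, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}

#: Homologous left/right derivations for the activation synchrony index.
ASI_PAIRS = (
    ("Fp1-T3", "Fp2-T4"),
    ("T3-O1", "T4-O2"),
    ("Fp1-C3", "Fp2-C4"),
    ("C3-O1", "C4-O2"),
)

#: Canonical 23-feature roster (per analysis segment).
FEATURE_NAMES = (
    "env_p50",
    "env_p95",
    "reeg_p5",
    "reeg_p50",
    "reeg_p95",
    "power_total",
    "power_delta",
    "power_theta",
    "power_alpha",
    "power_beta",
    "rel_delta",
    "rel_theta",
    "rel_alpha",
    "rel_beta",
    "sats_per_hour",
    "sat_dur_p5",
    "sat_dur_p50",
    "sat_dur_p95",
    "isi_p5",
    "isi_p50",
    "isi_p95",
    "isi_rms",
    "asi",
)

SEGMENTS = ("full", "lowsat")

#: The 46 feature-vector column names.
FEATURE_COLUMNS = tuple(f"{n}_{seg}" for seg in SEGMENTS for n in FEATURE_NAMES)


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic associate of the EEG."""
    x = np.asarray(x, dtype=float)
    return np.abs(sps.hilbert(x, axis=-1))


def reeg(x: np.ndarray, fs: float = 64.0, win_s: float = 2.0) -> np.ndarray:
    """Range-EEG: peak-to-peak amplitude per non-overlapping window (µV)."""
    x = np.asarray(x, dtype=float)
    w = int(round(win_s * fs))
    if x.shape[-1] < w:
        raise ValueError("signal shorter than one rEEG window")
    n_win = x.shape[-1] // w
    xr = x[..., : n_win * w].reshape(*x.shape[:-1], n_win, w)
    return xr.max(axis=-1) - xr.min(axis=-1)


def band_powers(x: np.ndarray, fs: float = 64.0) -> dict[str, float]:
    """Welch band powers (µV²) over delta/theta/alpha/beta plus total.

    2 s Hamming segments with 50% overlap; the total is the sum of the
    four band powers (the bands partition 0-30 Hz), so the relative
    powers sum to one exactly.  A zero signal yields total 0 and NaN
    relative powers (flagged missing upstream).
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(2 * fs)), x.shape[-1])
    f, psd = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )
    df = f[1] - f[0] if f.size > 1 else 1.0
    out: dict[str, float] = {}
    total = 0.0
    for name, (lo, hi) in BANDS.items():
        sel = (f >= lo) & (f < hi)
        p = float(np.sum(psd[sel]) * df)
        out[f"power_{name}"] = p
        total += p
    out["power_total"] = total
    for name in BANDS:
        out[f"rel_{name}"] = out[f"power_{name}"] / total if total > 0 else np.nan
    return out


def sat_stats(
    interval_blocks: list[np.ndarray] | np.ndarray,
    duration_s: float,
) -> dict[str, float]:
    """SAT timing statistics from a consensus annotation.

    ``interval_blocks`` is either one interval array (full epoch) or the
    per-block clipped arrays from :func:`restrict_intervals`; inter-SAT
    intervals (ISIs) are the offset->next-onset gaps within a block.
    ``duration_s`` is the total analysed duration; the SAT rate is
    normalised to events per hour.  With fewer than two SATs the ISI
    statistics are NaN (imputed at model time).
    """
    if isinstance(interval_blocks, np.ndarray):
        interval_blocks = [interval_blocks]
    durations = []
    isis = []
    count = 0
    for block in interval_blocks:
        if len(block) == 0:
            continue
        count += len(block)
        durations.append(block[:, 1] - block[:, 0])
        if len(block) > 1:
            isis.append(block[1:, 0] - block[:-1, 1])
    out = {"sats_per_hour": count * 3600.0 / duration_s if duration_s > 0 else np.nan}
    if durations:
        d = np.concatenate(durations)
        out["sat_dur_p5"], out["sat_dur_p50"], out["sat_dur_p95"] = np.percentile(
            d, [5, 50, 95]
        )
    else:
        out["sat_dur_p5"] = out["sat_dur_p50"] = out["sat_dur_p95"] = np.nan
    if isis:
        g = np.concatenate(isis)
        out["isi_p5"], out["isi_p50"], out["isi_p95"] = np.percentile(g, [5, 50, 95])
        out["isi_rms"] = float(np.sqrt(np.mean(g**2)))
    else:
        out["isi_p5"] = out["isi_p50"] = out["isi_p95"] = out["isi_rms"] = np.nan
    return out


def activation_synchrony_index(
    per_channel_intervals: dict[str, np.ndarray],
    epoch_len_s: float,
    second_mask: np.ndarray | None = None,
    excluded: set[str] | frozenset[str] = frozenset(),
    pairs: tuple[tuple[str, str], ...] = ASI_PAIRS,
) -> float:
    """Interhemispheric activation synchrony index (ASI).

    Burst activity on each derivation is binarised at 1 s resolution (a
    second counts as active when at least half of it lies inside a SAT).
    For each homologous left/right pair the coincidence ratio
    ``CR = P(both active) / (P(left) * P(right))`` is computed from the
    empirical per-second fractions; CR is 1 under independence, > 1 for
    synchronous activation.  The ASI is the median CR over valid pairs;
    pairs with a zero marginal are dropped, and the result is NaN when no
    pair is valid.
    """
    n_sec = int(round(epoch_len_s))
    sec_edges = np.arange(n_sec + 1, dtype=float)

    def binarize(intervals: np.ndarray) -> np.ndarray:
        cov = np.zeros(n_sec)
        for on, off in np.atleast_2d(intervals) if len(intervals) else []:
            lo = np.clip(sec_edges[:-1], on, off)
            hi = np.clip(sec_edges[1:], on, off)
            cov += hi - lo
        return cov >= 0.5

    crs = []
    for left, right in pairs:
        if (
            left in excluded
            or right in excluded
            or left not in per_channel_intervals
            or right not in per_channel_intervals
        ):
            continue
        a = binarize(per_channel_intervals[left])
        b = binarize(per_channel_intervals[right])
        if second_mask is not None:
            a = a[second_mask]
            b = b[second_mask]
        if a.size == 0:
            continue
        pa = a.mean()
        pb = b.mean()
        if pa == 0 or pb == 0:
            continue
        crs.append(float(np.mean(a & b) / (pa * pb)))
    return float(np.median(crs)) if crs else float("nan")


@dataclass
class SegmentFeatures:
    """23 named feature values for one analysis segment."""

    values: dict[str, float]


def _segment_sample_mask(
    second_mask: np.ndarray | None, n_samples: int, fs: float
) -> np.ndarray:
    if second_mask is None:
        return np.ones(n_samples, dtype=bool)
    idx = np.minimum((np.arange(n_samples) / fs).astype(int), second_mask.size - 1)
    return second_mask[idx]


def _channel_median(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(np.median(arr)) if arr.size else float("nan")


def segment_features(
    data: np.ndarray,
    channel_labels: list[str],
    fs: float,
    consensus: np.ndarray,
    per_channel_intervals: dict[str, np.ndarray],
    second_mask: np.ndarray | None,
    epoch_len_s: float,
    excluded: set[str] | frozenset[str] = frozenset(),
    env: np.ndarray | None = None,
) -> dict[str, float]:
    """Compute the 23-feature set on one segment (full epoch or low-SAT)."""
    n = data.shape[1]
    smask = _segment_sample_mask(second_mask, n, fs)
    if env is None:
        env = envelope(data)
    valid = [i for i, c in enumerate(channel_labels) if c not in excluded]

    env_p50, env_p95 = [], []
    reeg_p5, reeg_p50, reeg_p95 = [], [], []
    bp_rows: list[dict[str, float]] = []
    win = int(round(2.0 * fs))
    n_win = n // win
    if second_mask is None:
        win_keep = np.ones(n_win, dtype=bool)
    else:
        centers = ((np.arange(n_win) + 0.5) * win / fs).astype(int)
        win_keep = second_mask[np.minimum(centers, second_mask.size - 1)]
    for i in valid:
        e = env[i][smask]
        env_p50.append(np.percentile(e, 50))
        env_p95.append(np.percentile(e, 95))
        r = reeg(data[i], fs=fs)[win_keep]
        if r.size:
            p5, p50, p95 = np.percentile(r, [5, 50, 95])
        else:
            p5 = p50 = p95 = np.nan
        reeg_p5.append(p5)
        reeg_p50.append(p50)
        reeg_p95.append(p95)
        bp_rows.append(band_powers(data[i][smask], fs=fs))

    out: dict[str, float] = {
        "env_p50": _channel_median(env_p50),
        "env_p95": _channel_median(env_p95),
        "reeg_p5": _channel_median(reeg_p5),
        "reeg_p50": _channel_median(reeg_p50),
        "reeg_p95": _channel_median(reeg_p95),
    }
    for key in ("power_total", "power_delta", "power_theta", "power_alpha",
                "power_beta", "rel_delta", "rel_theta", "rel_alpha", "rel_beta"):
        out[key] = _channel_median([row[key] for row in bp_rows])
    # the cross-channel median breaks the unit sum of the relative powers
    # (the median is not linear); renormalise so they remain a composition
    rel_sum = sum(out[f"rel_{b}"] for b in BANDS)
    if np.isfinite(rel_sum) and rel_sum > 0:
        for b in BANDS:
            out[f"rel_{b}"] /= rel_sum

    if second_mask is None:
        blocks: np.ndarray | list[np.ndarray] = consensus
        duration = epoch_len_s
    else:
        block_spans = mask_to_intervals(second_mask, fs=1.0)
        blocks = restrict_intervals(consensus, block_spans)
        duration = float(second_mask.sum())
    out.update(sat_stats(blocks, duration))
    out["asi"] = activation_synchrony_index(
        per_channel_intervals,
        epoch_len_s,
        second_mask=second_mask,
        excluded=excluded,
    )
    return out


def extract_features(
    epoch,
    annotation,
    low_sat_mask: np.ndarray,
    artefact_report=None,
) -> dict[str, float]:
    """Full 46-feature vector for one accepted epoch, with provenance.

    Amplitude and spectral features are per-channel medians over the
    non-excluded bipolar channels; SAT-timing features use the consensus
    annotation restricted to each segment.  Missing values (e.g. too few
    SATs in the low-SAT segment) are left NaN and imputed with
    training-fold medians at model time.
    """
    excluded = frozenset(artefact_report.excluded) if artefact_report else frozenset()
    env = envelope(epoch.data)
    row: dict[str, float] = {}
    for seg, mask in (("full", None), ("lowsat", low_sat_mask)):
        vals = segment_features(
            epoch.data,
            epoch.channel_labels,
            epoch.fs,
            annotation.consensus,
            annotation.channels,
            mask,
            epoch.duration_s,
            excluded=excluded,
            env=env,
        )
        row.update({f"{k}_{seg}": v for k, v in vals.items()})
    row.update(
        infant_id=epoch.infant_id,
        recording_id=epoch.recording_id,
        epoch_index=epoch.epoch_index,
        pma_days=epoch.pma_days,
        n_valid_channels=len(epoch.channel_labels) - len(excluded),
    )
    return row
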