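"""Synthetic preterm-EEG cohorts with age-dependent burst statistics.

Real neonatal cohort EEG cannot be redistributed, so every stage of the
pipeline is exercised on simulated recordings with known ground truth.
The generator emulates the statistical fingerprint of maturation that the
estimator exploits, not the visual morphology of preterm EEG:

* discontinuity — piecewise alternation of high-amplitude bursts (SATs)
  and low-amplitude inter-SAT periods, with the mean inter-SAT interval
  shrinking from ~30 s at 24 weeks post-menstrual age to ~6 s at 38 weeks;
* amplitude growth — burst envelope scale rising from 50 to 120 µV and
  the inter-burst floor from 5 to 25 µV over the same age range;
* spectral maturation — band-weighted noise, delta-dominant at all ages
  with a beta weight that rises with age;
* interhemispheric synchrony — homologous channels share burst onsets
  with an age-increasing probability;
* sleep cycling — a two-state slow modulation of the burst rate so that a
  low-SAT% (quiet-sleep proxy) segment exists in every epoch;
* artefacts — injectable >500 µV excursions inside SATs and near-flat
  electrodes, with labels, to exercise the artefact rules.

All randomness flows from a single seed through ``numpy`` generators, so
cohorts are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import ELECTRODES, RecordingSet

__all__ = ["CohortConfig", "EpochTruth", "generate_epoch", "generate_recording",
           "generate_cohort", "inject_artefacts"]

LEFT = ("Fp1", "C3", "T3", "O1")
RIGHT = ("Fp2", "C4", "T4", "O2")


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    Age-dependent parameters are given as (value at ``pma_min_days``,
    value at ``pma_max_days``) pairs, interpolated linearly in PMA
    (log-linearly for the inter-SAT interval).  Defaults describe a
    30-infant serial-recording cohort spanning 24-38 weeks PMA.
    """

    n_infants: int = 30
    recordings_per_infant: tuple[int, int] = (2, 4)
    pma_min_days: int = 168
    pma_max_days: int = 266
    recording_spacing_days: tuple[int, int] = (28, 35)
    duration_s: float = 3600.0
    fs: float = 256.0

    isi_mean_s: tuple[float, float] = (30.0, 6.0)
    isi_shape: float = 3.0
    isi_min_s: float = 1.5
    sat_dur_median_s: float = 4.0
    sat_dur_sigma: float = 0.35
    sat_dur_range_s: tuple[float, float] = (1.5, 15.0)
    burst_amp_uv: tuple[float, float] = (50.0, 120.0)
    floor_amp_uv: tuple[float, float] = (5.0, 25.0)
    sync_prob: tuple[float, float] = (0.4, 0.9)
    #: band weights (delta, theta, alpha, beta) at the two age anchors
    band_weights_young: tuple[float, float, float, float] = (0.70, 0.20, 0.07, 0.03)
    band_weights_old: tuple[float, float, float, float] = (0.50, 0.25, 0.15, 0.10)
    #: two-state sleep cycling: quiet periods multiply the mean ISI
    quiet_isi_factor: float = 2.0
    quiet_frac_range: tuple[float, float] = (0.15, 0.25)
    active_frac_range: tuple[float, float] = (0.25, 0.40)

    #: biological variability: the EEG of an infant reflects a functional
    #: age that deviates from the chart PMA by a stable per-infant offset
    #: (differing maturational tempo, uncertain conception date) plus a
    #: per-recording state jitter
    infant_age_sd_days: float = 7.0
    recording_age_jitter_sd_days: float = 3.0

    #: artefact injection rates (per recording)
    high_amp_rate: float = 0.0
    flat_channel_rate: float = 0.0
    high_amp_voltage_uv: float = 650.0
    flat_scale: float = 0.05
    seed: int = 0

    def _age_frac(self, pma_days: float) -> float:
        lo, hi = self.pma_min_days, self.pma_max_days
        return float(np.clip((pma_days - lo) / (hi - lo), 0.0, 1.0))

    def isi_mean(self, pma_days: float) -> float:
        a = self._age_frac(pma_days)
        lo, hi = self.isi_mean_s
        return float(np.exp((1 - a) * np.log(lo) + a * np.log(hi)))

    def burst_amp(self, pma_days: float) -> float:
        a = self._age_frac(pma_days)
        return self.burst_amp_uv[0] + a * (self.burst_amp_uv[1] - self.burst_amp_uv[0])

    def floor_amp(self, pma_days: float) -> float:
        a = self._age_frac(pma_days)
        return self.floor_amp_uv[0] + a * (self.floor_amp_uv[1] - self.floor_amp_uv[0])

    def synchrony(self, pma_days: float) -> float:
        a = self._age_frac(pma_days)
        return self.sync_prob[0] + a * (self.sync_prob[1] - self.sync_prob[0])

    def band_weights(self, pma_days: float) -> np.ndarray:
        a = self._age_frac(pma_days)
        w = (1 - a) * np.asarray(self.band_weights_young) + a * np.asarray(
            self.band_weights_old
        )
        return w / w.sum()


@dataclass
class EpochTruth:
    """Ground truth emitted with every generated recording."""

    events_left: np.ndarray
    events_right: np.ndarray
    state_spans: list[tuple[float, float, str]]
    isi_mean_s: float
    burst_amp_uv: float
    floor_amp_uv: float
    artefact_high_amp: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=float)
    )
    artefact_flat_channels: list[str] = field(default_factory=list)

    @property
    def events_union(self) -> np.ndarray:
        """Union of left/right schedules (what a consensus detector sees)."""
        ev = np.vstack([self.events_left, self.events_right])
        if len(ev) == 0:
            return ev
        ev = ev[np.argsort(ev[:, 0])]
        merged = [list(ev[0])]
        for on, off in ev[1:]:
            if on <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], off)
            else:
                merged.append([on, off])
        return np.asarray(merged)


def _state_schedule(
    duration_s: float, config: CohortConfig, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Alternating active/quiet spans covering the recording."""
    spans = []
    t = 0.0
    state = "active"
    while t < duration_s:
        if state == "active":
            frac = rng.uniform(*config.active_frac_range)
        else:
            frac = rng.uniform(*config.quiet_frac_range)
        t1 = min(duration_s, t + frac * duration_s)
        spans.append((t, t1, state))
        t = t1
        state = "quiet" if state == "active" else "active"
    return spans


def _state_factor(t: float, spans: list[tuple[float, float, str]], factor: float) -> float:
    for t0, t1, state in spans:
        if t0 <= t < t1:
            return factor if state == "quiet" else 1.0
    return 1.0


def _burst_schedule(
    duration_s: float,
    isi_mean: float,
    config: CohortConfig,
    spans: list[tuple[float, float, str]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential [onset, offset) burst events with state-modulated gaps."""
    events = []
    t = 0.0
    while True:
        mu = isi_mean * _state_factor(t, spans, config.quiet_isi_factor)
        gap = max(
            config.isi_min_s,
            rng.gamma(config.isi_shape, mu / config.isi_shape),
        )
        dur = float(
            np.clip(
                np.exp(rng.normal(np.log(config.sat_dur_median_s), config.sat_dur_sigma)),
                *config.sat_dur_range_s,
            )
        )
        on = t + gap
        off = on + dur
        if off >= duration_s:
            break
        events.append([on, off])
        t = off
    return np.asarray(events, dtype=float) if events else np.empty((0, 2))


def _desynchronise(
    events: np.ndarray,
    rho: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Right-hemisphere schedule: copy each event with probability rho.

    Synchronous copies get a small (±0.25 s) jitter; asynchronous events
    keep their duration but are displaced by up to half the local gap, so
    the two hemispheres share the event rate but not the timing.
    """
    out = []
    for i, (on, off) in enumerate(events):
        dur = off - on
        if rng.random() < rho:
            shift = rng.uniform(-0.25, 0.25)
        else:
            prev_off = events[i - 1, 1] if i > 0 else 0.0
            next_on = events[i + 1, 0] if i + 1 < len(events) else duration_s
            room = max(0.5, min(on - prev_off, next_on - off) * 0.9)
            shift = rng.uniform(-room, room)
        on2 = float(np.clip(on + shift, 0.0, duration_s - dur))
        out.append([on2, on2 + dur])
    if not out:
        return np.empty((0, 2))
    arr = np.asarray(sorted(out), dtype=float)
    # enforce disjointness after shifting
    merged = [list(arr[0])]
    for on, off in arr[1:]:
        if on < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])
    return np.asarray(merged)


def _band_noise(
    n: int, fs: float, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise with the requested delta..beta power weights."""
    edges = [(0.3, 3.0), (3.0, 8.0), (8.0, 15.0), (15.0, 30.0)]
    out = np.zeros(n)
    for w, (lo, hi) in zip(weights, edges):
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        comp = sps.sosfilt(sos, rng.standard_normal(n))
        sd = comp.std()
        if sd > 0:
            out += np.sqrt(w) * comp / sd
    sd = out.std()
    return out / sd if sd > 0 else out


def _envelope_from_events(
    events: np.ndarray, n: int, fs: float, edge_s: float = 0.5
) -> np.ndarray:
    """0/1 burst indicator smoothed with raised-cosine edges."""
    ind = np.zeros(n)
    for on, off in np.atleast_2d(events) if len(events) else []:
        ind[int(on * fs) : int(off * fs)] = 1.0
    win = sps.windows.hann(max(3, int(edge_s * fs)))
    return np.convolve(ind, win / win.sum(), mode="same")


def generate_epoch(
    pma_days: float,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, list[str], EpochTruth]:
    """One 8-channel referential (Cz) recording segment with ground truth.

    Returns ``(signal, channels, truth)`` where ``signal`` is in µV at
    ``config.fs``.  Homologous left/right channels share burst onsets
    with the age-dependent synchrony probability; all four electrodes of
    a hemisphere share that hemisphere's schedule but carry independent
    noise realisations, so bipolar derivations retain the bursts.
    """
    cfg = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dur = duration_s if duration_s is not None else cfg.duration_s
    n = int(round(dur * cfg.fs))

    spans = _state_schedule(dur, cfg, rng)
    isi_mu = cfg.isi_mean(pma_days)
    left_events = _burst_schedule(dur, isi_mu, cfg, spans, rng)
    right_events = _desynchronise(left_events, cfg.synchrony(pma_days), dur, rng)

    amp = cfg.burst_amp(pma_days)
    floor = cfg.floor_amp(pma_days)
    weights = cfg.band_weights(pma_days)

    env_l = _envelope_from_events(left_events, n, cfg.fs)
    env_r = _envelope_from_events(right_events, n, cfg.fs)
    amp_l = floor + (amp - floor) * env_l
    amp_r = floor + (amp - floor) * env_r

    channels = list(ELECTRODES)
    signal = np.zeros((len(channels), n))
    for i, ch in enumerate(channels):
        noise = _band_noise(n, cfg.fs, weights, rng)
        a = amp_l if ch in LEFT else amp_r
        signal[i] = a / 3.0 * noise

    truth = EpochTruth(
        events_left=left_events,
        events_right=right_events,
        state_spans=spans,
        isi_mean_s=isi_mu,
        burst_amp_uv=amp,
        floor_amp_uv=floor,
    )
    return signal, channels, truth


def inject_artefacts(
    signal: np.ndarray,
    channels: list[str],
    truth: EpochTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    contamination_frac: float = 0.05,
    n_flat: int = 1,
    high_amp: bool = True,
    flat: bool = False,
) -> tuple[np.ndarray, EpochTruth]:
    """Contaminate a clean recording; labels are recorded in the truth.

    High-amplitude artefacts add a large low-frequency excursion to one
    frontal electrode inside randomly chosen true bursts until roughly
    ``contamination_frac`` of the recording is covered.  Flat-channel
    artefacts scale randomly chosen electrodes to ``config.flat_scale``
    of their amplitude (electrode shorting).
    """
    signal = signal.copy()
    fs = config.fs
    dur = signal.shape[1] / fs
    if high_amp and len(truth.events_union):
        target = contamination_frac * dur
        order = rng.permutation(len(truth.events_union))
        covered = 0.0
        chosen = []
        ch_idx = channels.index("Fp1")
        for k in order:
            on, off = truth.events_union[k]
            i0, i1 = int(on * fs), int(off * fs)
            t = np.arange(i1 - i0) / fs
            burst = config.high_amp_voltage_uv * np.sin(2 * np.pi * 2.0 * t)
            taper = sps.windows.tukey(len(t), 0.25)
            signal[ch_idx, i0:i1] += burst * taper
            chosen.append([on, off])
            covered += off - on
            if covered >= target:
                break
        truth.artefact_high_amp = np.asarray(sorted(chosen), dtype=float)
    if flat:
        cand = [c for c in channels if c not in truth.artefact_flat_channels]
        for ch in rng.choice(cand, size=min(n_flat, len(cand)), replace=False):
            signal[channels.index(ch)] *= config.flat_scale
            truth.artefact_flat_channels.append(str(ch))
    return signal, truth


def generate_recording(
    infant_id: str,
    recording_id: str,
    pma_days: int,
    config: CohortConfig,
    rng: np.random.Generator,
    functional_age_days: float | None = None,
) -> tuple[RecordingSet, EpochTruth]:
    """One recording, possibly contaminated per the configured rates.

    ``functional_age_days`` is the age that drives the generative
    parameters; it defaults to the chart PMA but cohort generation passes
    a biologically jittered value (see :class:`CohortConfig`).
    """
    age = pma_days if functional_age_days is None else functional_age_days
    signal, channels, truth = generate_epoch(age, config, rng)
    if config.high_amp_rate > 0 and rng.random() < config.high_amp_rate:
        signal, truth = inject_artefacts(
            signal, channels, truth, config, rng, high_amp=True, flat=False,
            contamination_frac=rng.uniform(0.02, 0.3),
        )
    if config.flat_channel_rate > 0 and rng.random() < config.flat_channel_rate:
        signal, truth = inject_artefacts(
            signal, channels, truth, config, rng, high_amp=False, flat=True,
        )
    rec = RecordingSet(
        infant_id=infant_id,
        recording_id=recording_id,
        pma_days=pma_days,
        channels=channels,
        fs_native=config.fs,
        signal=signal,
    )
    return rec, truth


def _cohort_plan(
    config: CohortConfig, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    """(infant_id, recording_id, pma_days) rows for the whole cohort."""
    rows = []
    lo_n, hi_n = config.recordings_per_infant
    for i in range(config.n_infants):
        infant = f"inf{i:03d}"
        n_rec = int(rng.integers(lo_n, hi_n + 1))
        spacing = rng.integers(
            config.recording_spacing_days[0],
            config.recording_spacing_days[1] + 1,
            size=max(0, n_rec - 1),
        )
        span = int(spacing.sum())
        first = int(
            rng.integers(config.pma_min_days, max(config.pma_min_days + 1,
                                                  config.pma_max_days - span))
        )
        pma = first
        for r in range(n_rec):
            rows.append((infant, f"{infant}_rec{r}", int(pma)))
            if r < n_rec - 1:
                pma += int(spacing[r])
    return rows


def generate_cohort(
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[tuple[RecordingSet, EpochTruth]]]:
    """Generate a serial-recording cohort; optionally write EDF files.

    Returns ``(manifest, recordings)``: the manifest has columns
    ``infant_id, recording_id, pma_days`` (plus ``edf_path`` when written
    to disk) and ``recordings`` pairs each :class:`RecordingSet` with its
    :class:`EpochTruth`.  With ``out_dir`` set, EDF files, the manifest
    CSV and a ground-truth CSV (burst schedules and artefact labels) are
    written.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    plan = _cohort_plan(cfg, rng)
    offsets = {
        infant: rng.normal(0.0, cfg.infant_age_sd_days)
        for infant in dict.fromkeys(i for i, _, _ in plan)
    }
    recordings = []
    rows = []
    truth_rows = []
    for infant_id, recording_id, pma in plan:
        age = pma + offsets[infant_id] + rng.normal(
            0.0, cfg.recording_age_jitter_sd_days
        )
        rec_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        rec, truth = generate_recording(
            infant_id, recording_id, pma, cfg, rec_rng, functional_age_days=age
        )
        recordings.append((rec, truth))
        row = {
            "infant_id": infant_id,
            "recording_id": recording_id,
            "pma_days": pma,
            "functional_age_days": age,
        }
        rows.append(row)
        for hemi, ev in (("left", truth.events_left), ("right", truth.events_right)):
            for on, off in ev:
                truth_rows.append(
                    {"recording_id": recording_id, "kind": f"sat_{hemi}",
                     "onset_s": on, "offset_s": off}
                )
        for on, off in truth.artefact_high_amp:
            truth_rows.append(
                {"recording_id": recording_id, "kind": "artefact_high_amp",
                 "onset_s": on, "offset_s": off}
            )
        for ch in truth.artefact_flat_channels:
            truth_rows.append(
                {"recording_id": recording_id, "kind": f"artefact_flat_{ch}",
                 "onset_s": np.nan, "offset_s": np.nan}
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from .edf_io import write_edf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for rec, _ in recordings:
            path = out / f"{rec.recording_id}.edf"
            write_edf(path, rec.signal, rec.fs_native, rec.channels,
                      patient_id=rec.infant_id, recording_note=rec.recording_id)
            paths.append(str(path))
        manifest["edf_path"] = paths
        # the manifest is the analysis input: ground truth stays in truth.csv
        manifest.drop(columns=["functional_age_days"]).to_csv(
            out / "manifest.csv", index=False
        )
        for _, r in manifest.iterrows():
            truth_rows.append(
                {"recording_id": r["recording_id"], "kind": "functional_age",
                 "onset_s": r["functional_age_days"], "offset_s": np.nan}
            )
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return manifest, recordings
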