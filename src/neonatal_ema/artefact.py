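"""Amplitude-based artefact rules and epoch acceptance.

NICU EEG is routinely contaminated.  Instead of visual preselection, two
deterministic amplitude rules decide which epochs enter the analysis:

* high amplitude — a SAT is artefactual if the voltage exceeds 500 µV at
  any time during the SAT on any channel; an epoch is rejected when more
  than 20% of it is covered by such SATs;
* low amplitude — a bipolar channel is excluded when its median envelope
  over time falls below 50% of the median envelope over time and
  channels (electrode shorting); a referential electrode whose envelope
  is both below 50% of the referential median and has a 95th percentile
  under 25 µV disqualifies every bipolar channel derived from it.

An epoch is accepted only if no channel is excluded and the contaminated
fraction is at most 20%.  Ties sit on the acceptance side: the rules are
written as strict "less than" / "more than".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import envelope
from .preprocessing import BIPOLAR_PAIRS, BIPOLAR_LABELS
from .sat_detection import merge_close_intervals

__all__ = [
    "ArtefactConfig",
    "ArtefactReport",
    "flag_high_amplitude_sats",
    "flag_low_amplitude_channels",
    "epoch_accept",
    "assess_epoch",
]


@dataclass
class ArtefactConfig:
    """Thresholds of the two amplitude rules (all overridable)."""

    high_amplitude_uv: float = 500.0
    envelope_ratio: float = 0.5
    referential_p95_uv: float = 25.0
    max_contamination: float = 0.20


@dataclass
class ArtefactReport:
    """Outcome of the artefact rules for one epoch."""

    excluded: dict[str, str] = field(default_factory=dict)
    artefact_intervals: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=float)
    )
    contamination_fraction: float = 0.0
    accepted: bool = True


def flag_high_amplitude_sats(
    data: np.ndarray,
    fs: float,
    per_channel_intervals: dict[str, np.ndarray],
    channel_labels: list[str],
    epoch_len_s: float,
    config: ArtefactConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Mark SATs whose voltage exceeds the high-amplitude threshold.

    Evaluated per channel on the filtered 64 Hz signal; the contamination
    fraction is the epoch share covered by the union of flagged SATs over
    all channels.
    """
    cfg = config or ArtefactConfig()
    idx = {c: i for i, c in enumerate(channel_labels)}
    flagged: list[list[float]] = []
    for label, intervals in per_channel_intervals.items():
        if label not in idx:
            continue
        x = data[idx[label]]
        for on, off in np.atleast_2d(intervals) if len(intervals) else []:
            i0, i1 = int(round(on * fs)), int(round(off * fs))
            seg = x[i0:i1]
            if seg.size and np.max(np.abs(seg)) > cfg.high_amplitude_uv:
                flagged.append([on, off])
    if not flagged:
        return np.empty((0, 2), dtype=float), 0.0
    arr = np.asarray(sorted(flagged), dtype=float)
    union = merge_close_intervals(arr, min_gap_s=0.0)
    fraction = float(np.sum(union[:, 1] - union[:, 0]) / epoch_len_s)
    return union, fraction


def _median_over_time(env: np.ndarray) -> np.ndarray:
    return np.median(env, axis=-1)


def flag_low_amplitude_channels(
    data: np.ndarray,
    channel_labels: list[str],
    ref_data: np.ndarray | None = None,
    ref_channels: list[str] | None = None,
    config: ArtefactConfig | None = None,
) -> dict[str, str]:
    """Exclude low-amplitude (shorted) channels.

    Bipolar rule: channel excluded when its median envelope over time is
    below ``envelope_ratio`` of the pooled median over time and channels.
    Several simultaneously flat channels drag the pooled median down, so
    the rule iterates to a fixed point excluding the worst channel first.

    Referential rule: an electrode is flagged when its median envelope is
    below the ratio of the pooled referential median AND its 95th
    percentile envelope is under ``referential_p95_uv``; every bipolar
    channel using that electrode is then excluded.
    """
    cfg = config or ArtefactConfig()
    excluded: dict[str, str] = {}

    env = envelope(data)
    active = list(range(len(channel_labels)))
    while active:
        pooled = np.median(env[active])
        med = _median_over_time(env[active])
        ratio = med / pooled if pooled > 0 else np.ones_like(med)
        worst = int(np.argmin(ratio))
        if pooled > 0 and med[worst] < cfg.envelope_ratio * pooled:
            excluded[channel_labels[active[worst]]] = "low-amplitude-bipolar"
            del active[worst]
        elif pooled == 0:
            for i in active:
                excluded[channel_labels[i]] = "low-amplitude-bipolar"
            break
        else:
            break

    if ref_data is not None and ref_channels:
        scalp = [i for i, c in enumerate(ref_channels) if c != "Cz"]
        renv = envelope(ref_data[scalp])
        pooled = np.median(renv)
        med = _median_over_time(renv)
        p95 = np.percentile(renv, 95, axis=-1)
        for j, i in enumerate(scalp):
            electrode = ref_channels[i]
            if (
                pooled > 0
                and med[j] < cfg.envelope_ratio * pooled
                and p95[j] < cfg.referential_p95_uv
            ) or (pooled == 0 and p95[j] < cfg.referential_p95_uv):
                for (a, b), lab in zip(BIPOLAR_PAIRS, BIPOLAR_LABELS):
                    if electrode in (a, b) and lab in channel_labels:
                        excluded.setdefault(lab, "low-amplitude-referential-derived")
    return excluded


def epoch_accept(report: ArtefactReport, config: ArtefactConfig | None = None) -> bool:
    """Accept iff no channel is excluded and contamination <= 20%."""
    cfg = config or ArtefactConfig()
    return (
        len(report.excluded) == 0
        and report.contamination_fraction <= cfg.max_contamination
    )


def assess_epoch(
    epoch,
    per_channel_intervals: dict[str, np.ndarray],
    config: ArtefactConfig | None = None,
) -> ArtefactReport:
    """Run both artefact rules on one epoch and decide acceptance."""
    cfg = config or ArtefactConfig()
    intervals, fraction = flag_high_amplitude_sats(
        epoch.data,
        epoch.fs,
        per_channel_intervals,
        epoch.channel_labels,
        epoch.duration_s,
        cfg,
    )
    excluded = flag_low_amplitude_channels(
        epoch.data,
        epoch.channel_labels,
        ref_data=epoch.ref_data,
        ref_channels=epoch.ref_channels,
        config=cfg,
    )
    report = ArtefactReport(
        excluded=excluded,
        artefact_intervals=intervals,
        contamination_fraction=fraction,
    )
    report.accepted = epoch_accept(report, cfg)
    return report
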