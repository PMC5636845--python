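"""End-to-end orchestration: recordings -> accepted-epoch feature table.

Chains preprocessing, SAT detection, artefact screening and feature
extraction.  The feature table (one row per accepted epoch, 46 feature
columns plus provenance) is the contract between extraction and the
brain-age model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .artefact import ArtefactConfig, ArtefactReport, assess_epoch
from .features import extract_features
from .preprocessing import (
    BipolarEpoch,
    RecordingSet,
    RecordingTooShortError,
    preprocess_recording,
)
from .sat_detection import (
    SATAnnotation,
    SATDetectorConfig,
    consensus_annotation,
    detect_sats,
    low_sat_segment,
    sat_percent,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "MONTAGE_VARIANTS", "subset_epoch",
           "annotate_epoch", "process_epoch", "process_recording",
           "cohort_feature_table"]

#: Reduced-montage variants (all symmetric across hemispheres), named by
#: electrode pair type: Fp - frontal polar, C - central, T - temporal,
#: O - occipital.  Streamlined NICU monitoring typically records the
#: 2- or 4-channel sets.
MONTAGE_VARIANTS: dict[str, tuple[str, ...]] = {
    "8ch": ("Fp1-C3", "C3-O1", "Fp1-T3", "T3-O1",
            "Fp2-C4", "C4-O2", "Fp2-T4", "T4-O2"),
    "4ch Fp-T, T-O": ("Fp1-T3", "T3-O1", "Fp2-T4", "T4-O2"),
    "4ch Fp-C, C-O": ("Fp1-C3", "C3-O1", "Fp2-C4", "C4-O2"),
    "2ch Fp-T": ("Fp1-T3", "Fp2-T4"),
    "2ch T-O": ("T3-O1", "T4-O2"),
    "2ch Fp-C": ("Fp1-C3", "Fp2-C4"),
    "2ch C-O": ("C3-O1", "C4-O2"),
}


def subset_epoch(epoch: BipolarEpoch, channels: tuple[str, ...]) -> BipolarEpoch:
    """Restrict an epoch to a reduced montage (referential data kept)."""
    idx = [epoch.channel_labels.index(c) for c in channels]
    return BipolarEpoch(
        channel_labels=[epoch.channel_labels[i] for i in idx],
        fs=epoch.fs,
        data=epoch.data[idx],
        start_offset_s=epoch.start_offset_s,
        recording_id=epoch.recording_id,
        infant_id=epoch.infant_id,
        pma_days=epoch.pma_days,
        ref_channels=epoch.ref_channels,
        ref_data=epoch.ref_data,
        epoch_index=epoch.epoch_index,
    )


@dataclass
class PipelineConfig:
    """Epoch geometry and sub-module parameters.

    With the default 1-h epochs the SAT% trace uses 5-minute windows
    advanced by 1 minute and low-SAT% runs must last at least 5 minutes;
    shorter epochs (e.g. 10 minutes for quick simulation studies) scale
    these windows proportionally.
    """

    epoch_len_s: float = 3600.0
    step_s: float | None = None  # default: epoch_len / 4 (75% overlap)
    detector: SATDetectorConfig = field(default_factory=SATDetectorConfig)
    artefact: ArtefactConfig = field(default_factory=ArtefactConfig)

    @property
    def sat_window_s(self) -> float:
        return self.epoch_len_s / 12.0

    @property
    def sat_step_s(self) -> float:
        return self.epoch_len_s / 60.0

    @property
    def low_sat_min_run_s(self) -> float:
        return self.epoch_len_s / 12.0


def annotate_epoch(
    epoch: BipolarEpoch, config: PipelineConfig | None = None
) -> SATAnnotation:
    """Detect SATs per channel and build the per-epoch consensus."""
    cfg = config or PipelineConfig(epoch_len_s=epoch.duration_s)
    per_channel = {
        label: detect_sats(epoch.data[i], fs=epoch.fs, config=cfg.detector)
        for i, label in enumerate(epoch.channel_labels)
    }
    consensus = consensus_annotation(
        per_channel, epoch.duration_s, fs=epoch.fs, config=cfg.detector
    )
    return SATAnnotation(
        channels=per_channel, consensus=consensus, epoch_len_s=epoch.duration_s
    )


def process_epoch(
    epoch: BipolarEpoch,
    config: PipelineConfig | None = None,
    channels: tuple[str, ...] | None = None,
) -> tuple[dict | None, ArtefactReport, SATAnnotation]:
    """Annotate, screen and featurise one epoch.

    ``channels`` restricts the analysis to a reduced montage.  Returns
    ``(feature_row, artefact_report, annotation)``; the feature row is
    ``None`` for rejected epochs.
    """
    cfg = config or PipelineConfig(epoch_len_s=epoch.duration_s)
    if channels is not None:
        epoch = subset_epoch(epoch, channels)
    ann = annotate_epoch(epoch, cfg)
    report = assess_epoch(epoch, ann.channels, cfg.artefact)
    if not report.accepted:
        return None, report, ann
    trace = sat_percent(
        ann.consensus,
        epoch_len_s=epoch.duration_s,
        window_len_s=cfg.sat_window_s,
        step_s=cfg.sat_step_s,
    )
    mask = low_sat_segment(
        trace,
        epoch_len_s=epoch.duration_s,
        min_run_s=cfg.low_sat_min_run_s,
    )
    row = extract_features(epoch, ann, mask, report)
    return row, report, ann


def process_recording(
    rec: RecordingSet,
    config: PipelineConfig | None = None,
    channels: tuple[str, ...] | None = None,
) -> list[dict]:
    """Preprocess a recording and featurise its accepted epochs."""
    cfg = config or PipelineConfig()
    try:
        epochs = preprocess_recording(rec, epoch_len_s=cfg.epoch_len_s,
                                      step_s=cfg.step_s)
    except RecordingTooShortError:
        logger.warning("recording %s shorter than one epoch: skipped",
                       rec.recording_id)
        return []
    rows = []
    for epoch in epochs:
        row, report, _ = process_epoch(epoch, cfg, channels=channels)
        if row is None:
            logger.info(
                "epoch %s/%d rejected (%d channels excluded, %.1f%% contaminated)",
                rec.recording_id, epoch.epoch_index, len(report.excluded),
                100 * report.contamination_fraction,
            )
            continue
        rows.append(row)
    return rows


def cohort_feature_table(
    recordings: list[RecordingSet],
    config: PipelineConfig | None = None,
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Feature table over a cohort: one row per accepted epoch."""
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    for rec in recordings:
        rows.extend(process_recording(rec, cfg, channels=channels))
    df = pd.DataFrame(rows)
    if not df.empty:
        meta = ["infant_id", "recording_id", "epoch_index", "pma_days",
                "n_valid_channels"]
        df = df[meta + [c for c in df.columns if c not in meta]]
    return df
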