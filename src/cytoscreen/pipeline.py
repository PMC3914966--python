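"""End-to-end composition: images → cells → wells → screen statistics.

Outputs are deterministic for fixed inputs and seed; every row of every
artifact is traceable to its plate/well(/field).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .errors import InsufficientDataError
from .io import discover_fields, read_field, read_plate_map, write_csv
from .phenotypes import classify_frame, features_to_frame, summarize_wells
from .screen_stats import call_hits, cross_timepoint_hits, qc_report
from .segmentation import segment_field

log = logging.getLogger(__name__)

#: Endpoints scored in the screen (the mitosis endpoint is QC-only by
#: default because its controls overlap).
SCREEN_ENDPOINTS = ("n_cells", "pct_abnormal")


def segment_directory(images_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Segment every discovered field and pool per-cell features."""
    frames = []
    for files in discover_fields(images_dir):
        fieldimg = read_field(files, config.pixel_size_um)
        feats, nuclei, _ = segment_field(fieldimg, config.segmentation)
        if config.verbose:
            log.info(
                "%s/%s f%d: %d cells retained",
                files.plate_id, files.well_id, files.field_index, len(feats),
            )
        frames.append(features_to_frame(feats))
    features = pd.concat(frames, ignore_index=True)
    log.info("segmented %d cells from %d fields", len(features), len(frames))
    return features


def screen_from_summaries(
    summaries: pd.DataFrame, layout: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Hit calling (per endpoint × timepoint) plus QC, from well summaries."""
    hit_frames = []
    timepoints = sorted(layout["timepoint_h"].dropna().unique())
    for endpoint in SCREEN_ENDPOINTS:
        for tp in timepoints or [None]:
            hit_frames.append(
                call_hits(
                    summaries,
                    layout,
                    endpoint,
                    timepoint_h=tp,
                    z_cutoff=config.z_cutoff,
                    replicate_agg=config.replicate_agg,
                    batch_scope=config.batch_scope,
                )
            )
    hits = cross_timepoint_hits(pd.concat(hit_frames, ignore_index=True))
    try:
        qc = qc_report(summaries, layout, z_cutoff=config.z_cutoff, batch_scope=config.batch_scope)
    except InsufficientDataError as exc:
        log.warning("QC report skipped: %s", exc)
        qc = None
    return hits, qc


def run_pipeline(
    config: RunConfig,
    images_dir: str | Path,
    plate_map: str | Path | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Full run: segment, classify, summarise, and (if a plate map with
    controls is given) QC and hit-call. Returns the written artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    features = segment_directory(images_dir, config)
    artifacts["cell_features"] = write_csv(features, out / "cell_features.csv")
    classified = classify_frame(features, config.rules)
    artifacts["cell_classes"] = write_csv(classified, out / "cell_classes.csv")
    summaries = summarize_wells(features, config.rules)
    artifacts["well_summaries"] = write_csv(summaries, out / "well_summaries.csv")

    if plate_map is not None:
        layout = read_plate_map(plate_map)
        roles = set(layout["role"])
        if {"negative_control"} <= roles:
            hits, qc = screen_from_summaries(summaries, layout, config)
            artifacts["hits"] = write_csv(hits, out / "hits.csv")
            if qc is not None:
                artifacts["qc"] = write_csv(qc, out / "qc.csv")
    log.info("pipeline artifacts: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts
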