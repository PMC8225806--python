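"""Per-visit feature extraction: from wound series to a tidy feature table.

For each visit the thermal frame is segmented (normalize -> contour ->
morphological refinement), the refined mask's pixel count gives the
thermal-area proxy, and the mask-aware GLCM chain yields the 12 texture
features.  Planimetry area comes from the visit's trace (shoelace) or a
precomputed ``area_cm2``.  Wounds whose frames cannot be segmented or
quantized are excluded with an explicit reason -- cohort attrition is an
auditable part of the method, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import logging

import numpy as np
import pandas as pd

from .errors import WoundTextureError
from .preprocess import MIN_WOUND_PIXELS, segment_wound, thermal_area
from .stats import polygon_area
from .texture import FEATURE_COLUMNS, features_from_frame
from .thermal_io import WoundSeries

logger = logging.getLogger(__name__)

#: Column layout of the per-visit feature table.
TABLE_COLUMNS: Tuple[str, ...] = (
    "wound_id",
    "participant_id",
    "visit_week",
    "healed_at_week12",
    "planimetry_area_cm2",
    "thermal_area_px",
) + FEATURE_COLUMNS


class ExtractionExclusion(NamedTuple):
    wound_id: str
    visit_week: Optional[int]
    reason: str


@dataclass
class ExtractionSettings:
    """Knobs of the preprocessing + texture stages."""

    n_levels: int = 16
    glcm_distance: int = 1
    morphology_radius: int = 2
    min_wound_pixels: int = MIN_WOUND_PIXELS

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise WoundTextureError("n_levels must be >= 2")
        if self.glcm_distance < 1:
            raise WoundTextureError("glcm_distance must be >= 1")
        if self.morphology_radius < 0:
            raise WoundTextureError("morphology_radius must be >= 0")
        if self.min_wound_pixels < 1:
            raise WoundTextureError("min_wound_pixels must be >= 1")


def extract_feature_table(
    cohort: Sequence[WoundSeries],
    settings: Optional[ExtractionSettings] = None,
) -> Tuple[pd.DataFrame, List[ExtractionExclusion]]:
    """Extract the per-visit feature table for a cohort.

    Returns the table (one row per wound-week, columns
    :data:`TABLE_COLUMNS`) and the list of excluded wounds with reasons.  A
    wound is excluded entirely if any of its three visits fails segmentation
    or texture extraction, since week ratios need all three weeks.
    """
    settings = settings or ExtractionSettings()
    rows = []
    excluded: List[ExtractionExclusion] = []
    for series in cohort:
        wound_rows = []
        failure: Optional[ExtractionExclusion] = None
        for week in sorted(series.records):
            rec = series.records[week]
            row = {
                "wound_id": series.wound_id,
                "participant_id": rec.participant_id,
                "visit_week": week,
                "healed_at_week12": int(series.healed_at_week12),
                "planimetry_area_cm2": np.nan,
                "thermal_area_px": np.nan,
            }
            if rec.trace is not None:
                row["planimetry_area_cm2"] = polygon_area(rec.trace)
            elif rec.area_cm2 is not None:
                row["planimetry_area_cm2"] = rec.area_cm2
            if rec.frame is not None:
                try:
                    mask = segment_wound(
                        rec.frame,
                        min_wound_pixels=settings.min_wound_pixels,
                        morphology_radius=settings.morphology_radius,
                    )
                    row["thermal_area_px"] = thermal_area(mask)
                    fv = features_from_frame(
                        rec.frame,
                        mask,
                        n_levels=settings.n_levels,
                        distance=settings.glcm_distance,
                        min_pixels=settings.min_wound_pixels,
                    )
                    row.update(fv.as_dict())
                except WoundTextureError as exc:
                    failure = ExtractionExclusion(series.wound_id, week, str(exc))
                    break
            wound_rows.append(row)
        if failure is not None:
            logger.info(
                "excluding wound %s (week %s): %s",
                failure.wound_id,
                failure.visit_week,
                failure.reason,
            )
            excluded.append(failure)
            continue
        rows.extend(wound_rows)

    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return df, excluded
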