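"""Synthetic thermal wound cohorts for testing the longitudinal pipeline.

The study's clinical images were never deposited, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

* a wound bed, a random star-convex polygon, warmer than periwound skin by
  ``wound_delta_temp`` degC;
* spatially correlated textural noise inside the wound (white noise smoothed
  with a Gaussian kernel of width ``texture_corr_len`` -- the simplest
  stationary random field with a controllable heterogeneity knob that GLCM
  features respond to);
* uncorrelated sensor noise over the whole frame;
* healing dynamics: for healed wounds the planimetry area shrinks
  geometrically toward a target week2/week0 median of 0.50 and the wound's
  temperature offset and texture variance decay week by week; unhealed wounds
  stay near-constant (area median anchor 0.88).  The 0.50/0.88 anchors and the
  default 17 healed / 55 unhealed split reproduce the source cohort's
  planimetry medians and outcome split.

Reproducibility: one root seed; wound ``i`` draws from an independent
substream ``SeedSequence(seed, spawn_key=(i,))``, so results do not depend on
generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _draw_polygon

from .errors import DegenerateInputError
from .thermal_io import (
    PlanimetryTrace,
    ThermalFrame,
    VisitRecord,
    WoundSeries,
    write_thermal_frame,
    write_trace,
)


@dataclass
class TrajectoryParams:
    """Generative parameters for one cohort's wound trajectories.

    Temperatures are in degC, lengths in cm or pixels as named.  The decay
    factors multiply both the wound's temperature offset and its texture
    standard deviation once per week (cumulatively, ``factor ** week``); the
    healed decay must not exceed the unhealed decay -- that ordering is what
    makes week2/week0 texture ratios separate the groups.

    The defaults are calibrated so that, at the default 17 v 55 cohort split,
    the week2/week0 PCA1 contrast separates the groups with high power while
    the week1/week0 contrast remains clearly weaker (see docs/methods.md).
    """

    baseline_skin_temp: float = 32.0
    wound_delta_temp: float = 1.5
    texture_sigma: float = 0.6
    texture_corr_len: float = 2.0
    smooth_sigma: float = 0.3
    smooth_corr_len: float = 6.0
    weekly_texture_decay_healed: float = 0.45
    weekly_texture_decay_unhealed: float = 0.97
    area_ratio_w20_healed: float = 0.50
    area_ratio_w20_unhealed: float = 0.88
    area_ratio_log_sigma: float = 0.25
    sensor_noise_sigma: float = 0.05
    frame_height: int = 120
    frame_width: int = 160
    pixels_per_cm: float = 14.0
    mean_wound_radius_cm: float = 2.0
    radius_log_sigma: float = 0.25
    texture_sigma_log_jitter: float = 0.25

    def __post_init__(self) -> None:
        if self.weekly_texture_decay_healed <= 0 or self.weekly_texture_decay_unhealed <= 0:
            raise DegenerateInputError("decay factors must be > 0")
        if self.weekly_texture_decay_healed > self.weekly_texture_decay_unhealed:
            raise DegenerateInputError(
                "healed decay must be <= unhealed decay (healed wounds quieten faster)"
            )
        if self.texture_corr_len <= 0:
            raise DegenerateInputError("texture_corr_len must be > 0")
        if self.texture_sigma < 0 or self.sensor_noise_sigma < 0 or self.smooth_sigma < 0:
            raise DegenerateInputError("noise standard deviations must be >= 0")
        if self.smooth_corr_len <= 0:
            raise DegenerateInputError("smooth_corr_len must be > 0")
        if self.area_ratio_w20_healed <= 0 or self.area_ratio_w20_unhealed <= 0:
            raise DegenerateInputError("area ratio targets must be > 0")
        if self.frame_height < 2 or self.frame_width < 2:
            raise DegenerateInputError("frame must be at least 2x2")
        if self.pixels_per_cm <= 0 or self.mean_wound_radius_cm <= 0:
            raise DegenerateInputError("geometry parameters must be > 0")

    def null(self) -> "TrajectoryParams":
        """A no-group-effect version: healed wounds behave like unhealed ones."""
        return dataclasses.replace(
            self,
            weekly_texture_decay_healed=self.weekly_texture_decay_unhealed,
            area_ratio_w20_healed=self.area_ratio_w20_unhealed,
        )


@dataclass
class SyntheticCohortConfig:
    """Cohort-level configuration; defaults reproduce the 17/55 outcome split."""

    n_healed: int = 17
    n_unhealed: int = 55
    params: TrajectoryParams = field(default_factory=TrajectoryParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healed < 1 or self.n_unhealed < 1:
            raise DegenerateInputError("cohort needs at least one wound per group")


def generate_wound_polygon(
    rng: np.random.Generator,
    radius_cm: float,
    center_cm: Tuple[float, float],
    n_vertices: Optional[int] = None,
) -> PlanimetryTrace:
    """Random star-convex polygon (8-16 vertices, radius jitter).

    Star-convexity with strictly increasing vertex angles guarantees a simple
    polygon and avoids circular-mask artifacts in contour detection tests.
    """
    if n_vertices is None:
        n_vertices = int(rng.integers(8, 17))
    k = np.arange(n_vertices)
    angles = 2.0 * np.pi * (k + rng.uniform(-0.3, 0.3, n_vertices)) / n_vertices
    radii = radius_cm * (1.0 + rng.uniform(-0.35, 0.35, n_vertices))
    cx, cy = center_cm
    verts = np.column_stack(
        [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
    )
    return PlanimetryTrace(vertices=verts)


def rasterize_trace(
    trace: PlanimetryTrace, shape: Tuple[int, int], pixels_per_cm: float
) -> np.ndarray:
    """Rasterize a cm-space trace onto the pixel grid (x -> column, y -> row)."""
    cols = trace.vertices[:, 0] * pixels_per_cm
    rows = trace.vertices[:, 1] * pixels_per_cm
    h, w = shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise DegenerateInputError("polygon does not fit inside the frame")
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def generate_wound_image(
    params: TrajectoryParams,
    week: int,
    healed: bool,
    wound_polygon: PlanimetryTrace,
    rng: np.random.Generator,
    wound_id: str = "",
) -> Tuple[ThermalFrame, np.ndarray]:
    """One visit's thermal frame plus its ground-truth wound mask.

    Pixel model: ``baseline + (in wound: decayed delta + decayed rough texture
    + persistent smooth field) + sensor noise``.  Each correlated field is
    frame-wide smoothed white noise rescaled to unit variance, so its in-wound
    standard deviation equals its sigma parameter.  The rough field (width
    ``texture_corr_len``) carries the wound's textural heterogeneity and
    decays as the wound heals; the smooth field (width ``smooth_corr_len``)
    models the broad physiological temperature profile of the limb and does
    not heal away.  Because downstream quantization is amplitude-invariant,
    it is this *mix shift* from rough toward smooth -- not the shrinking
    amplitude itself -- that moves the co-occurrence features of healed
    wounds between weeks.  Deterministic given the rng state.
    """
    shape = (params.frame_height, params.frame_width)
    mask = rasterize_trace(wound_polygon, shape, params.pixels_per_cm)
    decay_base = (
        params.weekly_texture_decay_healed
        if healed
        else params.weekly_texture_decay_unhealed
    )
    decay = decay_base ** week

    pixels = np.full(shape, params.baseline_skin_temp, dtype=np.float64)
    pixels[mask] += params.wound_delta_temp * decay

    def _unit_field(corr_len: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal(shape), corr_len)
        sd = f.std()
        return f / sd if sd > 0 else f

    if params.texture_sigma > 0:
        pixels[mask] += params.texture_sigma * decay * _unit_field(
            params.texture_corr_len
        )[mask]
    if params.smooth_sigma > 0:
        pixels[mask] += params.smooth_sigma * _unit_field(params.smooth_corr_len)[mask]
    if params.sensor_noise_sigma > 0:
        pixels += params.sensor_noise_sigma * rng.standard_normal(shape)

    frame = ThermalFrame(pixels=pixels, wound_id=wound_id, visit_week=week)
    return frame, mask


def _scaled_trace(
    trace: PlanimetryTrace, scale: float, wound_id: str, week: int
) -> PlanimetryTrace:
    center = trace.vertices.mean(axis=0)
    verts = center + scale * (trace.vertices - center)
    return PlanimetryTrace(vertices=verts, wound_id=wound_id, visit_week=week)


def generate_wound_series(
    params: TrajectoryParams,
    healed: bool,
    rng: np.random.Generator,
    wound_id: str = "W000",
    participant_id: str = "P000",
    with_frames: bool = True,
) -> WoundSeries:
    """Three weekly visits sharing one wound identity.

    The polygon shrinks geometrically so that the week2/week0 area ratio is
    log-normally spread around the group's target median; a per-wound
    log-normal jitter on ``texture_sigma`` models between-wound heterogeneity.
    With ``with_frames=False`` only traces are generated (a planimetry-only
    cohort); frame generation consumes additional random draws, so the two
    modes yield different polygons for the *next* wound only if one generator
    is shared -- per-wound substreams avoid that.
    """
    target = params.area_ratio_w20_healed if healed else params.area_ratio_w20_unhealed
    ratio_w20 = target * float(np.exp(rng.normal(0.0, params.area_ratio_log_sigma)))

    radius = params.mean_wound_radius_cm * float(
        np.exp(rng.normal(0.0, params.radius_log_sigma))
    )
    # keep the polygon (at its largest weekly extent, jitter included) in-frame
    half_extent_cm = (
        min(params.frame_height, params.frame_width) / 2.0 - 3.0
    ) / params.pixels_per_cm
    max_scale = max(1.0, ratio_w20 ** 0.5)
    radius = min(radius, half_extent_cm / (1.35 * max_scale))
    radius = max(radius, 2.0 / params.pixels_per_cm)  # at least ~2 px

    center = (
        params.frame_width / 2.0 / params.pixels_per_cm,
        params.frame_height / 2.0 / params.pixels_per_cm,
    )
    base = generate_wound_polygon(rng, radius, center)

    sigma_jitter = float(np.exp(rng.normal(0.0, params.texture_sigma_log_jitter)))
    wound_params = dataclasses.replace(
        params, texture_sigma=params.texture_sigma * sigma_jitter
    )

    records = {}
    for week in (0, 1, 2):
        scale = ratio_w20 ** (week / 4.0)  # area scale ratio**(week/2)
        trace = _scaled_trace(base, scale, wound_id, week)
        frame = None
        if with_frames:
            frame, _ = generate_wound_image(
                wound_params, week, healed, trace, rng, wound_id=wound_id
            )
        records[week] = VisitRecord(
            wound_id=wound_id,
            participant_id=participant_id,
            visit_week=week,
            frame=frame,
            trace=trace,
        )
    return WoundSeries(wound_id=wound_id, records=records, healed_at_week12=healed)


def _participant_index(i: int, n_total: int) -> int:
    # some participants present with two wounds (e.g. 72 wounds in 60 people):
    # the last 2*d wounds are paired onto d participants, d = n_total // 6
    d = n_total // 6
    cut = n_total - 2 * d
    return i if i < cut else cut + (i - cut) // 2


def generate_cohort(
    config: SyntheticCohortConfig, with_frames: bool = True
) -> List[WoundSeries]:
    """Generate ``n_healed + n_unhealed`` wound series, healed wounds first."""
    n_total = config.n_healed + config.n_unhealed
    cohort: List[WoundSeries] = []
    for i in range(n_total):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i,))
        )
        cohort.append(
            generate_wound_series(
                config.params,
                healed=i < config.n_healed,
                rng=rng,
                wound_id=f"W{i:03d}",
                participant_id=f"P{_participant_index(i, n_total):03d}",
                with_frames=with_frames,
            )
        )
    return cohort


def write_cohort(
    cohort: List[WoundSeries], outdir, dialect: str = "tiff16"
) -> Path:
    """Write frames, traces and a manifest CSV; returns the manifest path.

    The manifest follows the cohort-table schema of
    :func:`woundtexture.thermal_io.read_cohort_table` and is byte-identical
    across runs with the same cohort.
    """
    from .stats import polygon_area  # local import to avoid a cycle at import time

    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    ext = {"csv_matrix": "csv", "tiff16": "tif", "png8": "png"}[dialect]
    rows = []
    for series in cohort:
        for week in sorted(series.records):
            rec = series.records[week]
            stem = f"{series.wound_id}_w{week}"
            frame_rel = trace_rel = ""
            area = ""
            if rec.frame is not None:
                frame_rel = f"frames/{stem}.{ext}"
                write_thermal_frame(rec.frame, outdir / frame_rel, dialect)
            if rec.trace is not None:
                trace_rel = f"traces/{stem}.csv"
                write_trace(rec.trace, outdir / trace_rel)
                area = f"{polygon_area(rec.trace):.10g}"
            rows.append(
                {
                    "wound_id": series.wound_id,
                    "participant_id": rec.participant_id,
                    "visit_week": week,
                    "frame_path": frame_rel,
                    "trace_path": trace_rel,
                    "area_cm2": area,
                    "healed_at_week12": int(series.healed_at_week12),
                }
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
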