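"""Domain containers and on-disk formats for thermal wound imaging.

A visit's raw observation is a :class:`ThermalFrame` -- a matrix of absolute
skin temperatures in degrees Celsius as produced by a hand-held thermal camera
(nominally 160x120 pixels, accuracy about +/- 2 degC, emissivity 0.98 for clean
skin).  Wounds are additionally traced on acetate film and digitized as a
:class:`PlanimetryTrace` (a simple closed polygon in cm coordinates).  Weekly
visits are bundled into a :class:`WoundSeries` with a week-12 healed/unhealed
outcome label.

On-disk dialects
----------------
``csv_matrix``
    Comma-separated float matrix, one image row per line.  Lossless.
``tiff16``
    16-bit grayscale TIFF with a JSON sidecar ``{"scale", "offset",
    "emissivity", ...}``; temperature = DN * scale + offset.  Lossy only at the
    DN quantization step (half a scale unit).  Radiometric TIFF tag conventions
    are vendor-specific, so an explicit sidecar is used instead.
``png8``
    8-bit grayscale PNG + sidecar.  Lossy (min-max scaled to 256 levels); meant
    for visual QC exports, not analysis.

Coordinate conventions: images are row-major with the origin at the top-left
pixel center, 0-based indices; trace coordinates are (x, y) in cm with x along
image columns and y along rows.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    CohortError,
    FrameValidationError,
    ThermalIOError,
    TraceValidationError,
)

logger = logging.getLogger(__name__)

#: Measurement range of the study camera, degC.
CAMERA_RANGE_C: Tuple[float, float] = (-20.0, 120.0)

#: Default emissivity for clean human skin.
DEFAULT_EMISSIVITY: float = 0.98

#: The three analysis weeks; a wound missing any of them is excluded.
ANALYSIS_WEEKS: Tuple[int, int, int] = (0, 1, 2)

DIALECTS = ("csv_matrix", "tiff16", "png8")

_EXT_TO_DIALECT = {
    ".csv": "csv_matrix",
    ".tif": "tiff16",
    ".tiff": "tiff16",
    ".png": "png8",
}


@dataclass
class ThermalFrame:
    """A 2-D matrix of absolute temperatures (degC) plus acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of float, shape (height, width)
        Temperatures in degC; must be finite and within the camera range.
    emissivity : float
        Dimensionless in (0, 1]; defaults to 0.98 (clean skin).
    wound_id, visit_week
        Identity of the observation.
    """

    pixels: np.ndarray
    emissivity: float = DEFAULT_EMISSIVITY
    wound_id: str = ""
    visit_week: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FrameValidationError(
                f"pixels must be 2-D, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape
        if h < 2 or w < 2:
            raise FrameValidationError(f"frame too small: {h}x{w} (need >= 2x2)")
        if not np.isfinite(self.pixels).all():
            raise FrameValidationError("frame contains non-finite temperatures")
        lo, hi = CAMERA_RANGE_C
        tmin = float(self.pixels.min())
        tmax = float(self.pixels.max())
        if tmin < lo or tmax > hi:
            raise FrameValidationError(
                f"temperatures [{tmin:.2f}, {tmax:.2f}] degC outside camera "
                f"range [{lo}, {hi}] degC"
            )
        if not (0.0 < self.emissivity <= 1.0):
            raise FrameValidationError(f"emissivity {self.emissivity} not in (0, 1]")
        self.visit_week = int(self.visit_week)
        if self.visit_week < 0:
            raise FrameValidationError("visit_week must be >= 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PlanimetryTrace:
    """Digitized wound outline: a simple closed polygon in cm coordinates."""

    vertices: np.ndarray  # (n, 2) array of (x, y) in cm
    wound_id: str = ""
    visit_week: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise TraceValidationError(
                f"vertices must be (n, 2), got {self.vertices.shape}"
            )
        if len(self.vertices) < 3:
            raise TraceValidationError("a trace needs at least 3 vertices")
        if not np.isfinite(self.vertices).all():
            raise TraceValidationError("trace contains non-finite coordinates")
        poly = _ShapelyPolygon(self.vertices)
        if (not poly.is_valid) or poly.area <= 0.0:
            raise TraceValidationError(
                "trace is not a simple closed polygon with positive area"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class VisitRecord:
    """One weekly visit for one wound; at least one measurement is present."""

    wound_id: str
    participant_id: str
    visit_week: int
    frame: Optional[ThermalFrame] = None
    trace: Optional[PlanimetryTrace] = None
    area_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        self.visit_week = int(self.visit_week)
        if self.visit_week < 0:
            raise CohortError("visit_week must be >= 0")
        if self.frame is None and self.trace is None and self.area_cm2 is None:
            raise CohortError(
                f"visit {self.wound_id}/week{self.visit_week} carries no data"
            )
        if self.area_cm2 is not None and not (
            math.isfinite(self.area_cm2) and self.area_cm2 >= 0
        ):
            raise CohortError("area_cm2 must be a finite non-negative number")


@dataclass
class WoundSeries:
    """All three analysis visits of one wound plus its week-12 outcome."""

    wound_id: str
    records: Dict[int, VisitRecord]
    healed_at_week12: bool

    def __post_init__(self) -> None:
        weeks = tuple(sorted(self.records))
        if weeks != ANALYSIS_WEEKS:
            raise CohortError(
                f"wound {self.wound_id}: weeks {weeks} present, need exactly "
                f"{ANALYSIS_WEEKS}"
            )
        self.healed_at_week12 = bool(self.healed_at_week12)

    @property
    def participant_id(self) -> str:
        return self.records[0].participant_id


# ---------------------------------------------------------------------------
# Frame I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise ThermalIOError(f"missing sidecar metadata file {sc}")
    with open(sc) as fh:
        return json.load(fh)


def write_thermal_frame(frame: ThermalFrame, path, dialect: str = "csv_matrix") -> Path:
    """Write a frame to disk in one of the documented dialects.

    Returns the path written.  ``tiff16`` spreads the frame's min-max range
    over the full 16-bit DN range; ``png8`` over 8 bits (lossy, QC only).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ThermalIOError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    meta = {
        "emissivity": frame.emissivity,
        "wound_id": frame.wound_id,
        "visit_week": frame.visit_week,
    }
    try:
        if dialect == "csv_matrix":
            np.savetxt(path, frame.pixels, delimiter=",", fmt="%.17g")
            _write_sidecar(path, meta)
        else:
            tmin = float(frame.pixels.min())
            tmax = float(frame.pixels.max())
            max_dn = 65535 if dialect == "tiff16" else 255
            scale = (tmax - tmin) / max_dn if tmax > tmin else 1.0
            dn = np.round((frame.pixels - tmin) / scale)
            meta.update({"scale": scale, "offset": tmin})
            if dialect == "tiff16":
                tifffile.imwrite(path, dn.astype("<u2"))
            else:
                iio.imwrite(path, dn.astype(np.uint8))
            _write_sidecar(path, meta)
    except OSError as exc:  # unwritable path, etc.
        raise ThermalIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_thermal_frame(path, dialect: Optional[str] = None) -> ThermalFrame:
    """Read a frame written by :func:`write_thermal_frame`.

    ``dialect`` is inferred from the file extension when omitted.  Out-of-range
    or non-finite temperatures are rejected with a diagnostic (the
    :class:`ThermalFrame` invariants apply on read as well as on write).
    """
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such file: {path}")
    if dialect is None:
        dialect = _EXT_TO_DIALECT.get(path.suffix.lower())
        if dialect is None:
            raise ThermalIOError(f"cannot infer dialect from extension of {path}")
    if dialect not in DIALECTS:
        raise ThermalIOError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")

    if dialect == "csv_matrix":
        try:
            pixels = np.loadtxt(path, delimiter=",", ndmin=2, dtype=np.float64)
        except ValueError as exc:
            raise ThermalIOError(f"malformed CSV matrix in {path}: {exc}") from exc
        sc = _sidecar_path(path)
        meta = {}
        if sc.exists():
            with open(sc) as fh:
                meta = json.load(fh)
    else:
        meta = _read_sidecar(path)
        if "scale" not in meta or "offset" not in meta:
            raise ThermalIOError(f"sidecar of {path} lacks scale/offset")
        if dialect == "tiff16":
            dn = tifffile.imread(path).astype(np.float64)
        else:
            dn = iio.imread(path).astype(np.float64)
        pixels = dn * float(meta["scale"]) + float(meta["offset"])

    try:
        return ThermalFrame(
            pixels=pixels,
            emissivity=float(meta.get("emissivity", DEFAULT_EMISSIVITY)),
            wound_id=str(meta.get("wound_id", "")),
            visit_week=int(meta.get("visit_week", 0)),
        )
    except FrameValidationError as exc:
        raise ThermalIOError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Trace and mask I/O
# ---------------------------------------------------------------------------


def write_trace(trace: PlanimetryTrace, path) -> Path:
    """Write a trace as a two-column CSV (x_cm, y_cm)."""
    path = Path(path)
    df = pd.DataFrame(trace.vertices, columns=["x_cm", "y_cm"])
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_trace(path, wound_id: str = "", visit_week: int = 0) -> PlanimetryTrace:
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    if not {"x_cm", "y_cm"}.issubset(df.columns):
        raise ThermalIOError(f"{path} lacks x_cm/y_cm columns")
    return PlanimetryTrace(
        vertices=df[["x_cm", "y_cm"]].to_numpy(),
        wound_id=wound_id,
        visit_week=visit_week,
    )


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean mask as an 8-bit PNG (0 = background, 255 = wound)."""
    path = Path(path)
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, arr)
    return path


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such file: {path}")
    return np.asarray(iio.imread(path)) > 127


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "wound_id",
    "participant_id",
    "visit_week",
    "frame_path",
    "trace_path",
    "area_cm2",
    "healed_at_week12",
)


class CohortExclusion(NamedTuple):
    wound_id: str
    reason: str


class LoadedCohort(NamedTuple):
    """Result of :func:`read_cohort_table`: kept series plus audited exclusions."""

    series: List[WoundSeries]
    excluded: List[CohortExclusion]


_TRUE = {"1", "true", "yes", "healed"}
_FALSE = {"0", "false", "no", "unhealed"}


def _parse_label(raw, wound_id: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CohortError(f"wound {wound_id}: unparseable healed_at_week12 value {raw!r}")


def read_cohort_table(path) -> LoadedCohort:
    """Load a cohort manifest CSV into per-wound series.

    Rows are grouped by ``wound_id``.  A wound missing any of weeks 0-2 is
    excluded and the exclusion is reported, never silently dropped:
    ``len(series) + len(excluded)`` equals the number of distinct wound ids in
    the file.  Relative frame/trace paths are resolved against the manifest's
    directory.
    """
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"wound_id": str, "participant_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"cohort table lacks columns: {sorted(missing)}")
    base = path.parent

    dup = df.duplicated(subset=["wound_id", "visit_week"])
    if dup.any():
        first = df.loc[dup, ["wound_id", "visit_week"]].iloc[0]
        raise CohortError(
            f"duplicate visit: wound {first['wound_id']} week {first['visit_week']}"
        )

    series: List[WoundSeries] = []
    excluded: List[CohortExclusion] = []
    for wound_id, group in df.groupby("wound_id", sort=True):
        labels = {_parse_label(v, wound_id) for v in group["healed_at_week12"]}
        if len(labels) != 1:
            raise CohortError(f"wound {wound_id}: conflicting healing labels")
        healed = labels.pop()
        weeks = set(int(w) for w in group["visit_week"])
        if not set(ANALYSIS_WEEKS) <= weeks:
            reason = (
                f"missing weeks {sorted(set(ANALYSIS_WEEKS) - weeks)}; "
                "all of weeks 0-2 are required"
            )
            logger.info("excluding wound %s: %s", wound_id, reason)
            excluded.append(CohortExclusion(str(wound_id), reason))
            continue
        records: Dict[int, VisitRecord] = {}
        for _, row in group.iterrows():
            week = int(row["visit_week"])
            if week not in ANALYSIS_WEEKS:
                logger.info(
                    "wound %s: ignoring extra visit at week %d", wound_id, week
                )
                continue
            frame = trace = None
            if isinstance(row["frame_path"], str) and row["frame_path"].strip():
                frame = read_thermal_frame(base / row["frame_path"])
            if isinstance(row["trace_path"], str) and row["trace_path"].strip():
                trace = read_trace(
                    base / row["trace_path"], wound_id=str(wound_id), visit_week=week
                )
            area = row["area_cm2"]
            area = float(area) if pd.notna(area) else None
            records[week] = VisitRecord(
                wound_id=str(wound_id),
                participant_id=str(row["participant_id"]),
                visit_week=week,
                frame=frame,
                trace=trace,
                area_cm2=area,
            )
        series.append(
            WoundSeries(wound_id=str(wound_id), records=records, healed_at_week12=healed)
        )
    return LoadedCohort(series, excluded)
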