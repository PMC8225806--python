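"""Mask-aware grey-level co-occurrence matrices and the 12 texture features.

The co-occurrence matrix P counts how often a pixel at quantized level i sits
at a fixed offset from a pixel at level j, with both pixels inside the wound
mask; pairs touching background or the frame edge contribute nothing.  Four
offsets are used (horizontal, both diagonals, vertical), accumulated
symmetrically, normalized, and averaged into one matrix before the features
are computed.  That ordering makes the direction-averaged feature vector
exactly invariant under 90-degree rotation of frame and mask.

Quantization uses the min-max range of the *in-mask* temperatures, so every
feature is invariant under affine temperature maps T -> a*T + b (a > 0):
ambient shifts and gain changes do not alter the texture description.

The 12 features carry the letter codes a-l used throughout the package's
tables and loading plots:

====== ========================== =================================================
letter name                       formula on the averaged normalized P (0-based i,j)
====== ========================== =================================================
a      asm                        sum p^2
b      contrast                   sum (i-j)^2 p
c      idm                        sum p / (1 + (i-j)^2)
d      entropy                    -sum p log2 p
e      correlation                (sum i*j*p - mu_x mu_y) / (sigma_x sigma_y)
f      sum_of_squares_variance    sum (i - mu_x)^2 p
g      sum_average                sum k p_{x+y}(k)
h      sum_entropy                -sum p_{x+y} log2 p_{x+y}
i      difference_entropy         -sum p_{x-y} log2 p_{x-y}
j      inertia                    identical to contrast (Conners/ITK naming;
                                  the duplication keeps the 12-slot vector and
                                  is acknowledged, the two are collinear)
k      cluster_shade              sum (i + j - mu_x - mu_y)^3 p
l      cluster_prominence         sum (i + j - mu_x - mu_y)^4 p
====== ========================== =================================================

Entropies use log base 2 (bits) with 0*log(0) = 0; correlation is defined as 0
when a marginal variance vanishes, so degenerate masks never yield non-finite
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np

from .errors import DegenerateInputError, DegenerateMaskError
from .preprocess import MIN_WOUND_PIXELS, MaskedFrame, WoundMask, apply_mask
from .thermal_io import ThermalFrame

#: Feature letter codes in list order (a = ASM ... l = cluster prominence).
FEATURE_NAMES: Tuple[Tuple[str, str], ...] = (
    ("a", "asm"),
    ("b", "contrast"),
    ("c", "idm"),
    ("d", "entropy"),
    ("e", "correlation"),
    ("f", "sum_of_squares_variance"),
    ("g", "sum_average"),
    ("h", "sum_entropy"),
    ("i", "difference_entropy"),
    ("j", "inertia"),
    ("k", "cluster_shade"),
    ("l", "cluster_prominence"),
)

#: CSV/table column names, e.g. ``a_asm`` ... ``l_cluster_prominence``.
FEATURE_COLUMNS: Tuple[str, ...] = tuple(f"{c}_{n}" for c, n in FEATURE_NAMES)

N_FEATURES = len(FEATURE_NAMES)

#: Offset (drow, dcol) per direction in degrees; 0 = horizontal, 90 = vertical.
DIRECTIONS: Tuple[int, ...] = (0, 45, 90, 135)
_OFFSETS: Dict[int, Tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass
class QuantizedFrame:
    """In-mask temperatures binned uniformly into ``n_levels`` grey levels.

    ``levels`` is -1 outside the mask.  A constant in-mask region maps to
    level 0 everywhere and is flagged degenerate.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    t_min_mask: float
    t_max_mask: float
    degenerate: bool = False


@dataclass
class GLCMatrix:
    """One co-occurrence matrix; symmetric by construction.

    Unnormalized entries are integer counts summing to ``2 * n_pairs``;
    normalized entries sum to 1.
    """

    P: np.ndarray
    direction: Union[int, str]
    distance: int
    normalized: bool
    n_pairs: int


def quantize(
    masked: MaskedFrame, n_levels: int = 16, min_pixels: int = MIN_WOUND_PIXELS
) -> QuantizedFrame:
    """Uniformly bin in-mask temperatures into ``n_levels`` levels.

    Bins span [t_min_mask, t_max_mask]; the maximum temperature is assigned to
    level ``n_levels - 1``.
    """
    if n_levels < 2:
        raise DegenerateInputError("need at least 2 grey levels")
    vals = masked.in_mask_values
    if vals.size < min_pixels:
        raise DegenerateMaskError(
            f"only {vals.size} in-mask pixels < required {min_pixels}"
        )
    t_min = float(vals.min())
    t_max = float(vals.max())
    levels = np.full(masked.pixels.shape, -1, dtype=np.int32)
    if t_max > t_min:
        lv = np.floor((vals - t_min) / (t_max - t_min) * n_levels).astype(np.int32)
        np.clip(lv, 0, n_levels - 1, out=lv)
        degenerate = False
    else:
        lv = np.zeros(vals.shape, dtype=np.int32)
        degenerate = True
    levels[masked.mask] = lv
    return QuantizedFrame(
        levels=levels,
        mask=masked.mask,
        n_levels=n_levels,
        t_min_mask=t_min,
        t_max_mask=t_max,
        degenerate=degenerate,
    )


def compute_glcm(
    q: QuantizedFrame, distance: int = 1, direction: int = 0
) -> GLCMatrix:
    """Unnormalized symmetric GLCM for one offset direction.

    Each ordered in-mask pixel pair (p, p + offset*distance) increments both
    P[l(p), l(p+offset)] and its transpose entry.
    """
    if direction not in _OFFSETS:
        raise DegenerateInputError(
            f"direction {direction!r} not one of {DIRECTIONS}"
        )
    if distance < 1:
        raise DegenerateInputError("distance must be >= 1")
    dr, dc = _OFFSETS[direction]
    dr *= distance
    dc *= distance
    h, w = q.levels.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise DegenerateInputError(
            f"distance {distance} exceeds frame extent for direction {direction}"
        )

    # core window and its shifted counterpart
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q.levels[r0:r1, c0:c1]
    b = q.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a >= 0) & (b >= 0)
    av = a[valid].astype(np.int64)
    bv = b[valid].astype(np.int64)
    L = q.n_levels
    counts = np.bincount(av * L + bv, minlength=L * L).reshape(L, L)
    P = (counts + counts.T).astype(np.float64)
    return GLCMatrix(
        P=P,
        direction=direction,
        distance=distance,
        normalized=False,
        n_pairs=int(valid.sum()),
    )


def normalize_glcm(g: GLCMatrix) -> GLCMatrix:
    """Divide entries by their total so the matrix sums to 1."""
    if g.normalized:
        return g
    if g.n_pairs < 1:
        raise DegenerateInputError(
            "zero co-occurring pairs: mask too thin for this direction/distance"
        )
    return GLCMatrix(
        P=g.P / g.P.sum(),
        direction=g.direction,
        distance=g.distance,
        normalized=True,
        n_pairs=g.n_pairs,
    )


def average_glcm(glcms: Sequence[GLCMatrix]) -> np.ndarray:
    """Average four normalized directional matrices (canonical pairing order).

    The pairwise summation ``(P0 + P45) + (P90 + P135)`` is what makes the
    90-degree rotation invariance exact in floating point: rotation swaps
    0<->90 and 45<->135, i.e. it swaps the two parenthesized partial sums, and
    floating-point addition is commutative.
    """
    if len(glcms) != 4:
        raise DegenerateInputError("expected the four directional matrices")
    for g in glcms:
        if not g.normalized:
            raise DegenerateInputError("matrices must be normalized first")
    shapes = {g.P.shape for g in glcms}
    if len(shapes) != 1:
        raise DegenerateInputError("matrices have mismatched level counts")
    by_dir = {g.direction: g.P for g in glcms}
    if set(by_dir) != set(DIRECTIONS):
        raise DegenerateInputError(f"need one matrix per direction {DIRECTIONS}")
    return ((by_dir[0] + by_dir[45]) + (by_dir[90] + by_dir[135])) / 4.0


@dataclass
class FeatureVector:
    """The 12 named texture features for one visit; all dimensionless."""

    asm: float
    contrast: float
    idm: float
    entropy: float
    correlation: float
    sum_of_squares_variance: float
    sum_average: float
    sum_entropy: float
    difference_entropy: float
    inertia: float
    cluster_shade: float
    cluster_prominence: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for _, name in FEATURE_NAMES])

    def as_dict(self) -> Dict[str, float]:
        return {col: getattr(self, name) for col, (_, name) in zip(FEATURE_COLUMNS, FEATURE_NAMES)}


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(P: np.ndarray) -> FeatureVector:
    """Compute the 12 features from one normalized symmetric matrix."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise DegenerateInputError("P must be square")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise DegenerateInputError(f"P must be normalized (sums to {total})")
    L = P.shape[0]
    i, j = np.indices((L, L))
    levels = np.arange(L)
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((levels * px).sum())
    var = float(((levels - mu) ** 2 * px).sum())
    sd = np.sqrt(var)

    asm = float((P * P).sum())
    contrast = float((((i - j) ** 2) * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())
    entropy = float(-_xlog2x(P).sum())
    if sd > 0:
        correlation = float(((i * j * P).sum() - mu * mu) / (sd * sd))
    else:
        correlation = 0.0
    ssv = float((((i - mu) ** 2) * P).sum())

    p_sum = np.bincount((i + j).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    sum_average = float((np.arange(2 * L - 1) * p_sum).sum())
    sum_entropy = float(-_xlog2x(p_sum).sum())
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=P.ravel(), minlength=L)
    difference_entropy = float(-_xlog2x(p_diff).sum())

    centered = i + j - 2.0 * mu
    cluster_shade = float(((centered ** 3) * P).sum())
    cluster_prominence = float(((centered ** 4) * P).sum())

    return FeatureVector(
        asm=asm,
        contrast=contrast,
        idm=idm,
        entropy=entropy,
        correlation=correlation,
        sum_of_squares_variance=ssv,
        sum_average=sum_average,
        sum_entropy=sum_entropy,
        difference_entropy=difference_entropy,
        inertia=contrast,
        cluster_shade=cluster_shade,
        cluster_prominence=cluster_prominence,
    )


def haralick_features(glcms: Sequence[GLCMatrix]) -> FeatureVector:
    """Average the four normalized directional matrices, then compute features."""
    return glcm_features(average_glcm(glcms))


def features_from_frame(
    frame: ThermalFrame,
    mask: Union[WoundMask, np.ndarray],
    n_levels: int = 16,
    distance: int = 1,
    min_pixels: int = MIN_WOUND_PIXELS,
) -> FeatureVector:
    """Full per-visit texture chain: quantize, four GLCMs, normalize, features."""
    masked = apply_mask(frame, mask)
    q = quantize(masked, n_levels=n_levels, min_pixels=min_pixels)
    glcms = [
        normalize_glcm(compute_glcm(q, distance=distance, direction=d))
        for d in DIRECTIONS
    ]
    return haralick_features(glcms)
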