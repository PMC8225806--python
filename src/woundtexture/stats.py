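"""Longitudinal statistics: week ratios, PCA, normality gate, group tests.

Wounds differ hugely in absolute texture scale and size, so all longitudinal
comparisons use week-to-week *ratios* (week1/week0, week2/week1, week2/week0)
of each feature and of the area, letting wounds be pooled.  The 12 feature
ratios are standardized and reduced by PCA on the correlation matrix; healed
vs unhealed groups are compared with a Kruskal-Wallis test (nonparametric
branch) or one-way ANOVA with a Tukey simultaneous 95% CI (parametric
branch), the branch chosen by a per-group Anderson-Darling normality gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError
from .texture import FEATURE_COLUMNS, FeatureVector
from .thermal_io import PlanimetryTrace

RATIO_TYPES: Tuple[str, str, str] = ("w1_over_w0", "w2_over_w1", "w2_over_w0")

#: (numerator week, denominator week) per ratio type.
RATIO_WEEKS: Dict[str, Tuple[int, int]] = {
    "w1_over_w0": (1, 0),
    "w2_over_w1": (2, 1),
    "w2_over_w0": (2, 0),
}


# ---------------------------------------------------------------------------
# Planimetry
# ---------------------------------------------------------------------------


def polygon_area(trace: Union[PlanimetryTrace, np.ndarray]) -> float:
    """Polygon area via the shoelace formula; orientation-independent.

    This is the exact continuous limit of counting grid squares inside a
    digitized wound tracing.  Input must be a simple closed polygon with at
    least 3 vertices (validated through :class:`PlanimetryTrace`).
    """
    if not isinstance(trace, PlanimetryTrace):
        trace = PlanimetryTrace(vertices=np.asarray(trace, dtype=float))
    x = trace.vertices[:, 0]
    y = trace.vertices[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


# ---------------------------------------------------------------------------
# Week ratios
# ---------------------------------------------------------------------------


@dataclass
class RatioVector:
    """Week-to-week feature (and area) ratios for one wound.

    ``values`` holds the 12 feature ratios in letter order; entries where the
    denominator is zero or either side is non-finite are non-finite here and
    flagged through ``valid`` -- such wounds are excluded from that ratio
    type's analysis rather than imputed.
    """

    wound_id: str
    ratio_type: str
    values: Optional[np.ndarray]
    area_ratio: Optional[float]
    healed_at_week12: bool
    valid: bool
    finite_mask: Optional[np.ndarray] = None


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def compute_ratios(
    features_by_week: Optional[Dict[int, FeatureVector]] = None,
    areas_by_week: Optional[Dict[int, float]] = None,
    wound_id: str = "",
    healed_at_week12: bool = False,
) -> Dict[str, RatioVector]:
    """Element-wise week ratios of the 12 features and of the area.

    Requires all three analysis weeks.  For every entry where all three
    ratios are finite the chain identity w2/w0 = (w2/w1) * (w1/w0) holds.
    """
    if features_by_week is not None and set(features_by_week) != {0, 1, 2}:
        raise DegenerateInputError("features for weeks 0, 1, 2 are required")
    if areas_by_week is not None and set(areas_by_week) != {0, 1, 2}:
        raise DegenerateInputError("areas for weeks 0, 1, 2 are required")
    if features_by_week is None and areas_by_week is None:
        raise DegenerateInputError("nothing to compute ratios from")

    out: Dict[str, RatioVector] = {}
    for rtype, (num_w, den_w) in RATIO_WEEKS.items():
        values = finite = None
        area_ratio = None
        valid = True
        if features_by_week is not None:
            num = features_by_week[num_w].as_array()
            den = features_by_week[den_w].as_array()
            values = _safe_ratio(num, den)
            finite = np.isfinite(values)
            valid = valid and bool(finite.all())
        if areas_by_week is not None:
            den_a = areas_by_week[den_w]
            if den_a != 0 and np.isfinite(den_a) and np.isfinite(areas_by_week[num_w]):
                area_ratio = float(areas_by_week[num_w] / den_a)
            else:
                area_ratio = None
                valid = False
        out[rtype] = RatioVector(
            wound_id=wound_id,
            ratio_type=rtype,
            values=values,
            area_ratio=area_ratio,
            healed_at_week12=healed_at_week12,
            valid=valid,
            finite_mask=finite,
        )
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the feature-ratio table.

    Loadings are unit-norm, mutually orthogonal columns, oriented so the
    loading of feature j (inertia) is >= 0 -- eigenvector signs are arbitrary
    and this convention makes loadings, scores and group orderings
    reproducible across runs.  ``scores = standardized data @ loadings``.
    """

    loadings: pd.DataFrame  # retained features x 2
    scores: np.ndarray  # n x 2
    explained_variance_fraction: np.ndarray  # (2,)
    mean: pd.Series
    std: pd.Series
    dropped: List[str] = field(default_factory=list)

    def transform(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        """Project new observations using the stored standardization."""
        if isinstance(X, np.ndarray):
            X = pd.DataFrame(X, columns=list(self.mean.index) + self.dropped)
        Z = (X[self.loadings.index] - self.mean) / self.std
        return Z.to_numpy() @ self.loadings.to_numpy()


def fit_pca(
    ratio_matrix: Union[pd.DataFrame, np.ndarray],
    feature_names: Sequence[str] = FEATURE_COLUMNS,
    n_components: int = 2,
) -> PCAResult:
    """PCA of z-scored feature ratios via the correlation-matrix eigenproblem.

    The 12 features live on wildly different scales (entropies in bits,
    cluster prominence in fourth powers of grey levels), so the correlation
    matrix -- not the raw covariance -- is decomposed.  Constant columns are
    dropped with a warning.  Needs n >= 3 observations.
    """
    if isinstance(ratio_matrix, np.ndarray):
        ratio_matrix = pd.DataFrame(ratio_matrix, columns=list(feature_names))
    X = ratio_matrix.astype(float)
    n = len(X)
    if n < 3:
        raise DegenerateInputError(f"PCA needs at least 3 observations, got {n}")
    mean = X.mean()
    std = X.std(ddof=1)
    dropped = list(X.columns[std == 0])
    if dropped:
        warnings.warn(
            f"dropping constant feature columns from PCA: {dropped}", stacklevel=2
        )
    keep = [c for c in X.columns if c not in dropped]
    if len(keep) < n_components:
        raise DegenerateInputError("not enough non-constant columns for PCA")
    Z = ((X[keep] - mean[keep]) / std[keep]).to_numpy()
    R = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    W = eigvecs[:, :n_components].copy()
    ref = keep.index("j_inertia") if "j_inertia" in keep else None
    for c in range(n_components):
        col = W[:, c]
        pivot = col[ref] if ref is not None and col[ref] != 0 else col[np.nonzero(col)[0][0]]
        if pivot < 0:
            W[:, c] = -col

    evr = eigvals[:n_components] / eigvals.sum()
    loadings = pd.DataFrame(
        W, index=keep, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    return PCAResult(
        loadings=loadings,
        scores=Z @ W,
        explained_variance_fraction=evr,
        mean=mean[keep],
        std=std[keep],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


class GroupStats(NamedTuple):
    median: float
    mean: float
    sd: float
    n: int


def _group_stats(x: np.ndarray) -> GroupStats:
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
    return GroupStats(float(np.median(x)), float(np.mean(x)), sd, len(x))


def anderson_darling_pvalue(x: Sequence[float]) -> float:
    """Anderson-Darling normality p-value, mean and variance estimated.

    Uses the Stephens small-sample correction ``A* = A2 (1 + 0.75/n +
    2.25/n^2)`` and the standard piecewise-exponential tail approximation
    (the same formulas behind R's ``nortest::ad.test``).  A constant sample
    returns 0.0 (maximally non-normal).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise DegenerateInputError("Anderson-Darling needs n >= 3")
    if np.std(x) == 0:
        return 0.0
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    logcdf = sps.norm.logcdf(z)
    logsf = sps.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n)
    z = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if z >= 0.6:
        p = np.exp(1.2937 - 5.709 * z + 0.0186 * z ** 2)
    elif z >= 0.34:
        p = np.exp(0.9177 - 4.279 * z - 1.38 * z ** 2)
    elif z >= 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * z - 59.938 * z ** 2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * z - 223.73 * z ** 2)
    return float(min(max(p, 0.0), 1.0))


@dataclass
class NormalityGate:
    """Per-group normality p-values and the resulting test-family decision."""

    p_values: Dict[str, float]
    decision: str  # "parametric" or "nonparametric"
    alpha: float


def normality_gate(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> NormalityGate:
    """Anderson-Darling test per group; nonparametric if any group rejects."""
    p_values = {name: anderson_darling_pvalue(vals) for name, vals in groups.items()}
    decision = "nonparametric" if any(p < alpha for p in p_values.values()) else "parametric"
    return NormalityGate(p_values=p_values, decision=decision, alpha=alpha)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """One healed-vs-unhealed comparison row (test, statistic, p, CI, stats)."""

    test: str  # "kruskal_wallis" or "anova_tukey"
    healed_stats: GroupStats
    unhealed_stats: GroupStats
    statistic: float  # H or F
    p_value: float
    tukey_ci_95: Optional[Tuple[float, float]] = None
    normality_p: Optional[Dict[str, float]] = None


def kruskal_wallis(
    healed: Sequence[float], unhealed: Sequence[float]
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H for two groups, p from chi2 with 1 df."""
    healed = np.asarray(healed, dtype=float)
    unhealed = np.asarray(unhealed, dtype=float)
    if len(healed) < 1 or len(unhealed) < 1 or len(healed) + len(unhealed) < 3:
        raise DegenerateInputError("need n >= 1 per group and total n >= 3")
    pooled = np.concatenate([healed, unhealed])
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # all observations tied: no evidence of any difference
    else:
        h, p = sps.kruskal(healed, unhealed)
    return GroupComparison(
        test="kruskal_wallis",
        healed_stats=_group_stats(healed),
        unhealed_stats=_group_stats(unhealed),
        statistic=float(h),
        p_value=float(p),
    )


def anova_tukey(
    healed: Sequence[float], unhealed: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with a Tukey simultaneous CI for (unhealed - healed).

    F has (1, n-2) degrees of freedom.  The Tukey interval uses the
    studentized range q with 2 groups, which reduces to the pooled-t interval
    (q = sqrt(2) * t).  Reported healed-subtracted.  With zero within-group
    variance and equal means, F is undefined and reported as NaN.
    """
    healed = np.asarray(healed, dtype=float)
    unhealed = np.asarray(unhealed, dtype=float)
    n1, n2 = len(healed), len(unhealed)
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("ANOVA needs n >= 2 per group")
    n = n1 + n2
    m1, m2 = healed.mean(), unhealed.mean()
    ssw = float(((healed - m1) ** 2).sum() + ((unhealed - m2) ** 2).sum())
    grand = (n1 * m1 + n2 * m2) / n
    ssb = float(n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2)
    diff = float(m2 - m1)
    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p, ci = float("nan"), float("nan"), (diff, diff)
        else:
            f_stat, p, ci = float("inf"), 0.0, (diff, diff)
    else:
        msw = ssw / (n - 2)
        f_stat = ssb / msw
        p = float(sps.f.sf(f_stat, 1, n - 2))
        # studentized range with k = 2: q_{1-a,2,df} = sqrt(2) * t_{1-a/2,df},
        # so the Tukey interval reduces to the pooled-t interval exactly
        tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, n - 2))
        half = tcrit * np.sqrt(msw * (1.0 / n1 + 1.0 / n2))
        ci = (diff - half, diff + half)
    return GroupComparison(
        test="anova_tukey",
        healed_stats=_group_stats(healed),
        unhealed_stats=_group_stats(unhealed),
        statistic=float(f_stat),
        p_value=p,
        tukey_ci_95=ci,
    )


class IntervalSummary(NamedTuple):
    mean: float
    ci_half_width: float
    median: float
    sd: float
    n: int


def interval_summary(
    groups: Dict[str, Sequence[float]], confidence: float = 0.95
) -> Dict[str, IntervalSummary]:
    """Per-group mean with a t-based CI half-width, plus median and sd."""
    out: Dict[str, IntervalSummary] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        n = len(x)
        if n < 2:
            raise DegenerateInputError(f"group {name!r} needs n >= 2")
        sd = float(np.std(x, ddof=1))
        tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
        out[name] = IntervalSummary(
            mean=float(x.mean()),
            ci_half_width=tcrit * sd / np.sqrt(n),
            median=float(np.median(x)),
            sd=sd,
            n=n,
        )
    return out


# ---------------------------------------------------------------------------
# Healing prediction (extension beyond the group-difference inference)
# ---------------------------------------------------------------------------


@dataclass
class HealingPrediction:
    """Midpoint-threshold classification of PCA1 scores.

    This operationalizes the observed group difference as a per-wound
    predictor; it is an extension of the underlying analysis, which only
    establishes a group-level difference, and is labelled as such.
    """

    threshold: Optional[float]
    predicted_healed: Optional[np.ndarray]  # None when the model abstains
    healed_mean: float
    unhealed_mean: float

    @property
    def abstained(self) -> bool:
        return self.predicted_healed is None


def predict_healing(
    pca1_scores: Sequence[float],
    labels: Sequence[bool],
    method: str = "group_midpoint",
    scores_to_classify: Optional[Sequence[float]] = None,
) -> HealingPrediction:
    """Threshold PCA1 at the midpoint of the two group means.

    Wounds on the healed-mean side of the threshold are predicted healed;
    the orientation is read off the group means, so the classifier is
    indifferent to the sign convention of :func:`fit_pca`.  Degenerate
    inputs (all scores equal) abstain.
    """
    if method != "group_midpoint":
        raise DegenerateInputError(f"unknown method {method!r}")
    scores = np.asarray(pca1_scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise DegenerateInputError("both groups are required to set a threshold")
    m_h = float(scores[labels].mean())
    m_u = float(scores[~labels].mean())
    target = scores if scores_to_classify is None else np.asarray(
        scores_to_classify, dtype=float
    )
    if m_h == m_u:
        return HealingPrediction(
            threshold=None, predicted_healed=None, healed_mean=m_h, unhealed_mean=m_u
        )
    thr = (m_h + m_u) / 2.0
    if m_h < m_u:
        pred = target < thr
    else:
        pred = target > thr
    return HealingPrediction(
        threshold=thr, predicted_healed=pred, healed_mean=m_h, unhealed_mean=m_u
    )
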