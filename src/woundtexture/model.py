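"""Model/results objects for the healed-vs-unhealed trajectory analysis.

:class:`HealingTrajectoryModel` is built from a per-visit feature table (or
directly from a cohort of :class:`~woundtexture.thermal_io.WoundSeries`) and
``fit(ratio_type)`` runs one week-ratio contrast end to end: week ratios,
correlation PCA of the 12 feature ratios, the Anderson-Darling normality
gate, and healed-vs-unhealed comparisons for the three measurement arms
(planimetry area, thermal-mask area, PCA1 of texture ratios).  The returned
:class:`HealingTrajectoryResults` carries every estimate plus a
``summary()`` table, in the spirit of statsmodels model/results pairs.

Example
-------
>>> from woundtexture import synthetic, model
>>> cohort = synthetic.generate_cohort(synthetic.SyntheticCohortConfig(seed=1))
>>> res = model.HealingTrajectoryModel.from_cohort(cohort).fit("w2_over_w0")
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as wstats
from .errors import DegenerateInputError
from .extraction import (
    ExtractionExclusion,
    ExtractionSettings,
    TABLE_COLUMNS,
    extract_feature_table,
)
from .stats import (
    GroupComparison,
    HealingPrediction,
    NormalityGate,
    PCAResult,
    RATIO_TYPES,
    RATIO_WEEKS,
)
from .texture import FEATURE_COLUMNS
from .thermal_io import WoundSeries

ARMS = ("planimetry_area", "thermal_area", "pca1_texture")


@dataclass
class ArmResult:
    """One measurement arm's healed-vs-unhealed comparison.

    Both tests are computed for transparency; ``selected`` names the one the
    normality gate chose (Kruskal-Wallis when any group rejects normality,
    ANOVA + Tukey otherwise).
    """

    arm: str
    gate: Optional[NormalityGate]
    kruskal: GroupComparison
    anova: Optional[GroupComparison]
    selected_test: str  # "kruskal_wallis" or "anova_tukey"
    n_healed: int
    n_unhealed: int
    healed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    unhealed_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded_wounds: List[str] = field(default_factory=list)

    @property
    def selected(self) -> GroupComparison:
        if self.selected_test == "anova_tukey" and self.anova is not None:
            return self.anova
        return self.kruskal


@dataclass
class HealingTrajectoryResults:
    """Fitted results for one week-ratio contrast."""

    ratio_type: str
    arms: Dict[str, ArmResult]
    pca: Optional[PCAResult]
    pca1_scores: Optional[pd.DataFrame]  # wound_id, score_pc1, score_pc2, healed
    pca2_anova: Optional[GroupComparison]
    alpha: float
    normality_alpha: float
    excluded: Dict[str, List[str]]  # arm -> wound ids excluded at ratio stage

    def predict(self, method: str = "group_midpoint") -> HealingPrediction:
        """Midpoint-threshold healing prediction from PCA1 scores (extension)."""
        if self.pca1_scores is None:
            raise DegenerateInputError("no PCA scores available to predict from")
        return wstats.predict_healing(
            self.pca1_scores["score_pc1"].to_numpy(),
            self.pca1_scores["healed_at_week12"].to_numpy(dtype=bool),
            method=method,
        )

    def summary(self) -> str:
        """Plain-text summary table of all arms of this contrast."""
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append(f"Healing trajectory analysis -- ratio {self.ratio_type}")
        lines.append("=" * w)
        header = (
            f"{'arm':<16}{'test':<15}{'n(h/u)':<9}{'healed med':>11}"
            f"{'unheal med':>11}{'stat':>9}{'p':>9}"
        )
        lines.append(header)
        lines.append("-" * w)
        for name in ARMS:
            res = self.arms.get(name)
            if res is None:
                continue
            sel = res.selected
            stat_name = "H" if sel.test == "kruskal_wallis" else "F"
            lines.append(
                f"{name:<16}{sel.test:<15}"
                f"{res.n_healed}/{res.n_unhealed:<6}"
                f"{sel.healed_stats.median:>11.3f}"
                f"{sel.unhealed_stats.median:>11.3f}"
                f"{sel.statistic:>9.3f}{sel.p_value:>9.4f}"
            )
            if sel.tukey_ci_95 is not None:
                lo, hi = sel.tukey_ci_95
                lines.append(
                    f"{'':<16}Tukey 95% CI (unhealed - healed): "
                    f"[{lo:.3f}, {hi:.3f}]   ({stat_name} test)"
                )
        if self.pca is not None:
            lines.append("-" * w)
            ev = self.pca.explained_variance_fraction
            lines.append(
                f"PCA on {len(self.pca.loadings)} feature ratios: "
                f"PC1 {ev[0]:.1%}, PC2 {ev[1]:.1%} of variance"
            )
            top = self.pca.loadings["PC1"].abs().sort_values(ascending=False)
            lines.append(
                "largest |PC1| loadings: "
                + ", ".join(f"{k} ({self.pca.loadings.loc[k, 'PC1']:+.2f})" for k in top.index[:5])
            )
        lines.append("=" * w)
        return "\n".join(lines)


def _arm_from_groups(
    arm: str,
    healed: np.ndarray,
    unhealed: np.ndarray,
    alpha: float,
    normality_alpha: float,
    excluded: Sequence[str] = (),
) -> ArmResult:
    gate = None
    if len(healed) >= 3 and len(unhealed) >= 3:
        gate = wstats.normality_gate(
            {"healed": healed, "unhealed": unhealed}, alpha=normality_alpha
        )
    kruskal = wstats.kruskal_wallis(healed, unhealed)
    anova = None
    if len(healed) >= 2 and len(unhealed) >= 2:
        anova = wstats.anova_tukey(healed, unhealed, alpha=alpha)
    if gate is not None and gate.decision == "parametric" and anova is not None:
        selected = "anova_tukey"
    else:
        selected = "kruskal_wallis"
    for comp in (kruskal, anova):
        if comp is not None and gate is not None:
            comp.normality_p = dict(gate.p_values)
    return ArmResult(
        arm=arm,
        gate=gate,
        kruskal=kruskal,
        anova=anova,
        selected_test=selected,
        n_healed=len(healed),
        n_unhealed=len(unhealed),
        healed_values=np.asarray(healed, dtype=float),
        unhealed_values=np.asarray(unhealed, dtype=float),
        excluded_wounds=list(excluded),
    )


class HealingTrajectoryModel:
    """Longitudinal healed-vs-unhealed model over a per-visit feature table.

    Parameters
    ----------
    feature_table : DataFrame
        One row per wound-week with the columns of
        :data:`woundtexture.extraction.TABLE_COLUMNS`.  All three analysis
        weeks must be present per wound; wounds with missing weeks raise.
    exclusions : list, optional
        Extraction-stage exclusions to carry through into reports.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        exclusions: Optional[List[ExtractionExclusion]] = None,
    ) -> None:
        missing = set(TABLE_COLUMNS) - set(feature_table.columns)
        if missing:
            raise DegenerateInputError(f"feature table lacks columns {sorted(missing)}")
        df = feature_table.copy()
        df["visit_week"] = df["visit_week"].astype(int)
        bad = [
            wid
            for wid, g in df.groupby("wound_id")
            if set(g["visit_week"]) != {0, 1, 2}
        ]
        if bad:
            raise DegenerateInputError(
                f"wounds without exactly weeks 0-2 in the table: {bad[:5]}"
            )
        if df.empty:
            raise DegenerateInputError("empty feature table")
        self.feature_table = df
        self.exclusions = list(exclusions or [])
        labels = df.groupby("wound_id")["healed_at_week12"].nunique()
        if (labels > 1).any():
            raise DegenerateInputError("conflicting healing labels in feature table")

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[WoundSeries],
        settings: Optional[ExtractionSettings] = None,
    ) -> "HealingTrajectoryModel":
        """Run preprocessing + texture extraction, then build the model."""
        table, excluded = extract_feature_table(cohort, settings)
        if table.empty:
            raise DegenerateInputError(
                "no wounds survived extraction: "
                + "; ".join(f"{e.wound_id}: {e.reason}" for e in excluded[:5])
            )
        return cls(table, exclusions=excluded)

    # -- ratio assembly ----------------------------------------------------

    def _ratio_frame(self, ratio_type: str) -> pd.DataFrame:
        """Per-wound ratios of features and areas for one ratio type."""
        num_w, den_w = RATIO_WEEKS[ratio_type]
        df = self.feature_table.set_index(["wound_id", "visit_week"]).sort_index()
        value_cols = ["planimetry_area_cm2", "thermal_area_px", *FEATURE_COLUMNS]
        num = df.xs(num_w, level="visit_week")[value_cols]
        den = df.xs(den_w, level="visit_week")[value_cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = num / den.replace(0.0, np.nan)
        ratios["healed_at_week12"] = (
            df.xs(0, level="visit_week")["healed_at_week12"].astype(bool)
        )
        return ratios

    def fit(
        self,
        ratio_type: str = "w2_over_w0",
        alpha: float = 0.05,
        normality_alpha: float = 0.05,
    ) -> HealingTrajectoryResults:
        """Fit one week-ratio contrast and return its results object."""
        if ratio_type not in RATIO_TYPES:
            raise DegenerateInputError(
                f"ratio_type {ratio_type!r} not one of {RATIO_TYPES}"
            )
        ratios = self._ratio_frame(ratio_type)
        healed_mask = ratios["healed_at_week12"]

        arms: Dict[str, ArmResult] = {}
        excluded: Dict[str, List[str]] = {}

        for arm, col in (
            ("planimetry_area", "planimetry_area_cm2"),
            ("thermal_area", "thermal_area_px"),
        ):
            vals = ratios[col]
            ok = np.isfinite(vals)
            excluded[arm] = sorted(ratios.index[~ok])
            if ok.sum() == 0 or vals[ok & healed_mask].empty or vals[ok & ~healed_mask].empty:
                continue
            arms[arm] = _arm_from_groups(
                arm,
                vals[ok & healed_mask].to_numpy(),
                vals[ok & ~healed_mask].to_numpy(),
                alpha,
                normality_alpha,
                excluded[arm],
            )

        pca = None
        pca_scores_df = None
        pca2_anova = None
        feat = ratios[list(FEATURE_COLUMNS)]
        ok = np.isfinite(feat).all(axis=1)
        excluded["pca1_texture"] = sorted(ratios.index[~ok])
        feat_ok = feat[ok]
        labels_ok = healed_mask[ok].to_numpy(dtype=bool)
        if len(feat_ok) >= 3 and labels_ok.any() and (~labels_ok).any():
            pca = wstats.fit_pca(feat_ok)
            pca_scores_df = pd.DataFrame(
                {
                    "wound_id": feat_ok.index,
                    "score_pc1": pca.scores[:, 0],
                    "score_pc2": pca.scores[:, 1],
                    "healed_at_week12": labels_ok,
                }
            ).reset_index(drop=True)
            arms["pca1_texture"] = _arm_from_groups(
                "pca1_texture",
                pca.scores[labels_ok, 0],
                pca.scores[~labels_ok, 0],
                alpha,
                normality_alpha,
                excluded["pca1_texture"],
            )
            if labels_ok.sum() >= 2 and (~labels_ok).sum() >= 2:
                pca2_anova = wstats.anova_tukey(
                    pca.scores[labels_ok, 1], pca.scores[~labels_ok, 1], alpha=alpha
                )

        if not arms:
            raise DegenerateInputError(
                f"no arm could be analysed for ratio {ratio_type}"
            )
        return HealingTrajectoryResults(
            ratio_type=ratio_type,
            arms=arms,
            pca=pca,
            pca1_scores=pca_scores_df,
            pca2_anova=pca2_anova,
            alpha=alpha,
            normality_alpha=normality_alpha,
            excluded=excluded,
        )

    def fit_all(
        self,
        ratio_types: Sequence[str] = RATIO_TYPES,
        alpha: float = 0.05,
        normality_alpha: float = 0.05,
    ) -> Dict[str, HealingTrajectoryResults]:
        """Fit every requested ratio contrast (each is an independent fit)."""
        return {
            rt: self.fit(rt, alpha=alpha, normality_alpha=normality_alpha)
            for rt in ratio_types
        }
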