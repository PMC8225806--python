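"""End-to-end orchestration: cohort -> features -> statistics -> report bundle.

The pipeline has two stages that can run monolithically (``run``) or split
(``features`` then ``stats``); the split path produces a bit-identical
report.  Every report embeds the parsed configuration verbatim, the seed and
the package version, and lists every excluded wound with its reason --
cohort attrition is an auditable part of the method.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateInputError, WoundTextureError
from .extraction import ExtractionSettings, extract_feature_table
from .model import HealingTrajectoryModel, HealingTrajectoryResults
from .stats import RATIO_TYPES
from .synthetic import SyntheticCohortConfig, TrajectoryParams, generate_cohort
from .texture import DIRECTIONS, FEATURE_COLUMNS
from .thermal_io import WoundSeries, read_cohort_table

logger = logging.getLogger(__name__)

_ANALYSIS_DEFAULTS = dict(
    n_levels=16,
    glcm_distance=1,
    morphology_radius=2,
    min_wound_pixels=64,
    normality_alpha=0.05,
    test_alpha=0.05,
    ratio_types=list(RATIO_TYPES),
    seed=0,
    qc_images=False,
    log_level="INFO",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``raw`` preserves the parsed config-file content exactly as read; it is
    embedded verbatim in every report for provenance.
    """

    n_levels: int = 16
    glcm_distance: int = 1
    morphology_radius: int = 2
    min_wound_pixels: int = 64
    normality_alpha: float = 0.05
    test_alpha: float = 0.05
    ratio_types: List[str] = field(default_factory=lambda: list(RATIO_TYPES))
    seed: int = 0
    qc_images: bool = False
    log_level: str = "INFO"
    manifest: Optional[str] = None
    synthetic: Optional[SyntheticCohortConfig] = None
    outdir: str = "report"
    base_dir: Path = field(default_factory=Path)
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_levels < 2 or self.n_levels > 256:
            raise WoundTextureError("n_levels must be in [2, 256]")
        if self.glcm_distance < 1:
            raise WoundTextureError("glcm_distance must be >= 1")
        if self.morphology_radius < 0:
            raise WoundTextureError("morphology_radius must be >= 0")
        if self.min_wound_pixels < 1:
            raise WoundTextureError("min_wound_pixels must be >= 1")
        for a in (self.normality_alpha, self.test_alpha):
            if not (0.0 < a < 1.0):
                raise WoundTextureError("alpha levels must be in (0, 1)")
        bad = set(self.ratio_types) - set(RATIO_TYPES)
        if bad:
            raise WoundTextureError(f"unknown ratio types: {sorted(bad)}")
        if not self.raw:
            self.raw = self.to_raw()

    def to_raw(self) -> dict:
        analysis = {k: getattr(self, k) for k in _ANALYSIS_DEFAULTS}
        inputs: dict = {"outdir": self.outdir}
        if self.manifest is not None:
            inputs["manifest"] = self.manifest
        if self.synthetic is not None:
            params = dataclasses.asdict(self.synthetic.params)
            inputs["synthetic"] = {
                "n_healed": self.synthetic.n_healed,
                "n_unhealed": self.synthetic.n_unhealed,
                "seed": self.synthetic.seed,
                "params": params,
            }
        return {"analysis": analysis, "inputs": inputs}

    @property
    def extraction_settings(self) -> ExtractionSettings:
        return ExtractionSettings(
            n_levels=self.n_levels,
            glcm_distance=self.glcm_distance,
            morphology_radius=self.morphology_radius,
            min_wound_pixels=self.min_wound_pixels,
        )

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "PipelineConfig":
        analysis = dict(raw.get("analysis") or {})
        inputs = dict(raw.get("inputs") or {})
        unknown = set(analysis) - set(_ANALYSIS_DEFAULTS)
        if unknown:
            raise WoundTextureError(f"unknown analysis keys: {sorted(unknown)}")
        kwargs = {**_ANALYSIS_DEFAULTS, **analysis}
        synthetic = None
        if "synthetic" in inputs and inputs["synthetic"] is not None:
            syn = dict(inputs["synthetic"])
            params = TrajectoryParams(**(syn.get("params") or {}))
            synthetic = SyntheticCohortConfig(
                n_healed=int(syn.get("n_healed", 17)),
                n_unhealed=int(syn.get("n_unhealed", 55)),
                params=params,
                seed=int(syn.get("seed", kwargs["seed"])),
            )
        return cls(
            manifest=inputs.get("manifest"),
            synthetic=synthetic,
            outdir=inputs.get("outdir", "report"),
            base_dir=Path(base_dir),
            raw=raw,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a YAML (or JSON -- valid YAML) config file."""
        path = Path(path)
        if not path.exists():
            raise WoundTextureError(f"no such config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=path.parent)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_raw(), fh, sort_keys=True)
        return path


# ---------------------------------------------------------------------------
# JSON sanitation (deterministic, NaN-free reports)
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def _comparison_dict(comp) -> Optional[dict]:
    if comp is None:
        return None
    d = {
        "test": comp.test,
        "statistic": comp.statistic,
        "p_value": comp.p_value,
        "healed": comp.healed_stats._asdict(),
        "unhealed": comp.unhealed_stats._asdict(),
    }
    if comp.tukey_ci_95 is not None:
        d["tukey_ci_95"] = list(comp.tukey_ci_95)
    if comp.normality_p is not None:
        d["normality_p"] = comp.normality_p
    return d


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    from scipy.stats import t as _t

    ci_half = float(_t.ppf(0.975, n - 1) * sd / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(lo),
        "whisker_hi": float(hi),
        "mean": mean,
        "sd": sd,
        "ci95_half_width": ci_half,
        "n": n,
    }


# ---------------------------------------------------------------------------
# Analysis stage (shared by monolithic run and the staged stats command)
# ---------------------------------------------------------------------------


class AnalysisOutput(NamedTuple):
    report: dict
    tables: Dict[str, pd.DataFrame]
    boxplots: dict
    results: Dict[str, HealingTrajectoryResults]


def analyze_features(
    features: pd.DataFrame,
    config: PipelineConfig,
    exclusions: Sequence[dict] = (),
) -> AnalysisOutput:
    """Statistics stage: ratios, PCA, group comparisons, report assembly.

    ``exclusions`` are upstream (loader/extraction) exclusion records carried
    into the report.
    """
    model = HealingTrajectoryModel(features)
    results = model.fit_all(
        ratio_types=config.ratio_types,
        alpha=config.test_alpha,
        normality_alpha=config.normality_alpha,
    )

    wounds = features.groupby("wound_id")["healed_at_week12"].first()
    arms_report: Dict[str, dict] = {}
    pca_report: Dict[str, dict] = {}
    comparison_rows = []
    boxplots: Dict[str, dict] = {}
    tables: Dict[str, pd.DataFrame] = {"features": features}

    for rt, res in sorted(results.items()):
        arms_report[rt] = {}
        boxplots[rt] = {}
        for arm_name, arm in sorted(res.arms.items()):
            sel = arm.selected
            arms_report[rt][arm_name] = {
                "selected_test": arm.selected_test,
                "n_healed": arm.n_healed,
                "n_unhealed": arm.n_unhealed,
                "gate": None
                if arm.gate is None
                else {"p_values": arm.gate.p_values, "decision": arm.gate.decision},
                "kruskal_wallis": _comparison_dict(arm.kruskal),
                "anova_tukey": _comparison_dict(arm.anova),
                "excluded_wounds": arm.excluded_wounds,
            }
            comparison_rows.append(
                {
                    "ratio_type": rt,
                    "arm": arm_name,
                    "selected_test": arm.selected_test,
                    "n_healed": arm.n_healed,
                    "n_unhealed": arm.n_unhealed,
                    "healed_median": sel.healed_stats.median,
                    "healed_mean": sel.healed_stats.mean,
                    "healed_sd": sel.healed_stats.sd,
                    "unhealed_median": sel.unhealed_stats.median,
                    "unhealed_mean": sel.unhealed_stats.mean,
                    "unhealed_sd": sel.unhealed_stats.sd,
                    "statistic": sel.statistic,
                    "p_value": sel.p_value,
                    "tukey_ci_lo": sel.tukey_ci_95[0] if sel.tukey_ci_95 else np.nan,
                    "tukey_ci_hi": sel.tukey_ci_95[1] if sel.tukey_ci_95 else np.nan,
                }
            )
            boxplots[rt][arm_name] = {
                "healed": _box_stats(arm.healed_values),
                "unhealed": _box_stats(arm.unhealed_values),
            }
        if res.pca is not None:
            pca_report[rt] = {
                "explained_variance_fraction": list(
                    res.pca.explained_variance_fraction
                ),
                "dropped_features": res.pca.dropped,
                "loadings": {
                    feat: list(res.pca.loadings.loc[feat])
                    for feat in res.pca.loadings.index
                },
                "pca2_anova": _comparison_dict(res.pca2_anova),
            }
            tables[f"loadings_{rt}"] = res.pca.loadings.rename_axis("feature").reset_index()
            tables[f"scores_{rt}"] = res.pca1_scores

    tables["comparisons"] = pd.DataFrame(comparison_rows)

    prediction = None
    if "w2_over_w0" in results and results["w2_over_w0"].pca1_scores is not None:
        pred = results["w2_over_w0"].predict()
        if not pred.abstained:
            labels = results["w2_over_w0"].pca1_scores["healed_at_week12"].to_numpy(
                dtype=bool
            )
            correct = pred.predicted_healed == labels
            sens = float(correct[labels].mean())
            spec = float(correct[~labels].mean())
            prediction = {
                "method": "group_midpoint",
                "note": "per-wound classification is an extension beyond the "
                "group-difference inference",
                "threshold": pred.threshold,
                "healed_mean_pc1": pred.healed_mean,
                "unhealed_mean_pc1": pred.unhealed_mean,
                "balanced_accuracy_in_sample": (sens + spec) / 2.0,
            }

    report = {
        "package": "woundtexture",
        "version": __version__,
        "config": config.raw,
        "seed": config.seed,
        "cohort": {
            "n_wounds": int(len(wounds)),
            "n_healed": int(wounds.sum()),
            "n_unhealed": int((1 - wounds).sum()),
            "excluded": list(exclusions),
        },
        "structural": {
            "n_texture_features": len(FEATURE_COLUMNS),
            "n_glcm_directions": len(DIRECTIONS),
            "n_pca_components": 2,
        },
        "arms": arms_report,
        "pca": pca_report,
        "prediction": prediction,
    }
    return AnalysisOutput(_jsonable(report), tables, _jsonable(boxplots), results)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _load_series(config: PipelineConfig) -> Tuple[List[WoundSeries], List[dict]]:
    if config.manifest is not None:
        manifest = config.base_dir / config.manifest
        loaded = read_cohort_table(manifest)
        excl = [
            {"wound_id": e.wound_id, "stage": "cohort_loading", "reason": e.reason}
            for e in loaded.excluded
        ]
        return loaded.series, excl
    if config.synthetic is not None:
        return generate_cohort(config.synthetic), []
    raise WoundTextureError("config provides neither a manifest nor a synthetic cohort")


def extract_stage(
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, List[dict], List[WoundSeries]]:
    """Stage 1: resolve inputs and extract the per-visit feature table."""
    series, exclusions = _load_series(config)
    if not series:
        raise WoundTextureError("no wounds survive cohort loading")
    table, extraction_excl = extract_feature_table(series, config.extraction_settings)
    exclusions = exclusions + [
        {
            "wound_id": e.wound_id,
            "stage": "feature_extraction",
            "week": e.visit_week,
            "reason": e.reason,
        }
        for e in extraction_excl
    ]
    if table.empty:
        raise WoundTextureError(
            "no wounds survive feature extraction; first reason: "
            + (exclusions[-1]["reason"] if exclusions else "unknown")
        )
    return table, exclusions, series


def write_report_bundle(
    outdir: Path, output: AnalysisOutput, exclusions: Sequence[dict]
) -> Path:
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(output.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, df in output.tables.items():
        df.to_csv(outdir / "tables" / f"{name}.csv", index=False)
    with open(outdir / "boxplots.json", "w") as fh:
        json.dump(output.boxplots, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "tables" / "features_meta.json", "w") as fh:
        json.dump({"excluded": _jsonable(list(exclusions))}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report_path


def render_qc_images(
    series: Sequence[WoundSeries], outdir: Path, config: PipelineConfig
) -> None:
    """Per-wound QC strips (normalized frame, mask, masked frame per week)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .preprocess import normalize_thermal, segment_wound

    qcdir = Path(outdir) / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    for s in series:
        weeks = sorted(s.records)
        fig, axes = plt.subplots(3, len(weeks), figsize=(3 * len(weeks), 7))
        axes = np.atleast_2d(axes)
        for k, week in enumerate(weeks):
            rec = s.records[week]
            if rec.frame is None:
                for r in range(3):
                    axes[r, k].axis("off")
                continue
            norm = normalize_thermal(rec.frame)
            axes[0, k].imshow(norm.values, cmap="gray")
            axes[0, k].set_title(f"week {week}")
            try:
                mask = segment_wound(
                    rec.frame,
                    min_wound_pixels=config.min_wound_pixels,
                    morphology_radius=config.morphology_radius,
                )
                axes[1, k].imshow(mask.mask, cmap="gray")
                shown = np.where(mask.mask, rec.frame.pixels, np.nan)
                axes[2, k].imshow(shown, cmap="inferno")
            except WoundTextureError:
                axes[1, k].text(0.5, 0.5, "no mask", ha="center")
            for r in range(3):
                axes[r, k].axis("off")
        fig.suptitle(f"{s.wound_id} ({'healed' if s.healed_at_week12 else 'unhealed'})")
        fig.tight_layout()
        fig.savefig(qcdir / f"{s.wound_id}.png", dpi=72)
        plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full analysis and write the report bundle; returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(outdir) if outdir is not None else config.base_dir / config.outdir
    table, exclusions, series = extract_stage(config)
    output = analyze_features(table, config, exclusions)
    write_report_bundle(outdir, output, exclusions)
    if config.qc_images:
        render_qc_images(series, outdir, config)
    logger.info("report written to %s", outdir)
    return output.report


# ---------------------------------------------------------------------------
# Replicate studies (power / type-I error of the PCA1 contrast)
# ---------------------------------------------------------------------------


class RejectionStudy(NamedTuple):
    """Rejection frequencies of the ANOVA on PCA1 over seeded replicates."""

    rates: Dict[str, float]
    n_valid: int
    n_replicates: int


def rejection_study(
    cohort_config: SyntheticCohortConfig,
    n_replicates: int,
    ratio_types: Sequence[str] = ("w2_over_w0",),
    alpha: float = 0.05,
    seed: int = 0,
    settings: Optional[ExtractionSettings] = None,
) -> RejectionStudy:
    """Frequency with which ANOVA on PCA1 rejects, over seeded cohorts.

    Each replicate generates a fresh cohort (seed derived from ``seed`` and
    the replicate counter), runs extraction and the model fit, and tests the
    PCA1 scores with one-way ANOVA at level ``alpha``.  Replicates where a
    whole group drops out (extraction failure) are excluded from the
    denominator and counted in ``n_replicates - n_valid``.
    """
    rejections = {rt: 0 for rt in ratio_types}
    n_valid = 0
    for r in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0]
            % (2 ** 31)
        )
        cfg = dataclasses.replace(cohort_config, seed=rep_seed)
        try:
            cohort = generate_cohort(cfg)
            table, _ = extract_feature_table(cohort, settings)
            model = HealingTrajectoryModel(table)
            pvals = {}
            for rt in ratio_types:
                res = model.fit(rt, alpha=alpha)
                arm = res.arms.get("pca1_texture")
                if arm is None or arm.anova is None:
                    raise DegenerateInputError("PCA1 ANOVA unavailable")
                pvals[rt] = arm.anova.p_value
        except WoundTextureError:
            continue
        n_valid += 1
        for rt, p in pvals.items():
            if p < alpha:
                rejections[rt] += 1
    rates = {
        rt: (rejections[rt] / n_valid if n_valid else float("nan"))
        for rt in ratio_types
    }
    return RejectionStudy(rates=rates, n_valid=n_valid, n_replicates=n_replicates)
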