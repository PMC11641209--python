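"""End-to-end workflows: analyze one cohort, compare two cohorts.

``run_analyze`` takes a cohort of worms through side assignment,
identification (unless the input labels are trusted), the minimum-pair
filter, per-side plane fits and the inter-plane angle.  ``run_compare`` runs
two cohorts and adds the one-way ANOVA on angles, the per-rank distance
regressions and the within-rank permutation test on the slope-difference
statistic.  Both return plain JSON-serialisable dicts that embed the
resolved configuration and seed, and log every dropped worm with a
machine-readable reason (``too_few_pairs`` or ``degenerate_geometry``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import (
    DegenerateGeometryError,
    EmptyCohortError,
    InsufficientPointsError,
    ValidationError,
)
from .geometry import dihedral_opening, fit_plane, plane_angle
from .neuron_id import AmphidClassifier, count_pairs
from .samples import WormSample
from . import stats as _stats

__all__ = ["AnalysisConfig", "analyze_worm", "run_analyze", "run_compare"]

logger = logging.getLogger("amphid")


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved analysis settings.

    Defaults follow the study protocol where one exists: worms with fewer
    than 4 complete bilateral pairs are excluded, and the permutation null
    uses 10,000 resamples.  ``alternative`` fixes the tail of the
    slope-difference test (see :mod:`amphid.stats`); ``identification`` is
    ``"auto"`` (run the rule cascade) or ``"trust_labels"`` (use the class
    and side columns as given).
    """

    min_pairs: int = 4
    n_perm: int = 10000
    seed: int = 0
    alternative: str = "greater"
    pooling: str = "pooled"
    collinearity_tol_um: float = 2.0
    ambiguity_margin: float = 1.1
    identification: str = "auto"
    midline_eps_um: float = 0.1

    def __post_init__(self) -> None:
        if self.identification not in ("auto", "trust_labels"):
            raise ValidationError(f"unknown identification mode {self.identification!r}")
        if self.pooling not in ("pooled", "per_worm"):
            raise ValidationError(f"unknown pooling mode {self.pooling!r}")
        if self.min_pairs < 1:
            raise ValidationError("min_pairs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat YAML config; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def classifier(self) -> AmphidClassifier:
        return AmphidClassifier(
            collinearity_tol_um=self.collinearity_tol_um,
            ambiguity_margin=self.ambiguity_margin,
            midline_eps_um=self.midline_eps_um,
        ).fit()


def analyze_worm(worm: WormSample, config: AnalysisConfig) -> dict:
    """Process one worm; returns a record with its angle or a drop reason."""
    if config.identification == "auto":
        worm = config.classifier().label_sample(worm)
    record = {"worm_id": worm.worm_id, "strain": worm.strain, "kept": False}
    n_pairs = count_pairs(worm)
    record["n_pairs"] = n_pairs
    if n_pairs < config.min_pairs:
        record["drop_reason"] = "too_few_pairs"
        return record
    try:
        fits = {side: fit_plane(worm.points(side=side)) for side in ("L", "R")}
    except (InsufficientPointsError, DegenerateGeometryError):
        record["drop_reason"] = "degenerate_geometry"
        return record
    record.update(
        kept=True,
        angle_deg=plane_angle(fits["L"], fits["R"]),
        opening=dihedral_opening(fits["L"], fits["R"]),
        rms_residual_um={s: f.rms_residual for s, f in fits.items()},
        labeled_worm=worm,
    )
    return record


def run_analyze(cohort: list[WormSample], config: AnalysisConfig | None = None) -> dict:
    """Analyze one cohort; per-worm angles plus cohort mean +/- SD."""
    import numpy as np

    config = config or AnalysisConfig()
    if not cohort:
        raise EmptyCohortError("empty cohort")
    records = [analyze_worm(w, config) for w in cohort]
    for r in records:
        if not r["kept"]:
            logger.warning("worm %s dropped: %s", r["worm_id"], r["drop_reason"])
    kept = [r for r in records if r["kept"]]
    if not kept:
        raise EmptyCohortError("all worms were dropped; nothing to analyze")
    angles = np.array([r["angle_deg"] for r in kept])
    labeled = [r.pop("labeled_worm") for r in kept]
    for r in records:
        r.pop("labeled_worm", None)
    return {
        "strain": cohort[0].strain,
        "condition": cohort[0].condition,
        "n_worms": len(cohort),
        "n_kept": len(kept),
        "n_dropped": len(records) - len(kept),
        "dropped": [
            {"worm_id": r["worm_id"], "reason": r["drop_reason"]} for r in records if not r["kept"]
        ],
        "angles_deg": [round(float(a), 2) for a in angles],
        "angle_mean_deg": round(float(angles.mean()), 2),
        "angle_sd_deg": round(float(angles.std(ddof=1)), 2) if len(angles) > 1 else 0.0,
        "worms": records,
        "config": config.to_dict(),
        "_labeled_cohort": labeled,
    }


def run_compare(
    cohort_a: list[WormSample], cohort_b: list[WormSample], config: AnalysisConfig | None = None
) -> dict:
    """Compare two cohorts: ANOVA on angles, rank regressions, permutation test."""
    config = config or AnalysisConfig()
    rep_a = run_analyze(cohort_a, config)
    rep_b = run_analyze(cohort_b, config)
    labeled_a = rep_a.pop("_labeled_cohort")
    labeled_b = rep_b.pop("_labeled_cohort")
    label_a = rep_a["strain"] or "a"
    label_b = rep_b["strain"] or "b"
    if label_a == label_b:
        label_a, label_b = f"{label_a}_a", f"{label_b}_b"
    anova = _stats.angle_anova({label_a: rep_a["angles_deg"], label_b: rep_b["angles_deg"]})
    table_a = _stats.build_rank_table(labeled_a, label=label_a)
    table_b = _stats.build_rank_table(labeled_b, label=label_b)
    reg_a = _stats.cohort_regression(table_a, pooling=config.pooling)
    reg_b = _stats.cohort_regression(table_b, pooling=config.pooling)
    perm = _stats.permutation_test(
        table_a, table_b, n_perm=config.n_perm, seed=config.seed, alternative=config.alternative
    )
    return {
        "cohorts": {label_a: rep_a, label_b: rep_b},
        "anova": dataclasses.asdict(anova),
        "rank_means_um": {
            label_a: _stats.rank_means(table_a, config.pooling),
            label_b: _stats.rank_means(table_b, config.pooling),
        },
        "regression_slopes_um_per_rank": {label_a: reg_a.slope, label_b: reg_b.slope},
        "slope_difference": {
            "observed_um_per_rank": perm.observed,
            "p_value": perm.p_value,
            "alternative": perm.alternative,
            "null_percentile_5": perm.percentile_5,
            "null_percentile_95": perm.percentile_95,
            "n_perm": perm.n_perm,
            "seed": perm.seed,
        },
        "pair_distances": {
            label_a: table_a.records.to_dict(orient="list"),
            label_b: table_b.records.to_dict(orient="list"),
        },
        "config": config.to_dict(),
    }
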