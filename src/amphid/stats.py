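"""Rank-distance regression and resampling inference.

Bilateral pair distances are pooled by the dorso-ventral rank of the neuron
class (1 = ventral ... 6 = dorsal) and summarised per cohort by an ordinary
least-squares line through the per-rank mean distances.  Two cohorts are
compared by the *slope-difference statistic*: per common rank, the mutant
mean distance is subtracted from the reference (WT) mean, and an OLS line is
fitted to those differences against rank — its slope is the observed
statistic.  Its null distribution is built by shuffling all distances within
each rank and reassigning them to the two cohorts preserving the original
per-rank group sizes (a stratified permutation; an optional with-replacement
bootstrap mode exists for sensitivity analysis).

One-sided direction.  The alternative of interest is a mutant whose inner
dorso-ventral ranks (2-4) are more separated than the reference.  Because
those ranks sit below the midpoint of the rank axis, such an effect pushes
the reference-minus-mutant slope *positive*, so the one-sided test of that
alternative is upper-tailed (``alternative="greater"``, the default);
``"less"`` and ``"two-sided"`` are available.

Per-worm angles are compared across strains by a standard one-way
fixed-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateRegressionError, EmptyCohortError, ValidationError
from .neuron_id import assign_rank
from .samples import WormSample
from .template import RANK_MAP

__all__ = [
    "RankDistanceTable",
    "RegressionFit",
    "PermutationResult",
    "AnovaResult",
    "build_rank_table",
    "rank_means",
    "cohort_regression",
    "slope_difference",
    "permutation_test",
    "angle_anova",
]


@dataclass(frozen=True)
class RankDistanceTable:
    """Bilateral pair distances of one cohort, tagged by class rank.

    ``records`` has columns ``worm_id``, ``neuron_class``, ``rank``,
    ``distance_um`` with one row per complete bilateral pair.
    """

    label: str
    records: pd.DataFrame


@dataclass(frozen=True)
class RegressionFit:
    """OLS line through the per-rank mean distances."""

    slope: float  # µm per rank unit
    intercept: float  # µm
    rank_means: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PermutationResult:
    """Observed slope-difference statistic and its resampling null."""

    observed: float
    null_slopes: np.ndarray
    p_value: float
    percentile_5: float
    percentile_95: float
    n_perm: int
    seed: int
    alternative: str


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA over per-worm angles (degrees)."""

    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_sizes: dict[str, int]


def build_rank_table(cohort: list[WormSample], label: str = "") -> RankDistanceTable:
    """One distance per complete bilateral pair, tagged with the class rank.

    Classes identified on only one side of a worm are skipped.  Worms are
    expected to be labeled and already filtered for the minimum pair count.
    """
    if not cohort:
        raise EmptyCohortError("cannot build a rank table from an empty cohort")
    rows = []
    for worm in cohort:
        df = worm.nuclei
        for cls in RANK_MAP:
            pair = df[df["class"] == cls]
            left = pair[pair["side"] == "L"]
            right = pair[pair["side"] == "R"]
            if len(left) != 1 or len(right) != 1:
                continue
            d = float(
                np.linalg.norm(
                    left[["ap_um", "dv_um", "ml_um"]].to_numpy(float)[0]
                    - right[["ap_um", "dv_um", "ml_um"]].to_numpy(float)[0]
                )
            )
            rows.append(
                {"worm_id": worm.worm_id, "neuron_class": cls, "rank": assign_rank(cls), "distance_um": d}
            )
    label = label or (cohort[0].strain if cohort else "")
    return RankDistanceTable(label=label, records=pd.DataFrame(rows, columns=["worm_id", "neuron_class", "rank", "distance_um"]))


def rank_means(table: RankDistanceTable, pooling: str = "pooled") -> dict[int, float]:
    """Mean distance per rank.

    ``pooled`` (default) averages all pair distances of a rank across worms;
    ``per_worm`` first averages within each worm, then across worms.
    """
    df = table.records
    if df.empty:
        return {}
    if pooling == "pooled":
        m = df.groupby("rank")["distance_um"].mean()
    elif pooling == "per_worm":
        m = df.groupby(["rank", "worm_id"])["distance_um"].mean().groupby("rank").mean()
    else:
        raise ValidationError(f"unknown pooling mode {pooling!r}")
    return {int(r): float(v) for r, v in m.items()}


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    return slope, float(ybar - slope * xbar)


def cohort_regression(table: RankDistanceTable, pooling: str = "pooled") -> RegressionFit:
    """OLS of the per-rank mean distances on the rank values present."""
    means = rank_means(table, pooling)
    if len(means) < 2:
        raise DegenerateRegressionError("regression requires >= 2 distinct ranks")
    ranks = np.array(sorted(means), dtype=float)
    y = np.array([means[int(r)] for r in ranks])
    slope, intercept = _ols(ranks, y)
    return RegressionFit(slope=slope, intercept=intercept, rank_means=means)


def _common_rank_weights(wt_means: dict, mut_means: dict) -> tuple[list[int], np.ndarray]:
    common = sorted(set(wt_means) & set(mut_means))
    if len(common) < 2:
        raise DegenerateRegressionError("slope difference requires >= 2 common ranks")
    r = np.array(common, dtype=float)
    w = (r - r.mean()) / ((r - r.mean()) ** 2).sum()
    return common, w


def slope_difference(wt: RankDistanceTable, mut: RankDistanceTable, pooling: str = "pooled") -> float:
    """Slope of the per-rank (reference minus mutant) mean distances on rank.

    Antisymmetric under swapping the cohorts; equal to the difference of the
    two cohorts' own regression slopes whenever both cover the same ranks.
    """
    wt_m, mut_m = rank_means(wt, pooling), rank_means(mut, pooling)
    common, w = _common_rank_weights(wt_m, mut_m)
    d = np.array([wt_m[r] - mut_m[r] for r in common])
    return float(w @ d)


def permutation_test(
    wt: RankDistanceTable,
    mut: RankDistanceTable,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "permutation",
) -> PermutationResult:
    """Within-rank stratified resampling test of the slope-difference statistic.

    Each resample pools the two cohorts' distances within every rank,
    shuffles them (``method="permutation"``; ``"bootstrap"`` draws with
    replacement) and reassigns them to the cohorts preserving the original
    per-rank group sizes, then recomputes the statistic.  The p-value uses
    the add-one convention ``(1 + #extreme) / (n_perm + 1)`` in the direction
    of ``alternative``, so it is never zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if method not in ("permutation", "bootstrap"):
        raise ValidationError(f"unknown method {method!r}")
    wt_m, mut_m = rank_means(wt), rank_means(mut)
    common, w = _common_rank_weights(wt_m, mut_m)
    observed = float(w @ np.array([wt_m[r] - mut_m[r] for r in common]))

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for r, wr in zip(common, w):
        a = wt.records.loc[wt.records["rank"] == r, "distance_um"].to_numpy(float)
        b = mut.records.loc[mut.records["rank"] == r, "distance_um"].to_numpy(float)
        pooled = np.concatenate([a, b])
        n1, m = len(a), len(pooled)
        if method == "permutation":
            mat = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        else:
            mat = pooled[rng.integers(0, m, size=(n_perm, m))]
        d_r = mat[:, :n1].mean(axis=1) - mat[:, n1:].mean(axis=1)
        null += wr * d_r

    if alternative == "less":
        extreme = np.count_nonzero(null <= observed)
    elif alternative == "greater":
        extreme = np.count_nonzero(null >= observed)
    else:
        extreme = np.count_nonzero(np.abs(null) >= abs(observed))
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null_slopes=null,
        p_value=float(p),
        percentile_5=float(np.percentile(null, 5.0)),
        percentile_95=float(np.percentile(null, 95.0)),
        n_perm=int(n_perm),
        seed=int(seed),
        alternative=alternative,
    )


def angle_anova(groups: dict[str, "np.ndarray | list[float]"]) -> AnovaResult:
    """One-way fixed-effects ANOVA on per-worm inter-plane angles (degrees)."""
    if len(groups) < 2:
        raise ValidationError("ANOVA requires >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 values")
    f, p = sps.f_oneway(*arrays.values())
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sds={k: float(a.std(ddof=1)) for k, a in arrays.items()},
        group_sizes={k: int(a.size) for k, a in arrays.items()},
    )
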