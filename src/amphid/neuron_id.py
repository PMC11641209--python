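"""Automated identification of the amphid neuron classes.

Experimenters identify the twelve-ish amphid nuclei by eye from stereotyped
positional, size and expression cues.  This module encodes those cues as a
deterministic rule cascade over one lateral side's segmented nuclei:

1. **Dorsal triplet** — the three most dorsal nuclei, verified to be nearly
   collinear, are ASK, ADL and ASI; their anterior-to-posterior order fixes
   which is which.
2. **ASH** — among the remainder, the nucleus on the ventral half with the
   largest size x intensity product.
3. **Ventral neighbours of ASH** — classified by the direction of their
   offset from ASH: ventro-posterior is ASJ, ventro-anterior is AWC, and
   posterior at similar dorso-ventral height is ASE.
4. **Middle four** — of the nuclei dorsal to ASH, the brightest of the
   posterior pair is ASG and the brightest of the anterior pair is ADF; of
   the remaining two, the larger and more medial is AWA, the smaller and
   more lateral AWB.

Every comparative rule carries an ambiguity margin: when the best and the
runner-up score are too close (ratio below ``ambiguity_margin``), or a
direction falls too close to a sector boundary, the contested nuclei are
labeled ``UNIDENTIFIED`` rather than guessed.  Unidentified nuclei are
excluded from plane fits and pair distances downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import NoRankError, ValidationError
from .samples import WormSample
from .template import RANK_MAP, UNIDENTIFIED

__all__ = [
    "AmphidClassifier",
    "split_sides",
    "identify_side",
    "assign_rank",
    "count_pairs",
    "filter_worm",
    "label_worm",
]

_FEATURES = ["ap_um", "dv_um", "ml_um", "size", "intensity"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in _FEATURES if c not in X.columns]
        if missing:
            raise ValidationError(f"missing feature columns: {missing}")
        return X[_FEATURES].astype(float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(_FEATURES):
        raise ValidationError(f"expected (n, {len(_FEATURES)}) features, got shape {X.shape}")
    return pd.DataFrame(X, columns=_FEATURES)


def _line_max_deviation(pts: np.ndarray) -> float:
    """Max perpendicular distance of points to their own total-least-squares line."""
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c - np.outer(c @ vt[0], vt[0])
    return float(np.linalg.norm(proj, axis=1).max())


class AmphidClassifier(BaseEstimator):
    """Rule-based classifier assigning amphid class labels to nuclei.

    Stateless in the sklearn sense (``fit`` only validates parameters); all
    knowledge lives in the rules.  ``predict`` takes the nuclei of **one
    worm** as rows of ``(ap_um, dv_um, ml_um, size, intensity)`` and returns
    a class label per nucleus (``UNIDENTIFIED`` where no unambiguous
    assignment exists).

    Parameters
    ----------
    collinearity_tol_um : float, default 2.0
        Maximum perpendicular deviation (µm) of the three most dorsal nuclei
        from their joint line for the dorsal-triplet rule to fire.
    ambiguity_margin : float, default 1.1
        Minimum ratio of best to runner-up score for a comparative rule to
        commit; below it the contested nuclei stay unidentified.
    sector_boundary_deg : float, default -25.0
        Direction (degrees in the AP-DV plane, 0 = posterior, positive =
        dorsal) separating the ASE sector from the ASJ sector.
    sector_tol_deg : float, default 5.0
        Nuclei whose direction from ASH falls within this tolerance of a
        sector boundary are left unidentified.
    dorsal_band_um : float, default 1.5
        Nuclei more than this far dorsal of ASH are treated as the "middle
        four" group rather than as ASH's ventral neighbours.
    midline_eps_um : float, default 0.1
        Half-width of the midline dead zone for side assignment.
    """

    def __init__(
        self,
        collinearity_tol_um: float = 2.0,
        ambiguity_margin: float = 1.1,
        sector_boundary_deg: float = -25.0,
        sector_tol_deg: float = 5.0,
        dorsal_band_um: float = 1.5,
        midline_eps_um: float = 0.1,
    ):
        self.collinearity_tol_um = collinearity_tol_um
        self.ambiguity_margin = ambiguity_margin
        self.sector_boundary_deg = sector_boundary_deg
        self.sector_tol_deg = sector_tol_deg
        self.dorsal_band_um = dorsal_band_um
        self.midline_eps_um = midline_eps_um

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X=None, y=None) -> "AmphidClassifier":
        if self.ambiguity_margin < 1.0:
            raise ValidationError("ambiguity_margin must be >= 1")
        if self.collinearity_tol_um <= 0 or self.sector_tol_deg < 0:
            raise ValidationError("tolerances must be positive")
        self.is_fitted_ = True
        return self

    # -- side assignment ----------------------------------------------------
    def predict_sides(self, X) -> np.ndarray:
        """Assign 'L'/'R' ('' near the midline) by a median split of ML.

        A cloud lying entirely on one side of the recorded midline (all ML
        coordinates of one sign) triggers a degenerate-split warning and is
        assigned wholesale to that side.
        """
        df = _as_frame(X)
        ml = df["ml_um"].to_numpy()
        if len(ml) < 2:
            raise ValidationError("side assignment requires >= 2 nuclei")
        if ml.min() > 0 or ml.max() < 0:
            side = "R" if ml.min() > 0 else "L"
            warnings.warn(
                f"all nuclei lie on one side of the midline; assigning all to {side}",
                stacklevel=2,
            )
            return np.full(len(ml), side, dtype=object)
        mid = float(np.median(ml))
        out = np.where(ml < mid, "L", "R").astype(object)
        out[np.abs(ml - mid) < self.midline_eps_um] = ""
        return out

    # -- per-side identification --------------------------------------------
    def predict_side(self, X) -> np.ndarray:
        """Class labels for the nuclei of one lateral side."""
        df = _as_frame(X)
        n = len(df)
        if not 1 <= n <= 12:
            raise ValidationError(f"a side should carry 1..12 nuclei, got {n}")
        labels = pd.Series(UNIDENTIFIED, index=df.index, dtype=object)
        pool = list(df.index)

        # Step 1: dorsal triplet ASK/ADL/ASI.
        if len(pool) >= 3:
            by_dv = df.loc[pool, "dv_um"].sort_values(ascending=False)
            trip = list(by_dv.index[:3])
            pts = df.loc[trip, ["ap_um", "dv_um", "ml_um"]].to_numpy()
            if _line_max_deviation(pts) < self.collinearity_tol_um:
                order = df.loc[trip, "ap_um"].sort_values().index
                labels[order[0]], labels[order[1]], labels[order[2]] = "ASK", "ADL", "ASI"
            for i in trip:
                pool.remove(i)

        # Step 2: ASH = max size*intensity on the ventral half of the rest.
        if not pool:
            return labels.to_numpy()
        dv_pool = df.loc[pool, "dv_um"]
        ventral = [i for i in pool if dv_pool[i] < float(dv_pool.median())]
        if not ventral:
            return labels.to_numpy()
        score = (df.loc[ventral, "size"] * df.loc[ventral, "intensity"]).sort_values(ascending=False)
        if len(score) >= 2 and score.iloc[0] / score.iloc[1] < self.ambiguity_margin:
            pool.remove(score.index[0])
            pool.remove(score.index[1])
            return labels.to_numpy()  # ASH contested: dependent steps cannot run
        ash = score.index[0]
        labels[ash] = "ASH"
        pool.remove(ash)

        # Step 3: ASJ / AWC / ASE by direction from ASH.
        d_ap = df.loc[pool, "ap_um"] - df.at[ash, "ap_um"]
        d_dv = df.loc[pool, "dv_um"] - df.at[ash, "dv_um"]
        near = [i for i in pool if d_dv[i] < self.dorsal_band_um]
        sectors: dict[str, list] = {"ASJ": [], "AWC": [], "ASE": []}
        for i in near:
            phi = float(np.degrees(np.arctan2(d_dv[i], d_ap[i])))
            if min(abs(abs(phi) - 90.0), abs(phi - self.sector_boundary_deg)) < self.sector_tol_deg:
                pass  # too close to a sector boundary: leave unidentified
            elif abs(phi) > 90.0:
                sectors["AWC"].append(i)
            elif phi >= self.sector_boundary_deg:
                sectors["ASE"].append(i)
            else:
                sectors["ASJ"].append(i)
            pool.remove(i)
        for name, members in sectors.items():
            if len(members) == 1:
                labels[members[0]] = name

        # Step 4: the middle four (dorsal of ASH): ASG, ADF, then AWA/AWB.
        if len(pool) == 4:
            ap_order = df.loc[pool, "ap_um"].sort_values().index
            anterior, posterior = list(ap_order[:2]), list(ap_order[2:])
            rest = []
            for name, pair in (("ADF", anterior), ("ASG", posterior)):
                inten = df.loc[pair, "intensity"].sort_values(ascending=False)
                if inten.iloc[0] / inten.iloc[1] >= self.ambiguity_margin:
                    labels[inten.index[0]] = name
                    rest.append(inten.index[1])
            if len(rest) == 2:
                med = df.loc[rest, "size"] / np.abs(df.loc[rest, "ml_um"])
                med = med.sort_values(ascending=False)
                if med.iloc[0] / med.iloc[1] >= self.ambiguity_margin:
                    labels[med.index[0]], labels[med.index[1]] = "AWA", "AWB"
        return labels.to_numpy()

    def predict(self, X) -> np.ndarray:
        """Class labels for one worm's nuclei (both sides, split internally)."""
        df = _as_frame(X)
        sides = self.predict_sides(df)
        out = np.full(len(df), UNIDENTIFIED, dtype=object)
        for side in ("L", "R"):
            mask = sides == side
            if mask.sum() == 0:
                continue
            sub = df.loc[df.index[mask]]
            if len(sub) > 12:  # keep the 12 largest nuclei as candidates
                sub = sub.sort_values("size", ascending=False).iloc[:12]
            lab = pd.Series(UNIDENTIFIED, index=df.index[mask], dtype=object)
            lab.loc[sub.index] = self.predict_side(sub)
            out[mask] = lab.to_numpy()
        return out

    def label_sample(self, worm: WormSample) -> WormSample:
        """Return a copy of ``worm`` with ``side`` and ``class`` assigned."""
        nuclei = worm.nuclei.copy()
        sides = self.predict_sides(nuclei)
        nuclei["side"] = sides
        nuclei["class"] = UNIDENTIFIED
        for side in ("L", "R"):
            mask = nuclei["side"] == side
            if mask.sum() == 0:
                continue
            sub = nuclei.loc[mask]
            if len(sub) > 12:
                sub = sub.sort_values("size", ascending=False).iloc[:12]
            lab = pd.Series(UNIDENTIFIED, index=nuclei.index[mask], dtype=object)
            lab.loc[sub.index] = self.predict_side(sub)
            nuclei.loc[mask, "class"] = lab
        nuclei.loc[nuclei["side"] == "", "class"] = UNIDENTIFIED
        return WormSample(worm.worm_id, worm.strain, worm.condition, nuclei)


# -- thin functional wrappers -----------------------------------------------

def split_sides(nuclei: pd.DataFrame, midline_eps_um: float = 0.1) -> pd.DataFrame:
    """Return a copy of a nucleus frame with the ``side`` column assigned."""
    clf = AmphidClassifier(midline_eps_um=midline_eps_um).fit()
    out = nuclei.copy()
    out["side"] = clf.predict_sides(nuclei)
    return out


def identify_side(nuclei: pd.DataFrame, **params) -> pd.DataFrame:
    """Label the nuclei of one lateral side; see :class:`AmphidClassifier`."""
    clf = AmphidClassifier(**params).fit()
    out = nuclei.copy()
    out["class"] = clf.predict_side(nuclei)
    return out


def label_worm(worm: WormSample, **params) -> WormSample:
    """Split sides and identify classes for one worm."""
    return AmphidClassifier(**params).fit().label_sample(worm)


def assign_rank(neuron_class: str) -> int:
    """Dorso-ventral rank (1 ventral .. 6 dorsal) of an amphid class."""
    try:
        return RANK_MAP[neuron_class]
    except KeyError:
        raise NoRankError(f"no dorso-ventral rank for class {neuron_class!r}") from None


def count_pairs(worm: WormSample) -> int:
    """Number of classes identified on both sides of this worm."""
    df = worm.nuclei
    left = set(df.loc[df["side"] == "L", "class"]) & set(RANK_MAP)
    right = set(df.loc[df["side"] == "R", "class"]) & set(RANK_MAP)
    return len(left & right)


def filter_worm(worm: WormSample, min_pairs: int = 4) -> bool:
    """Keep a worm iff it has at least ``min_pairs`` complete bilateral pairs."""
    return count_pairs(worm) >= min_pairs
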