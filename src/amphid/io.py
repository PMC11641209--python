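"""Reading and writing the package's file formats.

The ingestion boundary is a flat **nucleus-table CSV** (UTF-8, comma
separated, ``.`` decimal) with one row per segmented nucleus and columns::

    worm_id, strain, condition, nucleus_id, class, side,
    ap_um, dv_um, ml_um, size, intensity

``class`` may be one of the amphid class names, ``UNIDENTIFIED``, or empty
(unlabeled); ``side`` is ``L``, ``R``, or empty.  Upstream of this boundary
sits nuclear segmentation of confocal stacks, which is outside this package:
see :func:`convert_segmentation` for the expected adapter.

Ground truth from the synthetic generator is written as a companion CSV
(``worm_id, nucleus_id, true_class, true_side``) with the generative
parameters in a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .samples import CONDITIONS, NUCLEUS_COLUMNS, WormSample
from .synthetic import GroundTruth, LayoutParams
from .template import RANK_MAP, UNIDENTIFIED

__all__ = [
    "read_nucleus_table",
    "write_nucleus_table",
    "write_ground_truth",
    "write_params",
    "read_params",
    "convert_segmentation",
]

_ALL_COLUMNS = ("worm_id", "strain", "condition") + NUCLEUS_COLUMNS
_COORD_COLUMNS = ("ap_um", "dv_um", "ml_um", "size", "intensity")
_VALID_CLASSES = set(RANK_MAP) | {UNIDENTIFIED, ""}


def read_nucleus_table(path: str | Path) -> list[WormSample]:
    """Parse a nucleus-table CSV into one :class:`WormSample` per worm.

    Raises :class:`ValidationError` on missing columns, non-numeric
    coordinates, unknown class strings (naming the offending row), or
    duplicate ``(worm_id, nucleus_id)`` keys.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in _COORD_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric value in column {col!r}: {exc}") from None
    bad = df.index[~df["class"].isin(_VALID_CLASSES)]
    if len(bad):
        row = int(bad[0]) + 2  # 1-based, counting the header line
        raise ValidationError(f"{path}: unknown class {df.loc[bad[0], 'class']!r} at row {row}")
    bad_side = df.index[~df["side"].isin(["L", "R", ""])]
    if len(bad_side):
        row = int(bad_side[0]) + 2
        raise ValidationError(f"{path}: invalid side {df.loc[bad_side[0], 'side']!r} at row {row}")
    dup = df.duplicated(subset=["worm_id", "nucleus_id"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["worm_id", "nucleus_id"]].tolist()
        raise ValidationError(f"{path}: duplicate (worm_id, nucleus_id) = {tuple(key)}")
    worms = []
    for worm_id, grp in df.groupby("worm_id", sort=False):
        strain = grp["strain"].iloc[0]
        condition = grp["condition"].iloc[0]
        if condition not in CONDITIONS:
            raise ValidationError(f"{path}: unknown condition {condition!r} for worm {worm_id}")
        worms.append(
            WormSample(
                worm_id=str(worm_id),
                strain=strain,
                condition=condition,
                nuclei=grp[list(NUCLEUS_COLUMNS)].reset_index(drop=True),
            )
        )
    return worms


def write_nucleus_table(cohort: list[WormSample], path: str | Path, include_labels: bool = True) -> None:
    """Write a cohort as a nucleus-table CSV.

    With ``include_labels=False`` the ``class`` and ``side`` columns are
    blanked, producing the unlabeled input an identification run expects.
    """
    frames = []
    for worm in cohort:
        f = worm.nuclei.copy()
        f.insert(0, "worm_id", worm.worm_id)
        f.insert(1, "strain", worm.strain)
        f.insert(2, "condition", worm.condition)
        if not include_labels:
            f["class"] = ""
            f["side"] = ""
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)[list(_ALL_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.6g")


def write_ground_truth(truths: list[GroundTruth], path: str | Path) -> None:
    """Write the generator's true labels as a companion CSV."""
    frames = []
    for t in truths:
        f = t.labels.copy()
        f.insert(0, "worm_id", t.worm_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_params(params: LayoutParams, path: str | Path) -> None:
    """JSON sidecar with the generative parameters."""
    d = dataclasses.asdict(params)
    d["rank_displacement"] = {str(k): v for k, v in d["rank_displacement"].items()}
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_params(path: str | Path) -> LayoutParams:
    d = json.loads(Path(path).read_text())
    d["rank_displacement"] = {int(k): float(v) for k, v in d.get("rank_displacement", {}).items()}
    return LayoutParams(**d)


def convert_segmentation(*args, **kwargs):
    """Adapter stub for upstream nuclear-segmentation output.

    Segmentation of confocal stacks into nuclear centroids is performed by
    external tools; this package starts from centroid tables.  A site
    integrating such a tool should implement this function to emit the
    nucleus-table CSV columns documented in this module.
    """
    raise NotImplementedError(
        "segmentation output conversion is site-specific; produce the "
        "nucleus-table CSV described in amphid.io and use read_nucleus_table"
    )
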