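"""In-memory containers for segmented-nucleus data.

A worm's segmented nuclei travel through the pipeline as a
:class:`pandas.DataFrame` with one row per nucleus and the columns in
:data:`NUCLEUS_COLUMNS` (coordinates in µm, size in consistent volume units,
intensity in arbitrary units; ``class`` is one of the amphid class names,
``UNIDENTIFIED``, or ``""`` for unlabeled; ``side`` is ``"L"``, ``"R"``, or
``""``).  :class:`WormSample` bundles the frame with the animal's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["NUCLEUS_COLUMNS", "CONDITIONS", "WormSample"]

#: Per-nucleus columns, in canonical order (worm-level fields excluded).
NUCLEUS_COLUMNS = ("nucleus_id", "class", "side", "ap_um", "dv_um", "ml_um", "size", "intensity")

#: Recognised imaging conditions.
CONDITIONS = ("microfluidic", "agar_pad")


@dataclass
class WormSample:
    """All segmented nuclei of one animal plus its metadata.

    Attributes
    ----------
    worm_id
        Unique animal identifier within a cohort.
    strain
        Strain label (e.g. ``"WT"``, ``"unc-13(s69)"``); non-empty.
    condition
        Imaging condition, ``"microfluidic"`` or ``"agar_pad"``.
    nuclei
        DataFrame with columns :data:`NUCLEUS_COLUMNS`, one row per nucleus.
    """

    worm_id: str
    strain: str
    condition: str = "microfluidic"
    nuclei: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(NUCLEUS_COLUMNS)))

    def __post_init__(self) -> None:
        if not self.strain:
            raise ValueError("strain must be non-empty")
        missing = set(NUCLEUS_COLUMNS) - set(self.nuclei.columns)
        if missing:
            raise ValueError(f"nuclei frame is missing columns: {sorted(missing)}")

    def points(self, side: str | None = None, identified_only: bool = True):
        """Centroid array (n, 3) of this worm's nuclei, optionally one side.

        With ``identified_only`` (default) restricts to nuclei carrying one
        of the amphid class labels, which is how nuclei enter plane fits.
        """
        from .template import CLASS_NAMES

        df = self.nuclei
        if side is not None:
            df = df[df["side"] == side]
        if identified_only:
            df = df[df["class"].isin(CLASS_NAMES)]
        return df[["ap_um", "dv_um", "ml_um"]].to_numpy(dtype=float)
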