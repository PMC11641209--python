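"""Canonical template of the amphid chemosensory neuron classes.

The amphid sensilla of *C. elegans* house, on each lateral side of the head, a
stereotyped set of chemosensory neurons whose nuclei can be told apart by their
relative anterior-posterior (AP) and dorso-ventral (DV) positions, nuclear
size, and reporter expression level.  This module encodes that stereotype:

* the dorso-ventral *rank* of each class (1 = most ventral ... 6 = most
  dorsal; classes at similar DV height share a rank),
* a set of template centroid coordinates, in micrometres, that realise the
  qualitative anatomy (ordering along AP/DV, medial vs lateral offsets,
  the collinear dorsal triplet ASK-ADL-ASI),
* relative nuclear size and reporter intensity per class, which carry the
  visual identification cues (ASH largest/brightest ventrally, ASG/ADF
  brightest of the middle four, AWA larger and more medial than AWB).

Coordinate frame (right-handed): axis 0 = AP, increasing posterior; axis 1 =
DV, increasing dorsal; axis 2 = mediolateral (ML), increasing left-to-right,
midline at 0.  ``template_ml`` stores the magnitude of the lateral offset and
is mirrored across the midline per side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuronClassSpec", "CLASS_NAMES", "RANK_MAP", "UNIDENTIFIED", "make_template"]

#: Label used for nuclei that cannot be assigned unambiguously.
UNIDENTIFIED = "UNIDENTIFIED"

#: Dorso-ventral rank of each amphid neuron class, ventral (1) to dorsal (6).
RANK_MAP: dict[str, int] = {
    "ASJ": 1,
    "AWC": 2,
    "ASE": 3,
    "ASH": 3,
    "AWA": 4,
    "ADF": 4,
    "AWB": 5,
    "ASG": 5,
    "ASI": 6,
    "ADL": 6,
    "ASK": 6,
}

#: The amphid neuron classes covered by the rank map, in a fixed order.
CLASS_NAMES: tuple[str, ...] = tuple(RANK_MAP)


@dataclass(frozen=True)
class NeuronClassSpec:
    """Template description of one amphid neuron class.

    Parameters
    ----------
    name
        Class name, e.g. ``"ASH"``.
    rank
        Dorso-ventral rank, 1 (ventral) to 6 (dorsal).
    template_ap, template_dv
        Template centroid coordinates along the AP and DV axes, in µm.
    template_ml
        Magnitude of the lateral offset from the midline, in µm; mirrored
        per side.  Strictly positive.
    rel_size, rel_intensity
        Nuclear size and reporter intensity relative to a generic nucleus,
        dimensionless and strictly positive.
    """

    name: str
    rank: int
    template_ap: float
    template_dv: float
    template_ml: float
    rel_size: float
    rel_intensity: float


# Raw template layout (AP, DV, lateral-offset, size, intensity), one row per
# class.  The AP/DV coordinates span roughly 20 x 15 µm; only the ordinal
# relations between classes are anatomically meaningful.
_RAW = {
    # name:   (ap,   dv,   ml,  size, intensity)
    "ASJ": (13.0, 0.0, 3.0, 1.0, 1.0),
    "AWC": (3.0, 2.5, 3.2, 1.1, 1.1),
    "ASH": (8.0, 5.0, 2.8, 1.5, 1.8),
    "ASE": (14.0, 5.0, 3.0, 1.1, 1.2),
    "ADF": (5.0, 8.0, 2.6, 1.0, 1.5),
    "AWA": (8.0, 8.0, 1.8, 1.3, 1.0),
    "AWB": (11.0, 10.5, 4.6, 0.8, 0.9),
    "ASG": (13.5, 10.5, 3.4, 0.9, 1.6),
    "ASK": (4.0, 14.0, 3.0, 1.0, 1.0),
    "ADL": (9.0, 14.0, 3.0, 1.0, 1.0),
    "ASI": (14.0, 14.0, 3.0, 1.0, 1.0),
}


def make_template() -> list[NeuronClassSpec]:
    """Build the canonical amphid class template.

    Returns a list of one :class:`NeuronClassSpec` per class, deterministic
    (no randomness).  The per-class lateral offsets are decorrelated from the
    AP/DV spread (their least-squares projection onto the centred AP and DV
    coordinates is removed), so that the orthogonal best-fit plane of an
    untilted, noise-free half-layout is exactly sagittal.  Because the
    adjustment is affine in (AP, DV), exactly collinear template points (the
    dorsal triplet) remain exactly collinear.
    """
    names = list(_RAW)
    arr = np.array([_RAW[n] for n in names], dtype=float)
    ap, dv, ml = arr[:, 0], arr[:, 1], arr[:, 2]
    X = np.column_stack([ap - ap.mean(), dv - dv.mean()])
    beta, *_ = np.linalg.lstsq(X, ml - ml.mean(), rcond=None)
    ml_adj = ml - X @ beta
    return [
        NeuronClassSpec(
            name=n,
            rank=RANK_MAP[n],
            template_ap=float(ap[i]),
            template_dv=float(dv[i]),
            template_ml=float(ml_adj[i]),
            rel_size=float(arr[i, 3]),
            rel_intensity=float(arr[i, 4]),
        )
        for i, n in enumerate(names)
    ]
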