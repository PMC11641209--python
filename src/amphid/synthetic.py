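"""Synthetic amphid layout generator with known ground truth.

No public repository of segmented amphid centroid tables exists, so every
downstream stage is exercised on synthetic cohorts generated here.  A worm is
built from the class template (:func:`amphid.template.make_template`) by

1. mirroring each class's lateral offset across the midline to produce the
   right and left half-layouts,
2. rotating each half rigidly by half the inter-plane tilt about an
   anterior-posterior axis through the dorsal hinge (the dorsal-most template
   point at the midline) — a positive tilt opens the wedge ventrally, so
   dorsal neurons stay close while ventral ones spread,
3. adding a per-rank extra lateral displacement away from the midline on both
   sides (the alternative deformation mode, in which only selected ranks
   spread while the halves stay parallel),
4. adding i.i.d. isotropic Gaussian positional noise,
5. dropping each nucleus independently with a fixed probability.

Sizes and intensities are the template's relative values times a lognormal
jitter (sd 0.1 on the log scale), so identification cues are reliable but
degradable.  The generative tilt, displacements, noise and dropout are the
ground truth that the geometry and identification estimators must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .samples import NUCLEUS_COLUMNS, WormSample
from .template import NeuronClassSpec, make_template

__all__ = [
    "LayoutParams",
    "GroundTruth",
    "generate_worm",
    "generate_cohort",
    "expected_pair_distance",
]

#: sd of the lognormal size/intensity jitter (log scale).
_JITTER_SD = 0.1


@dataclass(frozen=True)
class LayoutParams:
    """Generative parameters of a synthetic cohort.

    Parameters
    ----------
    true_angle_deg
        Inter-plane tilt in degrees, ``0 <= angle < 90``, hinged at the
        dorsal edge; each half is rotated by half this angle.
    base_half_distance
        Midline-to-plane distance in µm when untilted (> 0); each class's
        template lateral offset is added on top.
    rank_displacement
        Mapping rank -> extra lateral offset in µm applied away from the
        midline on both sides (default: none).
    noise_sd
        sd of the isotropic Gaussian positional noise, µm (>= 0).
    dropout_prob
        Independent per-nucleus omission probability, in [0, 1).
    n_worms
        Cohort size (>= 1).
    seed
        Seed of the cohort's RNG stream.
    strain, condition
        Metadata stamped onto the generated worms.
    """

    true_angle_deg: float = 0.0
    base_half_distance: float = 5.0
    rank_displacement: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    dropout_prob: float = 0.0
    n_worms: int = 1
    seed: int = 0
    strain: str = "WT"
    condition: str = "microfluidic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_angle_deg < 90.0:
            raise ValidationError("true_angle_deg must be in [0, 90)")
        if self.base_half_distance <= 0:
            raise ValidationError("base_half_distance must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.n_worms < 1:
            raise ValidationError("n_worms must be >= 1")
        if any(r not in range(1, 7) for r in self.rank_displacement):
            raise ValidationError("rank_displacement keys must be ranks 1..6")


@dataclass(frozen=True)
class GroundTruth:
    """True labels of every emitted nucleus of one worm, plus the parameters."""

    worm_id: str
    labels: pd.DataFrame  # columns: nucleus_id, true_class, true_side
    params: LayoutParams


def _half_positions(params: LayoutParams, template: list[NeuronClassSpec]) -> dict[str, np.ndarray]:
    """Noise-free nucleus positions per side, keyed 'L'/'R', rows in template order."""
    ap = np.array([s.template_ap for s in template])
    dv = np.array([s.template_dv for s in template])
    ml = params.base_half_distance + np.array([s.template_ml for s in template])
    disp = np.array([params.rank_displacement.get(s.rank, 0.0) for s in template])

    half = np.radians(params.true_angle_deg) / 2.0
    dv_hinge = dv.max()
    # Rotate the right half by -half about the AP axis through (dv_hinge, 0):
    # ventral points (dv < hinge) move laterally outward.
    ddv = dv - dv_hinge
    dv_rot = dv_hinge + ddv * np.cos(half) + ml * np.sin(half)
    ml_rot = -ddv * np.sin(half) + ml * np.cos(half)
    right = np.column_stack([ap, dv_rot, ml_rot + disp])
    left = right * np.array([1.0, 1.0, -1.0])
    return {"L": left, "R": right}


def expected_pair_distance(params: LayoutParams, spec: NeuronClassSpec, dv_hinge: float) -> float:
    """Closed-form noise-free bilateral distance for one class (µm)."""
    half = np.radians(params.true_angle_deg) / 2.0
    ml = params.base_half_distance + spec.template_ml
    lateral = (dv_hinge - spec.template_dv) * np.sin(half) + ml * np.cos(half)
    return float(2.0 * (lateral + params.rank_displacement.get(spec.rank, 0.0)))


def generate_worm(
    params: LayoutParams,
    template: list[NeuronClassSpec],
    rng: np.random.Generator,
    worm_id: str = "w001",
) -> tuple[WormSample, GroundTruth]:
    """Generate one worm; returns the labeled sample and its ground truth.

    The emitted ``WormSample`` carries the true class and side labels; writers
    and the analysis pipeline may blank or ignore them (identification mode
    ``auto`` re-derives labels from geometry and signal cues alone).
    """
    halves = _half_positions(params, template)
    rows = []
    counter = 0
    for side in ("L", "R"):
        pos = halves[side]
        for i, spec in enumerate(template):
            xyz = pos[i] + rng.normal(0.0, params.noise_sd, size=3)
            size = spec.rel_size * rng.lognormal(0.0, _JITTER_SD)
            intensity = spec.rel_intensity * rng.lognormal(0.0, _JITTER_SD)
            drop = rng.random() < params.dropout_prob
            if drop:
                continue
            rows.append(
                {
                    "nucleus_id": f"n{counter:02d}",
                    "class": spec.name,
                    "side": side,
                    "ap_um": xyz[0],
                    "dv_um": xyz[1],
                    "ml_um": xyz[2],
                    "size": size,
                    "intensity": intensity,
                }
            )
            counter += 1
    nuclei = pd.DataFrame(rows, columns=list(NUCLEUS_COLUMNS))
    # Shuffle row order so nothing downstream can rely on emission order.
    order = rng.permutation(len(nuclei))
    nuclei = nuclei.iloc[order].reset_index(drop=True)
    nuclei["nucleus_id"] = [f"n{j:02d}" for j in range(len(nuclei))]
    sample = WormSample(worm_id=worm_id, strain=params.strain, condition=params.condition, nuclei=nuclei)
    truth = GroundTruth(
        worm_id=worm_id,
        labels=nuclei[["nucleus_id", "class", "side"]].rename(
            columns={"class": "true_class", "side": "true_side"}
        ),
        params=params,
    )
    return sample, truth


def generate_cohort(
    params: LayoutParams, template: list[NeuronClassSpec] | None = None
) -> tuple[list[WormSample], list[GroundTruth]]:
    """Generate ``params.n_worms`` independent worms from one seeded stream."""
    if template is None:
        template = make_template()
    rng = np.random.default_rng(params.seed)
    samples, truths = [], []
    for w in range(params.n_worms):
        s, t = generate_worm(params, template, rng, worm_id=f"w{w + 1:03d}")
        samples.append(s)
        truths.append(t)
    return samples, truths
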