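import numpy as np
import pandas as pd
import pytest

from amphid import LayoutParams, RankDistanceTable, generate_cohort, make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def clean_cohort(template):
    """Zero-noise, zero-tilt, zero-dropout cohort of 3 worms."""
    params = LayoutParams(n_worms=3, seed=42)
    return generate_cohort(params, template)


@pytest.fixture(scope="session")
def tilted_cohort(template):
    """Zero-noise cohort with a 30 degree generative tilt."""
    params = LayoutParams(true_angle_deg=30.0, n_worms=3, seed=43)
    return generate_cohort(params, template)


def make_rank_table(
    label: str,
    rng: np.random.Generator,
    n_worms: int = 15,
    mean: float = 10.0,
    sd: float = 2.0,
    rank_shift: dict[int, float] | None = None,
) -> RankDistanceTable:
    """Gaussian rank-distance table with the amphid rank multiplicities.

    Each worm contributes one distance per class; ranks 1 and 2 carry one
    class, 3-5 two, 6 three, mirroring the anatomy.
    """
    classes = {1: ["ASJ"], 2: ["AWC"], 3: ["ASE", "ASH"], 4: ["AWA", "ADF"], 5: ["AWB", "ASG"], 6: ["ASI", "ADL", "ASK"]}
    shift = rank_shift or {}
    rows = []
    for w in range(n_worms):
        for rank, names in classes.items():
            for cls in names:
                d = mean + shift.get(rank, 0.0) + rng.normal(0.0, sd)
                rows.append({"worm_id": f"w{w}", "neuron_class": cls, "rank": rank, "distance_um": abs(d)})
    return RankDistanceTable(label=label, records=pd.DataFrame(rows))


def table_from_rank_values(label: str, values: dict[int, list[float]]) -> RankDistanceTable:
    """Rank table with explicit per-rank distance lists (one synthetic worm each)."""
    rows = [
        {"worm_id": f"w{i}", "neuron_class": "ASJ", "rank": rank, "distance_um": v}
        for rank, vals in values.items()
        for i, v in enumerate(vals)
    ]
    return RankDistanceTable(label=label, records=pd.DataFrame(rows))
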