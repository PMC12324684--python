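"""Synthetic spheroid feature tables with planted defect labels."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ciliaquant.spheroids import SpheroidRecord
from ciliaquant.simulate.config import GroundTruth, SimConfig

_DEFECT_MECHANISMS = ("no_lumen", "multi_lumen", "distorted_lumen",
                      "protruding_nuclei", "disorganized_markers",
                      "misoriented_cilia")


def simulate_spheroid_table(
    config: SimConfig,
    defect_rate: float,
    n_spheroids: int = 40,
    death_rate: float = 0.05,
    ciliation_rate: float = 0.6,
    condition: str = "",
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpheroidRecord], GroundTruth]:
    """Sample per-spheroid features consistent with planted defect labels.

    Each spheroid is planted defective with probability ``defect_rate``;
    defective spheroids get one or more defect mechanisms, normal ones a
    single hollow lumen and clean flags, so the rule-based classifier
    recovers the planted labels exactly. Luminal apoptotic bodies and
    luminal cilia are binomial in the cell count at the given rates. Cell
    counts are drawn within the analyzable window (8–50 cells).
    """
    if not 0.0 <= defect_rate <= 1.0:
        raise ValueError("defect_rate must be in [0, 1]")
    if rng is None:
        rng = config.rng(salt=3)

    records: list[SpheroidRecord] = []
    truth_rows = []
    for i in range(n_spheroids):
        defective = bool(rng.uniform() < defect_rate)
        kwargs = dict(
            spheroid_id=f"{condition or 'sph'}_{i:03d}",
            condition=condition,
            replicate=f"r{i % n_replicates + 1}",
            cell_count=int(rng.integers(10, 46)),
            lumen_count=1,
            hollow_lumen=True,
        )
        if defective:
            n_mech = 1 + int(rng.integers(0, 2))
            mechanisms = rng.choice(_DEFECT_MECHANISMS, size=n_mech, replace=False)
            for mech in mechanisms:
                if mech == "no_lumen":
                    kwargs["hollow_lumen"] = False
                    kwargs["lumen_count"] = 0
                elif mech == "multi_lumen":
                    kwargs["lumen_count"] = int(rng.integers(2, 4))
                else:
                    kwargs[mech] = True
        rec = SpheroidRecord(**kwargs)
        rec.luminal_apoptotic_bodies = int(rng.binomial(rec.cell_count, death_rate))
        rec.luminal_cilia = int(rng.binomial(rec.cell_count, ciliation_rate))
        records.append(rec)
        truth_rows.append({"spheroid_id": rec.spheroid_id,
                           "planted_label": "defective" if defective else "normal"})

    truth = GroundTruth(spheroid_labels=pd.DataFrame(truth_rows))
    return records, truth
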