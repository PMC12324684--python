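import numpy as np
import pandas as pd
import pytest

from ciliaquant.interactome import PsmTable


@pytest.fixture
def tiny_psm() -> PsmTable:
    """Hand-sized PSM table: 2 bio x 2 tech replicates, one time point.

    Counts are chosen so NSAF values and fold changes are easy to verify
    by hand; run totals are all 100.
    """
    runs = {
        "bait_1h_b1_t1": [40, 10, 20, 0, 30],
        "bait_1h_b1_t2": [40, 10, 20, 0, 30],
        "bait_1h_b2_t1": [40, 10, 20, 0, 30],
        "bait_1h_b2_t2": [40, 10, 20, 0, 30],
        "control_1h_b1_t1": [10, 10, 20, 30, 30],
        "control_1h_b1_t2": [10, 10, 20, 30, 30],
        "control_1h_b2_t1": [10, 10, 20, 30, 30],
        "control_1h_b2_t2": [10, 10, 20, 30, 30],
    }
    counts = pd.DataFrame(runs, index=["enriched", "flat", "flat2", "ctrl_only", "flat3"])
    meta = pd.DataFrame(
        [(r, r.split("_")[0], r.split("_")[1], r.split("_")[2], r.split("_")[3])
         for r in runs],
        columns=["run_id", "role", "time_point", "bio_rep", "tech_rep"],
    ).set_index("run_id")
    return PsmTable(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
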