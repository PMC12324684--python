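"""Synthetic PSM tables with planted bait-enriched proteins.

Protein abundances are drawn log-normally and normalized to expected
per-run fractions; bait runs multiply the enriched set's abundance by
2**enrichment_log2fc before renormalizing (so enrichment of one set
slightly dilutes the rest, as in real spectral counting). Counts are
Poisson around the multinomial expectations, giving integer counts with
realistic dispersion while keeping run totals near ``psm_depth``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ciliaquant.interactome import PsmTable, ROLE_BAIT, ROLE_CONTROL
from ciliaquant.simulate.config import GroundTruth, SimConfig


def simulate_psm_tables(
    config: SimConfig,
    time_points: tuple[str, ...] = ("1h", "6h"),
    contaminant_fraction: float = 0.3,
    abundance_sigma: float = 1.0,
    enriched_per_timepoint: dict[str, int] | None = None,
    enriched_overlap: int | None = None,
) -> tuple[PsmTable, GroundTruth]:
    """Generate one run per (role x biological rep x technical rep x time point).

    By default one enriched set of size ``frac_enriched x n_proteins`` is
    shared by all time points. Passing ``enriched_per_timepoint`` (time
    point -> set size) with ``enriched_overlap`` plants time-point-specific
    enriched sets sharing exactly that many proteins, which exercises the
    two-time-point intersection downstream.

    ``contaminant_fraction`` of the never-enriched proteins are tagged in
    the contaminant registry with a contamination percentage drawn uniform
    on (0, 100), so the >50% filter is exercised on both sides of its
    cutoff.
    """
    rng = config.rng()
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]

    abundance = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)

    if enriched_per_timepoint is None:
        n_enriched = int(round(config.frac_enriched * n))
        shared = rng.choice(n, size=n_enriched, replace=False)
        enriched_idx = {tp: shared for tp in time_points}
    else:
        if set(enriched_per_timepoint) != set(time_points):
            raise ValueError("enriched_per_timepoint must cover every time point")
        if enriched_overlap is None or len(time_points) != 2:
            raise ValueError("per-time-point sets need exactly 2 time points "
                             "and an explicit overlap")
        tp_a, tp_b = time_points
        n_a, n_b = enriched_per_timepoint[tp_a], enriched_per_timepoint[tp_b]
        if enriched_overlap > min(n_a, n_b):
            raise ValueError("overlap larger than a set")
        pool = rng.permutation(n)
        total = n_a + n_b - enriched_overlap
        if total > n:
            raise ValueError("enriched sets larger than the proteome")
        common = pool[:enriched_overlap]
        only_a = pool[enriched_overlap: n_a]
        only_b = pool[n_a: total]
        enriched_idx = {tp_a: np.concatenate([common, only_a]),
                        tp_b: np.concatenate([common, only_b])}

    p_control = abundance / abundance.sum()
    counts = {}
    meta_rows = []
    for tp in time_points:
        mult = np.ones(n)
        mult[enriched_idx[tp]] = 2.0 ** config.enrichment_log2fc
        bait_abundance = abundance * mult
        p_bait = bait_abundance / bait_abundance.sum()
        for role, probs in ((ROLE_BAIT, p_bait), (ROLE_CONTROL, p_control)):
            for bio in range(1, config.n_biological_reps + 1):
                for tech in range(1, config.n_technical_reps + 1):
                    run_id = f"{role}_{tp}_b{bio}_t{tech}"
                    counts[run_id] = rng.poisson(probs * config.psm_depth)
                    meta_rows.append({"run_id": run_id, "role": role, "time_point": tp,
                                      "bio_rep": f"b{bio}", "tech_rep": f"t{tech}"})

    table = PsmTable(
        counts=pd.DataFrame(counts, index=proteins),
        meta=pd.DataFrame(meta_rows).set_index("run_id"),
    )

    ever_enriched = set(np.concatenate(list(enriched_idx.values())).tolist())
    non_enriched = sorted(set(range(n)) - ever_enriched)
    n_contam = int(round(contaminant_fraction * len(non_enriched)))
    contam_idx = rng.choice(non_enriched, size=n_contam, replace=False)
    registry = {proteins[i]: float(rng.uniform(0.0, 100.0)) for i in sorted(contam_idx)}

    truth = GroundTruth(
        enriched_proteins={proteins[i] for i in sorted(ever_enriched)},
        enriched_by_timepoint={tp: {proteins[i] for i in idx}
                               for tp, idx in enriched_idx.items()},
        contaminant_registry=registry,
    )
    return table, truth
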