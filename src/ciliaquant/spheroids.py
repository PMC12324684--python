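"""Rule-based scoring of 3D epithelial spheroids and simple blot ratios.

A healthy IMCD3-style spheroid has a single hollow lumen, apically
oriented cilia and organized apical/basal markers. Spheroids are scored
from pre-annotated per-spheroid feature records:

* :func:`exclude_spheroids` — drops clusters too small to score (< 8
  cells in cross-section) or large clusters (> 50 cells) that never
  formed a lumen;
* :func:`classify_defective` — a spheroid is defective if it lacks a
  hollow lumen, has multiple or distorted lumens, shows disorganized
  apical/basal markers, has nuclei protruding into the lumen, or (by
  default) misoriented cilia;
* :func:`luminal_death_frequency` — luminal apoptotic bodies per total
  cells, as a percentage, per replicate and condition;
* :func:`band_ratio` — loading-control-normalized band intensity ratios
  for western blots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL_DEFECTIVE = "defective"
LABEL_NORMAL = "normal"
LABEL_EXCLUDED = "excluded"

MIN_CELLS = 8
MAX_CELLS_WITHOUT_LUMEN = 50

DEFECT_FLAGS = ("distorted_lumen", "protruding_nuclei",
                "disorganized_markers", "misoriented_cilia")


@dataclass
class SpheroidRecord:
    """Pre-annotated morphology features of one spheroid cross-section."""

    spheroid_id: str
    condition: str
    replicate: str
    cell_count: int
    lumen_count: int
    hollow_lumen: bool
    distorted_lumen: bool = False
    protruding_nuclei: bool = False
    disorganized_markers: bool = False
    misoriented_cilia: bool = False
    luminal_apoptotic_bodies: int = 0
    luminal_cilia: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.cell_count < 0 or self.lumen_count < 0:
            raise ValueError("counts must be non-negative")
        if self.luminal_apoptotic_bodies < 0 or self.luminal_cilia < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class BlotMeasurement:
    """One lane: target band and its loading-control band."""

    lane_id: str
    target_intensity: float
    loading_intensity: float
    fraction: str = ""

    @property
    def normalized(self) -> float:
        if self.loading_intensity <= 0:
            raise ValueError(f"lane {self.lane_id!r}: loading control must be > 0")
        return self.target_intensity / self.loading_intensity


def exclude_spheroids(records: list[SpheroidRecord]) -> list[SpheroidRecord]:
    """Mark records failing the analysis-inclusion rules as excluded.

    Excluded iff cell count < 8, or cell count > 50 with no lumen. All
    records are returned; the ``label`` of excluded ones is set.
    """
    for rec in records:
        if rec.cell_count < MIN_CELLS:
            rec.label = LABEL_EXCLUDED
        elif rec.cell_count > MAX_CELLS_WITHOUT_LUMEN and rec.lumen_count == 0:
            rec.label = LABEL_EXCLUDED
    return records


def classify_defective(
    record: SpheroidRecord,
    count_misoriented_cilia: bool = True,
) -> str:
    """Defect call for one (non-excluded) spheroid.

    Defective iff any of: no hollow lumen, more than one lumen, distorted
    lumen, disorganized apical/basal markers, nuclei protruding into the
    lumen, or — toggleable — misoriented cilia.
    """
    if record.label == LABEL_EXCLUDED:
        raise ValueError(f"spheroid {record.spheroid_id!r} is excluded from analysis")
    defective = (
        not record.hollow_lumen
        or record.lumen_count > 1
        or record.distorted_lumen
        or record.disorganized_markers
        or record.protruding_nuclei
        or (count_misoriented_cilia and record.misoriented_cilia)
    )
    record.label = LABEL_DEFECTIVE if defective else LABEL_NORMAL
    return record.label


def score_cohort(
    records: list[SpheroidRecord],
    count_misoriented_cilia: bool = True,
) -> pd.DataFrame:
    """Exclude, classify and summarize a cohort.

    Returns a per-(condition, replicate) table with counts, the defect
    percentage among analyzable spheroids, luminal-death percentage and
    luminal-ciliation percentage.
    """
    exclude_spheroids(records)
    for rec in records:
        if rec.label != LABEL_EXCLUDED:
            classify_defective(rec, count_misoriented_cilia)
    df = pd.DataFrame([vars(r) for r in records])
    rows = []
    for (condition, replicate), grp in df.groupby(["condition", "replicate"], sort=True):
        analyzable = grp[grp["label"] != LABEL_EXCLUDED]
        n = len(analyzable)
        total_cells = int(analyzable["cell_count"].sum())
        rows.append({
            "condition": condition,
            "replicate": replicate,
            "n_spheroids": len(grp),
            "n_analyzable": n,
            "n_excluded": int((grp["label"] == LABEL_EXCLUDED).sum()),
            "defect_pct": float((analyzable["label"] == LABEL_DEFECTIVE).mean() * 100.0)
            if n else np.nan,
            "luminal_death_pct": float(
                analyzable["luminal_apoptotic_bodies"].sum() / total_cells * 100.0)
            if total_cells else np.nan,
            "luminal_ciliation_pct": float(
                analyzable["luminal_cilia"].sum() / total_cells * 100.0)
            if total_cells else np.nan,
        })
    return pd.DataFrame(rows)


def luminal_death_frequency(records: list[SpheroidRecord]) -> pd.DataFrame:
    """Per-condition luminal-death percentage.

    Within each replicate: sum of luminal apoptotic bodies over the sum of
    cell counts x 100; per condition, the mean over replicates.
    """
    df = pd.DataFrame([vars(r) for r in records])
    df = df[df["label"] != LABEL_EXCLUDED]
    rows = []
    for condition, grp in df.groupby("condition", sort=True):
        per_rep = []
        for _, rep_grp in grp.groupby("replicate"):
            cells = rep_grp["cell_count"].sum()
            if cells == 0:
                raise ValueError(f"zero total cells in a replicate of {condition!r}")
            per_rep.append(rep_grp["luminal_apoptotic_bodies"].sum() / cells * 100.0)
        rows.append({"condition": condition,
                     "luminal_death_pct": float(np.mean(per_rep)),
                     "n_replicates": len(per_rep)})
    return pd.DataFrame(rows)


def band_ratio(target: BlotMeasurement, reference: BlotMeasurement) -> float:
    """Fold change of loading-control-normalized band intensities.

    (target / its loading control) ÷ (reference / its loading control).
    For fractionation blots, pass the nuclear lane as ``target`` and the
    cytosolic lane as ``reference`` to get the nuclear:cytosol ratio.
    """
    return target.normalized / reference.normalized


def fold_change_of_means(case_mean: float, control_mean: float, decimals: int = 2) -> float:
    """Ratio of per-condition means, rounded to figure-legend precision."""
    if control_mean == 0:
        raise ValueError("control mean must be nonzero")
    return round(case_mean / control_mean, decimals)
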