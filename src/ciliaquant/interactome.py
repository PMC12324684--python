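"""NSAF-based proximity-interactome enrichment and filtering.

Implements the spectral-counting pipeline used to call high-confidence
proximity interactors from BioID pulldowns of a bait-fused biotin ligase
versus a ligase-only control:

1. :func:`compute_nsaf` — per-run Normalized Spectral Abundance Factors,
   here defined as a protein's PSM count divided by the run's total PSM
   count, so each run's NSAF column sums to 1.
2. :func:`exclude_low_evidence` — drops proteins detected only in control
   runs or in just one technical replicate of the bait condition.
3. :func:`compute_fold_change` — bait/control NSAF fold change per
   biological replicate (technical replicates averaged first), then the
   average log2 fold change over biological replicates for proteins seen
   in both.
4. :func:`filter_high_confidence` — keeps proteins with average
   log2(fold change) >= 1 whose contaminant-registry percentage (if known)
   does not exceed 50%.

Every removal is recorded in an audit trail mapping each input protein to
the first rule that removed it, so retained and removed sets always
partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_BAIT = "bait"
ROLE_CONTROL = "control"

#: Audit-trail reason codes, in the order the filters run.
REASON_ABSENT = "absent-everywhere"
REASON_CONTROL_ONLY = "control-only"
REASON_SINGLE_TECH_REP = "single-tech-rep"
REASON_MISSING_BIO_REP = "missing-biological-replicate"
REASON_LOW_FC = "log2fc-below-threshold"
REASON_CONTAMINANT = "contaminant"
REASON_RETAINED = "retained"


class PsmTable:
    """Protein-by-run spectral counts plus run metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by protein id with one integer column per run.
    meta
        DataFrame indexed by run id with columns ``role`` (``bait`` or
        ``control``), ``time_point``, ``bio_rep`` and ``tech_rep``.
    """

    META_COLUMNS = ("role", "time_point", "bio_rep", "tech_rep")

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        counts = counts.copy()
        counts.index = counts.index.astype(str).str.strip()
        self.counts = counts
        self.meta = meta.copy()
        self._validate()

    def _validate(self) -> None:
        missing = [c for c in self.META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"run metadata missing columns: {missing}")
        unknown = set(self.counts.columns) - set(self.meta.index)
        if unknown:
            raise ValueError(f"runs without metadata: {sorted(unknown)}")
        bad_roles = set(self.meta["role"]) - {ROLE_BAIT, ROLE_CONTROL}
        if bad_roles:
            raise ValueError(f"unknown run roles: {sorted(bad_roles)}")
        if (self.counts.values < 0).any():
            raise ValueError("PSM counts must be non-negative")
        key = self.meta.loc[list(self.counts.columns), ["role", "time_point", "bio_rep", "tech_rep"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].index.tolist()
            raise ValueError(f"duplicate (role, time_point, bio_rep, tech_rep) for runs: {dup}")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate protein ids")

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    @property
    def runs(self) -> pd.Index:
        return self.counts.columns

    def runs_for(self, role: str | None = None, time_point: str | None = None) -> list[str]:
        sel = self.meta.loc[list(self.counts.columns)]
        if role is not None:
            sel = sel[sel["role"] == role]
        if time_point is not None:
            sel = sel[sel["time_point"] == time_point]
        return list(sel.index)

    @property
    def time_points(self) -> list[str]:
        return sorted(self.meta.loc[list(self.counts.columns), "time_point"].unique())

    def subset_time_point(self, time_point: str) -> "PsmTable":
        runs = self.runs_for(time_point=time_point)
        if not runs:
            raise ValueError(f"no runs for time point {time_point!r}")
        return PsmTable(self.counts[runs], self.meta.loc[runs])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PsmTable({len(self.proteins)} proteins x {len(self.runs)} runs)"


class ContaminantRegistry:
    """Protein -> contamination percentage lookup (CRAPome-style).

    Proteins absent from the registry return ``None`` ("unknown"), which is
    distinct from a recorded 0% score: the high-confidence filter retains
    unknown proteins because registry coverage is incomplete.
    """

    def __init__(self, percentages: dict[str, float] | pd.Series | None = None):
        if percentages is None:
            percentages = {}
        if isinstance(percentages, pd.Series):
            percentages = percentages.to_dict()
        clean: dict[str, float] = {}
        for pid, pct in percentages.items():
            pct = float(pct)
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"contamination % out of [0, 100] for {pid!r}: {pct}")
            clean[str(pid).strip()] = pct
        self._pct = clean

    def lookup(self, protein_id: str) -> float | None:
        return self._pct.get(str(protein_id).strip())

    def __len__(self) -> int:
        return len(self._pct)

    def __contains__(self, protein_id: str) -> bool:
        return str(protein_id).strip() in self._pct

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   id_col: str = "protein_id",
                   pct_col: str = "contamination_pct") -> "ContaminantRegistry":
        return cls(dict(zip(frame[id_col].astype(str), frame[pct_col].astype(float))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self._pct), "contamination_pct": list(self._pct.values())}
        )


@dataclass
class InteractomeResult:
    """Outcome of the filtering pipeline for one time point."""

    time_point: str
    #: retained proteins with their scores (index: protein id; columns
    #: include ``avg_log2fc`` and ``contamination_pct``)
    high_confidence: pd.DataFrame
    #: protein id -> first filter that removed it (``retained`` otherwise)
    audit: pd.Series
    categories: pd.Series | None = None
    edges: pd.DataFrame | None = None
    dropped_edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def protein_set(self) -> set[str]:
        return set(self.high_confidence.index)

    def __post_init__(self) -> None:
        retained = set(self.high_confidence.index)
        marked = set(self.audit[self.audit == REASON_RETAINED].index)
        if retained != marked:
            raise ValueError("audit trail inconsistent with high-confidence set")


def compute_nsaf(psm: PsmTable) -> pd.DataFrame:
    """Normalized spectral abundance: NSAF[p, r] = PSM[p, r] / sum_q PSM[q, r].

    Each run column of the result sums to exactly 1 (within float error).
    Raises ``ValueError`` naming any run whose total PSM count is zero.
    """
    totals = psm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero run(s): {list(zero.index)}")
    return psm.counts.astype(float).div(totals, axis=1)


def exclude_low_evidence(psm: PsmTable, audit: dict[str, str] | None = None) -> PsmTable:
    """Remove proteins with insufficient bait-side evidence.

    A protein is considered *present* in a run when its PSM count is >= 1.
    Removed are proteins

    * absent from every run (``absent-everywhere``),
    * present in no bait run, i.e. detected only in the control
      (``control-only``),
    * present in exactly one technical replicate (run) of the bait
      condition (``single-tech-rep``).

    When ``audit`` is supplied, each removed protein's reason code is
    recorded there.
    """
    present = psm.counts >= 1
    bait_runs = psm.runs_for(role=ROLE_BAIT)
    n_bait = present[bait_runs].sum(axis=1)
    n_any = present.sum(axis=1)

    keep = n_bait >= 2
    if audit is not None:
        for pid in psm.proteins[~keep]:
            if n_any[pid] == 0:
                audit[pid] = REASON_ABSENT
            elif n_bait[pid] == 0:
                audit[pid] = REASON_CONTROL_ONLY
            else:
                audit[pid] = REASON_SINGLE_TECH_REP
    kept = psm.counts.loc[keep]
    return PsmTable(kept, psm.meta)


def compute_fold_change(
    nsaf: pd.DataFrame,
    meta: pd.DataFrame,
    tech_rep_strategy: str = "mean-nsaf",
) -> pd.DataFrame:
    """Per-protein bait/control enrichment scores.

    For each biological replicate the technical-replicate NSAF values are
    merged (``mean-nsaf``: arithmetic mean, the default; ``mean-fc``: fold
    changes computed per technical replicate pair and then averaged), and
    FC = merged bait NSAF / merged control NSAF. The average log2 fold
    change is the mean of log2(FC) over biological replicates and is
    defined only for proteins present (NSAF > 0 on the bait side) in both
    biological replicates; others get NaN and the ``missing_bio_rep`` flag.

    A zero control NSAF is replaced by the smallest nonzero merged control
    NSAF of that biological replicate and flagged (``zero_control``), which
    retains bait-specific proteins without producing infinite fold changes.

    Returns a DataFrame indexed by protein id with columns
    ``fc_<bio_rep>``, ``avg_log2fc``, ``n_bio_present``, ``zero_control``
    and ``missing_bio_rep``.
    """
    if tech_rep_strategy not in ("mean-nsaf", "mean-fc"):
        raise ValueError(f"unknown tech_rep_strategy {tech_rep_strategy!r}")
    meta = meta.loc[list(nsaf.columns)]
    bio_reps = sorted(meta["bio_rep"].unique())
    out = pd.DataFrame(index=nsaf.index)
    zero_control = pd.Series(False, index=nsaf.index)
    log2fcs = []
    present_per_rep = []
    for rep in bio_reps:
        bait_runs = meta[(meta["role"] == ROLE_BAIT) & (meta["bio_rep"] == rep)].index
        ctrl_runs = meta[(meta["role"] == ROLE_CONTROL) & (meta["bio_rep"] == rep)].index
        if len(bait_runs) == 0 or len(ctrl_runs) == 0:
            raise ValueError(f"biological replicate {rep!r} lacks bait or control runs")
        bait = nsaf[bait_runs].mean(axis=1)
        ctrl = nsaf[ctrl_runs].mean(axis=1)
        nonzero_ctrl = ctrl[ctrl > 0]
        floor = float(nonzero_ctrl.min()) if len(nonzero_ctrl) else np.nan
        ctrl_for_ratio = ctrl.where(ctrl > 0, floor)
        zero_control |= (ctrl == 0) & (bait > 0)
        if tech_rep_strategy == "mean-nsaf":
            fc = bait / ctrl_for_ratio
        else:  # mean of per-technical-replicate fold changes
            per_tech = []
            for b_run, c_run in zip(sorted(bait_runs), sorted(ctrl_runs)):
                c = nsaf[c_run].where(nsaf[c_run] > 0,
                                      nsaf[c_run][nsaf[c_run] > 0].min())
                per_tech.append(nsaf[b_run] / c)
            fc = pd.concat(per_tech, axis=1).mean(axis=1)
        present = bait > 0
        fc = fc.where(present)  # FC undefined where the bait never saw the protein
        out[f"fc_{rep}"] = fc
        log2fcs.append(np.log2(fc))
        present_per_rep.append(present)

    present_all = pd.concat(present_per_rep, axis=1)
    out["n_bio_present"] = present_all.sum(axis=1).astype(int)
    in_all = present_all.all(axis=1)
    avg = pd.concat(log2fcs, axis=1).mean(axis=1)
    out["avg_log2fc"] = avg.where(in_all)
    out["zero_control"] = zero_control
    out["missing_bio_rep"] = ~in_all
    return out


def filter_high_confidence(
    records: pd.DataFrame,
    registry: ContaminantRegistry | None = None,
    log2fc_min: float = 1.0,
    contam_max: float = 50.0,
    audit: dict[str, str] | None = None,
    time_point: str = "",
) -> InteractomeResult:
    """Apply the enrichment and contaminant filters.

    A protein is retained iff its ``avg_log2fc`` is defined and
    >= ``log2fc_min`` *and* its registry contamination percentage, when
    known, is <= ``contam_max``. Both comparisons are strict in the removal
    direction (removed iff score < threshold, removed iff contamination >
    cutoff), so boundary values are retained. Unknown contamination is
    retained.
    """
    if registry is None:
        registry = ContaminantRegistry()
    if audit is None:
        audit = {}
    if "avg_log2fc" not in records.columns:
        raise ValueError("records must carry an 'avg_log2fc' column")

    contam = pd.Series([registry.lookup(p) for p in records.index],
                       index=records.index, dtype="float64")
    retained_rows = []
    for pid, row in records.iterrows():
        if pid in audit and audit[pid] != REASON_RETAINED:
            continue  # already removed upstream
        score = row["avg_log2fc"]
        if pd.isna(score):
            audit[pid] = REASON_MISSING_BIO_REP
        elif score < log2fc_min:
            audit[pid] = REASON_LOW_FC
        elif contam[pid] is not None and not pd.isna(contam[pid]) and contam[pid] > contam_max:
            audit[pid] = REASON_CONTAMINANT
        else:
            audit[pid] = REASON_RETAINED
            retained_rows.append(pid)

    high = records.loc[retained_rows].copy()
    high["contamination_pct"] = contam.loc[retained_rows]
    audit_series = pd.Series(audit, dtype="object")
    return InteractomeResult(time_point=time_point, high_confidence=high, audit=audit_series)


def intersect_timepoints(a: InteractomeResult, b: InteractomeResult) -> set[str]:
    """Proteins called high-confidence at both time points."""
    return a.protein_set & b.protein_set


def annotate_and_link(
    result: InteractomeResult,
    categories: pd.DataFrame | None = None,
    edges: pd.DataFrame | None = None,
) -> InteractomeResult:
    """Attach user-supplied category labels and interaction edges.

    ``categories`` needs columns ``protein_id`` and ``category``; ``edges``
    needs ``protein_a`` and ``protein_b``. Labels and edges referring to
    proteins outside the high-confidence set are dropped and reported via
    ``result.dropped_edges`` / the returned unmatched-category index.
    """
    hc = result.protein_set
    cat_series = None
    if categories is not None:
        for col in ("protein_id", "category"):
            if col not in categories.columns:
                raise ValueError(f"category table missing column {col!r}")
        cats = categories.assign(protein_id=categories["protein_id"].astype(str).str.strip())
        matched = cats[cats["protein_id"].isin(hc)]
        cat_series = matched.set_index("protein_id")["category"]
    kept_edges = None
    dropped = pd.DataFrame()
    if edges is not None:
        for col in ("protein_a", "protein_b"):
            if col not in edges.columns:
                raise ValueError(f"edge table missing column {col!r}")
        e = edges.assign(
            protein_a=edges["protein_a"].astype(str).str.strip(),
            protein_b=edges["protein_b"].astype(str).str.strip(),
        )
        ok = e["protein_a"].isin(hc) & e["protein_b"].isin(hc)
        kept_edges = e[ok].reset_index(drop=True)
        dropped = e[~ok].reset_index(drop=True)
    return InteractomeResult(
        time_point=result.time_point,
        high_confidence=result.high_confidence,
        audit=result.audit,
        categories=cat_series,
        edges=kept_edges,
        dropped_edges=dropped,
    )


def run_pipeline(
    psm: PsmTable,
    registry: ContaminantRegistry | None = None,
    time_point: str | None = None,
    log2fc_min: float = 1.0,
    contam_max: float = 50.0,
    tech_rep_strategy: str = "mean-nsaf",
) -> InteractomeResult:
    """Full chain: NSAF -> low-evidence exclusion -> fold change -> filters.

    Operates on the runs of a single time point (``time_point=None`` is
    allowed when the table holds only one).
    """
    if time_point is None:
        tps = psm.time_points
        if len(tps) != 1:
            raise ValueError(f"table has time points {tps}; pass time_point explicitly")
        time_point = tps[0]
    sub = psm.subset_time_point(time_point)
    audit: dict[str, str] = {}
    # NSAF denominators are per-run totals over *all* proteins, so NSAF is
    # computed before the low-evidence exclusion.
    nsaf = compute_nsaf(sub)
    surviving = exclude_low_evidence(sub, audit=audit)
    records = compute_fold_change(nsaf.loc[surviving.proteins], surviving.meta,
                                  tech_rep_strategy=tech_rep_strategy)
    return filter_high_confidence(
        records, registry,
        log2fc_min=log2fc_min, contam_max=contam_max,
        audit=audit, time_point=time_point,
    )
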