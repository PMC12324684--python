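"""Cilium length time-series analysis.

Works on live-imaging traces of single cilia sampled at a fixed frame
interval (4 min by default, up to 6 h). Provides:

* :func:`detect_events` — frame-to-frame length drops scored as ciliary
  ectocytosis, classified by shed-piece size as *vesicle* (< 0.5 µm) or
  *fragment* (>= 0.5 µm);
* :func:`classify_mode` — disassembly-mode call per trace: *gradual*
  resorption, *instant* whole-cilium loss within the first 2 h, a
  *combined* resorption-then-shedding pattern, or *intact*; plus the
  deciliation rate, defined as (initial length − final length) / elapsed
  hours;
* :func:`summarize_cohort` — per-condition means, mode fractions and
  ectocytosis-event fractions;
* :func:`fluctuation_metrics` — descriptive variability statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODE_GRADUAL = "gradual"
MODE_INSTANT = "instant"
MODE_COMBINED = "combined"
MODE_INTACT = "intact"

CLASS_VESICLE = "vesicle"
CLASS_FRAGMENT = "fragment"

#: shed-piece size separating vesicle from fragment ectocytosis (µm);
#: a piece of exactly 0.5 µm is called a fragment (deterministic tie rule)
VESICLE_FRAGMENT_CUTOFF_UM = 0.5

DEFAULT_DROP_FLOOR_UM = 0.25
DEFAULT_FULL_LOSS_UM = 0.3       # sub-resolution stub: counts as full loss
DEFAULT_INSTANT_WINDOW_H = 2.0
DEFAULT_RESORPTION_FRACTION = 0.25  # < this fraction resorbed before loss -> instant
ABRUPT_DROP_FACTOR = 3.0         # terminal step > factor x median |Δ| -> abrupt


@dataclass
class LengthTrace:
    """One cilium's sampled length series.

    ``times_min`` must be strictly increasing with a uniform spacing equal
    to ``frame_interval_min``; lengths are in µm and non-negative, and once
    a trace reaches 0 it stays at 0.
    """

    cilium_id: str
    times_min: np.ndarray
    lengths_um: np.ndarray
    condition: str = ""
    replicate: str = ""
    frame_interval_min: float = 4.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.times_min.shape != self.lengths_um.shape:
            raise ValueError("times and lengths differ in shape")
        if len(self.times_min) >= 2:
            dt = np.diff(self.times_min)
            if (dt <= 0).any():
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, self.frame_interval_min, rtol=1e-6, atol=1e-6):
                raise ValueError("times must be uniform at the frame interval")
        if (self.lengths_um < 0).any():
            raise ValueError("lengths must be non-negative")
        zero = np.flatnonzero(self.lengths_um == 0)
        if len(zero) and (self.lengths_um[zero[0]:] != 0).any():
            raise ValueError("length must stay 0 after reaching 0")

    @property
    def duration_h(self) -> float:
        return float(self.times_min[-1] - self.times_min[0]) / 60.0

    @property
    def initial_length(self) -> float:
        return float(self.lengths_um[0])

    @property
    def final_length(self) -> float:
        return float(self.lengths_um[-1])


@dataclass
class EctocytosisEvent:
    """A discrete shedding event: time, shed size, and size class."""

    time_min: float
    size_um: float
    event_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.event_class = (
            CLASS_VESICLE if self.size_um < VESICLE_FRAGMENT_CUTOFF_UM else CLASS_FRAGMENT
        )


@dataclass
class DisassemblyCall:
    cilium_id: str
    condition: str
    replicate: str
    mode: str
    rate_um_per_h: float
    time_of_full_loss_min: float | None
    n_events: int
    n_vesicle_events: int
    n_fragment_events: int


def _full_loss_frame(trace: LengthTrace, full_loss_um: float) -> int | None:
    """First frame from which the length stays below the stub threshold."""
    below = trace.lengths_um < full_loss_um
    if not below[-1]:
        return None
    # walk back to the start of the terminal below-threshold stretch
    idx = len(below) - 1
    while idx > 0 and below[idx - 1]:
        idx -= 1
    return idx


def detect_events(
    trace: LengthTrace,
    drop_floor_um: float = DEFAULT_DROP_FLOOR_UM,
    full_loss_um: float = DEFAULT_FULL_LOSS_UM,
) -> list[EctocytosisEvent]:
    """Score frame-to-frame length decreases as ectocytosis events.

    A decrease of at least ``drop_floor_um`` between consecutive frames is
    emitted as one event whose shed size is the decrease itself (released
    pieces leave the cilium between frames). The single drop that takes the
    cilium below the full-loss threshold for good is terminal whole-cilium
    loss, not ectocytosis, and is skipped.
    """
    drops = -np.diff(trace.lengths_um)
    loss_frame = _full_loss_frame(trace, full_loss_um)
    events: list[EctocytosisEvent] = []
    for i, size in enumerate(drops):
        if size < drop_floor_um:
            continue
        if loss_frame is not None and i + 1 == loss_frame:
            continue  # terminal deciliation step
        events.append(EctocytosisEvent(time_min=float(trace.times_min[i + 1]),
                                       size_um=float(size)))
    return events


def _noise_scale(trace: LengthTrace) -> float:
    """Robust per-frame measurement-noise estimate from first differences."""
    diffs = np.diff(trace.lengths_um)
    diffs = diffs[trace.lengths_um[1:] > 0]  # frames after loss carry no noise
    if len(diffs) == 0:
        return 0.0
    mad = np.median(np.abs(diffs - np.median(diffs)))
    # sd of a single length sample; differences carry twice the variance
    return float(mad / 0.6745 / np.sqrt(2.0))


def classify_mode(
    trace: LengthTrace,
    events: list[EctocytosisEvent] | None = None,
    drop_floor_um: float = DEFAULT_DROP_FLOOR_UM,
    full_loss_um: float = DEFAULT_FULL_LOSS_UM,
    instant_window_h: float = DEFAULT_INSTANT_WINDOW_H,
    resorption_fraction: float = DEFAULT_RESORPTION_FRACTION,
) -> DisassemblyCall:
    """Call the disassembly mode and deciliation rate of one trace.

    With full loss (length permanently below ``full_loss_um``):

    * *instant* — loss within ``instant_window_h`` of the start with less
      than ``resorption_fraction`` of the initial length resorbed before
      the terminal drop;
    * *combined* — a resorption phase followed by an abrupt terminal drop
      (terminal step > 3x the median absolute frame-to-frame change);
    * *gradual* — otherwise (the decline ran smoothly to zero).

    Without full loss: *gradual* if the net decline clearly exceeds the
    measurement noise (> max(drop_floor, 5x the robust per-frame noise
    estimate)), *intact* otherwise. A trace with detected ectocytosis
    events is never called intact.

    The rate is always (initial − final length) / elapsed hours.
    """
    if len(trace.times_min) < 2:
        raise ValueError("trace must have at least 2 frames")
    if events is None:
        events = detect_events(trace, drop_floor_um, full_loss_um)

    elapsed_h = trace.duration_h
    rate = (trace.initial_length - trace.final_length) / elapsed_h

    loss_frame = _full_loss_frame(trace, full_loss_um)
    if loss_frame is not None and loss_frame > 0:
        t_loss = float(trace.times_min[loss_frame] - trace.times_min[0])
        pre_loss = trace.lengths_um[loss_frame - 1]
        resorbed_frac = (trace.initial_length - pre_loss) / trace.initial_length \
            if trace.initial_length > 0 else 0.0
        terminal_step = float(trace.lengths_um[loss_frame - 1] - trace.lengths_um[loss_frame])
        steps = np.abs(np.diff(trace.lengths_um[: loss_frame + 1]))
        median_step = float(np.median(steps)) if len(steps) else 0.0
        # abrupt: scale-free 3x the median frame step, guarded against pure
        # measurement noise (5x the robust noise estimate) and the drop floor
        abrupt_threshold = max(ABRUPT_DROP_FACTOR * median_step,
                               5.0 * _noise_scale(trace), drop_floor_um)
        abrupt = terminal_step > abrupt_threshold
        if t_loss <= instant_window_h * 60.0 and resorbed_frac < resorption_fraction:
            mode = MODE_INSTANT
        elif abrupt:
            mode = MODE_COMBINED
        else:
            mode = MODE_GRADUAL
    elif loss_frame == 0:
        # never had a measurable cilium; report as instant loss at t0
        t_loss = 0.0
        mode = MODE_INSTANT
    else:
        t_loss = None
        decline = trace.initial_length - trace.final_length
        threshold = max(drop_floor_um, 5.0 * _noise_scale(trace))
        if decline > threshold or events:
            mode = MODE_GRADUAL
        else:
            mode = MODE_INTACT

    n_ves = sum(1 for e in events if e.event_class == CLASS_VESICLE)
    n_frag = len(events) - n_ves
    return DisassemblyCall(
        cilium_id=trace.cilium_id,
        condition=trace.condition,
        replicate=trace.replicate,
        mode=mode,
        rate_um_per_h=float(rate),
        time_of_full_loss_min=t_loss,
        n_events=len(events),
        n_vesicle_events=n_ves,
        n_fragment_events=n_frag,
    )


def calls_to_frame(calls: list[DisassemblyCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def summarize_cohort(calls: list[DisassemblyCall]) -> pd.DataFrame:
    """Per-condition cohort summary.

    Reports, per condition: trace count, mean ± sd deciliation rate, the
    fraction of traces in each disassembly mode, and the percentage of
    traces with at least one ectocytosis event (any, vesicle-only and
    fragment-only columns). When replicate ids are present, a
    replicate-aware mean rate (mean of per-replicate means) is added.
    """
    if not calls:
        raise ValueError("no traces to summarize")
    df = calls_to_frame(calls)
    rows = []
    for condition, grp in df.groupby("condition", sort=True):
        row: dict[str, object] = {
            "condition": condition,
            "n_traces": len(grp),
            "rate_mean_um_per_h": grp["rate_um_per_h"].mean(),
            "rate_sd_um_per_h": grp["rate_um_per_h"].std(ddof=1) if len(grp) > 1 else 0.0,
        }
        reps = grp["replicate"].replace("", np.nan).dropna()
        if len(reps):
            row["rate_replicate_mean_um_per_h"] = (
                grp[grp["replicate"] != ""].groupby("replicate")["rate_um_per_h"].mean().mean()
            )
        for mode in (MODE_GRADUAL, MODE_INSTANT, MODE_COMBINED, MODE_INTACT):
            row[f"frac_{mode}"] = float((grp["mode"] == mode).mean())
        row["pct_with_event"] = float((grp["n_events"] > 0).mean() * 100.0)
        row["pct_with_vesicle"] = float((grp["n_vesicle_events"] > 0).mean() * 100.0)
        row["pct_with_fragment"] = float((grp["n_fragment_events"] > 0).mean() * 100.0)
        row["pct_intact"] = float((grp["mode"] == MODE_INTACT).mean() * 100.0)
        rows.append(row)
    return pd.DataFrame(rows)


def fluctuation_metrics(
    trace: LengthTrace,
    drop_floor_um: float = DEFAULT_DROP_FLOOR_UM,
) -> dict[str, float]:
    """Descriptive variability statistics for one trace.

    Returns the sd of the length samples, the length range, and the number
    of direction reversals whose flanking excursions both exceed the drop
    floor. These are descriptive only — no disassembly-mode semantics.
    """
    lengths = trace.lengths_um
    diffs = np.diff(lengths)
    reversals = 0
    for i in range(1, len(diffs)):
        if diffs[i - 1] * diffs[i] < 0 and min(abs(diffs[i - 1]), abs(diffs[i])) >= drop_floor_um:
            reversals += 1
    return {
        "length_sd_um": float(np.std(lengths, ddof=0)),
        "length_range_um": float(lengths.max() - lengths.min()),
        "n_reversals": int(reversals),
    }


def traces_from_frame(df: pd.DataFrame) -> list[LengthTrace]:
    """Build traces from a long-format table.

    Expected columns: ``cilium_id``, ``time_min``, ``length_um`` and
    optionally ``condition`` and ``replicate``.
    """
    for col in ("cilium_id", "time_min", "length_um"):
        if col not in df.columns:
            raise ValueError(f"trace table missing column {col!r}")
    traces = []
    for cid, grp in df.groupby("cilium_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        interval = float(np.diff(times)[0]) if len(times) > 1 else 4.0
        traces.append(LengthTrace(
            cilium_id=str(cid),
            times_min=times,
            lengths_um=grp["length_um"].to_numpy(dtype=float),
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
            replicate=str(grp["replicate"].iloc[0]) if "replicate" in grp else "",
            frame_interval_min=interval,
        ))
    return traces


def traces_to_frame(traces: list[LengthTrace]) -> pd.DataFrame:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "cilium_id": t.cilium_id,
            "condition": t.condition,
            "replicate": t.replicate,
            "time_min": t.times_min,
            "length_um": t.lengths_um,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cilium_id", "condition", "replicate", "time_min", "length_um"])
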