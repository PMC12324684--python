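"""Synthetic cilium length traces with planted disassembly dynamics.

Each trace is built from a noiseless trajectory determined by its planted
mode and deciliation rate, optionally decorated with discrete shedding
(ectocytosis) events, and then observed with additive Gaussian length
noise:

* ``stable`` — constant at the initial length (rate 0);
* ``gradual`` — linear resorption; the initial length is never below
  rate x duration, so the planted rate always equals the noiseless
  (initial − final) / duration;
* ``instant`` — constant until a loss time drawn uniform within the first
  2 h, then zero (whole-cilium shedding);
* ``combined`` — linear resorption of a drawn fraction of the length,
  then an abrupt drop of the remainder.

For modes that end at zero, the initial length is rate x duration, so the
planted rate is again exactly what the deciliation-rate formula recovers
on the noiseless trace. Scheduled shedding events subtract their size as
a step; for gradual traces the continuous slope is reduced so the total
decline (and hence the planted rate) is preserved. After the trajectory
reaches zero the observed length stays exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ciliaquant.kinetics import (
    LengthTrace,
    MODE_COMBINED,
    MODE_GRADUAL,
    MODE_INSTANT,
    MODE_INTACT,
)
from ciliaquant.simulate.config import GroundTruth, SimConfig

MODE_STABLE = "stable"
MODES = (MODE_STABLE, MODE_GRADUAL, MODE_INSTANT, MODE_COMBINED)

#: planted mode -> the disassembly call the classifier should produce
MODE_TO_CALL = {
    MODE_STABLE: MODE_INTACT,
    MODE_GRADUAL: MODE_GRADUAL,
    MODE_INSTANT: MODE_INSTANT,
    MODE_COMBINED: MODE_COMBINED,
}

INSTANT_WINDOW_H = 2.0


def _draw_event_sizes(rng: np.random.Generator, n: int,
                      vesicle_prob: float = 0.5) -> np.ndarray:
    """Shed-piece sizes straddling the 0.5 µm vesicle/fragment cutoff."""
    sizes = np.where(
        rng.uniform(size=n) < vesicle_prob,
        rng.uniform(0.32, 0.47, size=n),   # vesicles, clear of the detection floor
        rng.uniform(0.55, 1.2, size=n),    # fragments
    )
    return sizes


def _build_trace(
    mode: str,
    rate: float,
    initial: float,
    times_min: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    event_frames: np.ndarray,
    event_sizes: np.ndarray,
    loss_time_min: float | None = None,
    resorb_fraction: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless trajectory + observation. Returns (lengths, ev_frames, ev_sizes)."""
    duration_h = (times_min[-1] - times_min[0]) / 60.0
    t_h = (times_min - times_min[0]) / 60.0
    n = len(times_min)
    shed_total = float(event_sizes.sum())

    if mode == MODE_STABLE:
        base = np.full(n, initial)
    elif mode == MODE_GRADUAL:
        decline = rate * duration_h
        slope = max(decline - shed_total, 0.0) / duration_h
        base = initial - slope * t_h
    elif mode == MODE_INSTANT:
        base = np.full(n, initial)
        loss_idx = int(np.searchsorted(times_min, loss_time_min))
        base[loss_idx:] = 0.0
    elif mode == MODE_COMBINED:
        loss_idx = int(np.searchsorted(times_min, loss_time_min))
        resorb = resorb_fraction * initial - shed_total
        resorb = max(resorb, 0.0)
        slope = resorb / max(t_h[loss_idx - 1], 1e-9) if loss_idx > 0 else 0.0
        base = initial - slope * t_h
        base[loss_idx:] = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # superimpose scheduled shedding as step drops
    for f, s in zip(event_frames, event_sizes):
        base[int(f):] -= s
    base = np.maximum(base, 0.0)
    # once the noiseless trajectory reaches zero it stays there
    zero = np.flatnonzero(base <= 0)
    if len(zero):
        base[zero[0]:] = 0.0
        keep = event_frames < zero[0]
        event_frames, event_sizes = event_frames[keep], event_sizes[keep]

    obs = base.copy()
    alive = base > 0
    obs[alive] = base[alive] + rng.normal(0.0, noise_sd, size=int(alive.sum()))
    obs = np.maximum(obs, 0.0)
    # enforce the once-zero-stays-zero invariant on the observation too
    zero_obs = np.flatnonzero(obs == 0)
    if len(zero_obs):
        obs[zero_obs[0]:] = 0.0
        keep = event_frames < zero_obs[0]
        event_frames, event_sizes = event_frames[keep], event_sizes[keep]
    return obs, event_frames, event_sizes


def simulate_length_traces(
    config: SimConfig,
    mode_mix: dict[str, float],
    n_traces: int = 30,
    rate_mean: float = 1.0,
    rate_sd: float = 0.3,
    initial_length_um: float = 6.0,
    initial_length_sd_um: float = 0.5,
    event_fraction: float = 0.0,
    events_per_trace: float = 1.5,
    condition: str = "",
    n_replicates: int = 3,
    event_schedule: list[tuple[float, float]] | None = None,
    rates: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[LengthTrace], GroundTruth]:
    """Generate a cohort of traces with planted modes, rates and events.

    ``mode_mix`` maps mode names (stable/gradual/instant/combined) to
    fractions summing to 1. Rates are drawn N(rate_mean, rate_sd)
    truncated to be positive and, within a cohort, the highest drawn rates
    go to instant-loss traces (whole-cilium shedding produces the fastest
    deciliation). ``event_fraction`` of the non-stable traces receive
    shedding events (1 + Poisson(events_per_trace − 1) events each);
    passing ``event_schedule`` instead plants exactly those (hour, µm)
    events in every trace.
    """
    total = sum(mode_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode_mix must sum to 1, got {total}")
    unknown = set(mode_mix) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")
    if config.trace_duration_h <= 0:
        raise ValueError("trace duration must be positive")
    if rng is None:
        rng = config.rng(salt=1)

    n_frames = int(round(config.trace_duration_h * 60.0 / config.frame_interval_min)) + 1
    times = np.arange(n_frames) * config.frame_interval_min
    duration_h = config.trace_duration_h

    # integer mode allocation closest to the requested mix
    modes: list[str] = []
    for mode in MODES:
        modes.extend([mode] * int(round(mode_mix.get(mode, 0.0) * n_traces)))
    while len(modes) < n_traces:
        modes.append(max(mode_mix, key=mode_mix.get))
    modes = modes[:n_traces]
    rng.shuffle(modes)

    n_active = sum(1 for m in modes if m != MODE_STABLE)
    if rates is not None:
        if len(rates) != n_active:
            raise ValueError(f"need {n_active} rates for the non-stable traces")
        rates_pool = np.sort(np.asarray(rates, dtype=float))
    else:
        rates_pool = np.sort(np.abs(rng.normal(rate_mean, rate_sd, size=n_active)))
    # fastest rates go to instant-loss traces, slowest to gradual resorption
    order = sorted(range(len(modes)), key=lambda i: (
        0 if modes[i] == MODE_GRADUAL else 1 if modes[i] == MODE_COMBINED else 2))
    active_order = [i for i in order if modes[i] != MODE_STABLE]
    rates = np.zeros(len(modes))
    for pool_idx, trace_idx in enumerate(active_order):
        rates[trace_idx] = rates_pool[pool_idx]

    # event-bearing traces: a deterministic count (round(fraction x cohort)),
    # matching how per-cohort ectocytosis percentages are reported
    active_idx = [i for i, m in enumerate(modes) if m != MODE_STABLE]
    n_event_traces = int(round(event_fraction * len(active_idx)))
    event_trace_idx = set(
        rng.choice(active_idx, size=n_event_traces, replace=False).tolist()
    ) if n_event_traces else set()

    traces: list[LengthTrace] = []
    truth_rows = []
    event_rows = []
    for i, mode in enumerate(modes):
        cid = f"{condition or 'trace'}_{i:03d}"
        rate = float(rates[i])
        has_events = i in event_trace_idx
        loss_time = None
        resorb_fraction = None
        if mode == MODE_STABLE:
            initial = max(float(rng.normal(initial_length_um, initial_length_sd_um)), 1.0)
        elif mode == MODE_GRADUAL:
            initial = max(float(rng.normal(initial_length_um, initial_length_sd_um)),
                          rate * duration_h)
        elif mode == MODE_INSTANT:
            initial = rate * duration_h
            max_frame = max(int(min(INSTANT_WINDOW_H, duration_h) * 60.0
                                / config.frame_interval_min), 2)
            lo = 5 if has_events and max_frame > 6 else 1
            loss_frame = int(rng.integers(lo, max_frame))
            loss_time = times[loss_frame]
        else:  # combined
            initial = rate * duration_h
            resorb_fraction = float(rng.uniform(0.35, 0.6))
            lo = int(round(2.5 * 60.0 / config.frame_interval_min))
            hi = n_frames - int(round(0.5 * 60.0 / config.frame_interval_min))
            loss_frame = int(rng.integers(lo, max(hi, lo + 1)))
            loss_time = times[loss_frame]

        if event_schedule is not None:
            ev_frames = np.array(
                [int(round(h * 60.0 / config.frame_interval_min)) for h, _ in event_schedule],
                dtype=int)
            ev_sizes = np.array([s for _, s in event_schedule], dtype=float)
        elif has_events:
            n_ev = 1 + int(rng.poisson(max(events_per_trace - 1.0, 0.0)))
            ev_sizes = _draw_event_sizes(rng, n_ev)
            # events live strictly inside the pre-loss window
            last_frame = (int(np.searchsorted(times, loss_time)) - 2
                          if loss_time is not None else n_frames - 2)
            first_frame = 2
            budget = (0.8 * rate * duration_h if mode == MODE_GRADUAL
                      else 0.5 * initial)
            while len(ev_sizes) > 1 and ev_sizes.sum() > budget:
                ev_sizes = ev_sizes[:-1]
            if len(ev_sizes) == 1 and ev_sizes.sum() > budget:
                ev_sizes = np.array([min(0.4, max(budget, 0.32))])
            n_fit = min(len(ev_sizes), max(last_frame - first_frame + 1, 0))
            ev_sizes = ev_sizes[:n_fit]
            ev_frames = np.sort(rng.choice(
                np.arange(first_frame, last_frame + 1), size=n_fit, replace=False)
            ) if n_fit else np.array([], dtype=int)
        else:
            ev_frames = np.array([], dtype=int)
            ev_sizes = np.array([])

        lengths, ev_frames, ev_sizes = _build_trace(
            mode, rate, initial, times, rng, config.noise_sd_length_um,
            ev_frames, ev_sizes, loss_time, resorb_fraction,
        )
        replicate = f"r{i % n_replicates + 1}"
        traces.append(LengthTrace(
            cilium_id=cid, times_min=times.copy(), lengths_um=lengths,
            condition=condition, replicate=replicate,
            frame_interval_min=config.frame_interval_min,
        ))
        truth_rows.append({
            "cilium_id": cid, "condition": condition, "replicate": replicate,
            "mode": mode, "rate_um_per_h": rate, "initial_length_um": initial,
            "loss_time_min": loss_time, "n_events": len(ev_frames),
        })
        for f, s in zip(ev_frames, ev_sizes):
            event_rows.append({"cilium_id": cid, "time_min": float(times[int(f)]),
                               "size_um": float(s)})

    truth = GroundTruth(
        trace_records=pd.DataFrame(truth_rows),
        event_schedule=pd.DataFrame(event_rows,
                                    columns=["cilium_id", "time_min", "size_um"]),
    )
    return traces, truth


def simulate_disassembly_cohort(
    config: SimConfig,
    condition: str,
    rate_mean_um_per_h: float,
    rate_sd_um_per_h: float,
    mode_mix: dict[str, float],
    event_fraction: float,
    n_traces: int = 30,
    rng: np.random.Generator | None = None,
) -> tuple[list[LengthTrace], GroundTruth]:
    """One serum-stimulation live-imaging cohort at stated study conditions.

    Thin wrapper over :func:`simulate_length_traces` parameterized the way
    live-imaging disassembly experiments are reported: a per-condition
    mean ± sd deciliation rate, a disassembly-mode composition, and the
    fraction of cilia undergoing at least one ectocytosis event. The
    per-trace rates are planted on a normal quantile grid whose empirical
    mean equals the stated condition mean exactly (the reported numbers
    are themselves empirical cohort means), clipped away from zero with
    the clipped mass redistributed to preserve the mean.
    """
    from scipy import stats as sps

    n_stable = int(round(mode_mix.get(MODE_STABLE, 0.0) * n_traces))
    n_active = n_traces - n_stable
    if n_active > 0:
        grid = sps.norm.ppf((np.arange(1, n_active + 1) - 0.5) / n_active)
        planted = rate_mean_um_per_h + rate_sd_um_per_h * grid
        floor = 0.05
        deficit = np.clip(floor - planted, 0.0, None).sum()
        planted = np.clip(planted, floor, None)
        planted -= deficit / n_active  # restore the exact cohort mean
    else:
        planted = np.array([])
    return simulate_length_traces(
        config,
        mode_mix=mode_mix,
        n_traces=n_traces,
        rate_mean=rate_mean_um_per_h,
        rate_sd=rate_sd_um_per_h,
        event_fraction=event_fraction,
        condition=condition,
        rates=planted,
        rng=rng,
    )
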