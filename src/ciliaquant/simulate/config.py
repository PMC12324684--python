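"""Shared configuration and ground-truth containers for the generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimConfig:
    """Parameters shared by the synthetic-data generators.

    The defaults emulate the study conditions the pipeline targets: two
    biological x two technical BioID replicates, live traces sampled every
    4 min for 6 h, and 0.1 µm/pixel imaging.
    """

    seed: int = 0
    # spectral counting
    n_proteins: int = 500
    n_biological_reps: int = 2
    n_technical_reps: int = 2
    frac_enriched: float = 0.1
    enrichment_log2fc: float = 3.0
    psm_depth: int = 100_000
    # live traces
    frame_interval_min: float = 4.0
    trace_duration_h: float = 6.0
    noise_sd_length_um: float = 0.05
    # imaging
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_biological_reps", "n_technical_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_enriched",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.psm_depth < 1:
            raise ValueError("psm_depth must be >= 1 (zero-depth runs are meaningless)")
        if self.frame_interval_min <= 0 or self.trace_duration_h < 0:
            raise ValueError("frame interval must be positive and duration non-negative")
        if self.noise_sd_length_um < 0:
            raise ValueError("noise sd must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)


@dataclass
class GroundTruth:
    """Planted parameters emitted by a generator.

    Only the fields relevant to the generator that produced the record are
    populated; the rest stay at their defaults.
    """

    # spectral counting
    enriched_proteins: set[str] = field(default_factory=set)
    enriched_by_timepoint: dict[str, set[str]] = field(default_factory=dict)
    contaminant_registry: dict[str, float] = field(default_factory=dict)
    # traces: one row per cilium (mode, rate_um_per_h, initial_length_um)
    trace_records: pd.DataFrame | None = None
    # events: one row per scheduled shedding event (cilium_id, time_min, size_um)
    event_schedule: pd.DataFrame | None = None
    # imaging: one row per placed object
    image_objects: pd.DataFrame | None = None
    # spheroids: one row per record (spheroid_id, planted_label)
    spheroid_labels: pd.DataFrame | None = None
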